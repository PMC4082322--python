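"""Profile-HMM construction, scoring, calibration and iterative search."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_profile_hmm
from domainscout.alphabet import AMINO_ACIDS, UNIFORM_BACKGROUND
from domainscout.hmm import (
    GumbelCalibration,
    ProfileHMM,
    build_profile,
    calibrate_evalues,
    fit_gumbel,
    forward_score,
    iterative_search,
    load_hmm,
    relative_entropy_logo,
    save_hmm,
    search,
    viterbi_score,
)
from domainscout.msa import Msa
from domainscout.synthetic import (
    FamilyParams,
    family_domain_columns,
    make_search_database,
    simulate_domain_family,
)


def sharp_model(consensus: str, eps: float = 1e-4) -> ProfileHMM:
    """Near-deterministic model emitting *consensus* at its match states."""
    M = len(consensus)
    emis = np.full((M, 20), eps / 19.0)
    for k, ch in enumerate(consensus):
        emis[k] = eps / 19.0
        emis[k, AMINO_ACIDS.index(ch)] = 1.0 - eps
    t = np.tile([0.96, 0.01, 0.01, 0.02], (M, 1))
    t[M - 1] = [0, 0, 0, 1.0]
    return ProfileHMM(
        match_emissions=emis,
        insert_emissions=np.tile(UNIFORM_BACKGROUND, (M + 1, 1)),
        t_mm=t[:, 0], t_mi=t[:, 1], t_md=t[:, 2], t_me=t[:, 3],
        t_im=np.full(M, 0.7), t_ii=np.full(M, 0.3),
        t_dm=np.full(M, 0.7), t_dd=np.full(M, 0.3),
        entry=np.full(M, 1.0 / M),
        background=UNIFORM_BACKGROUND.copy(),
    )


def enumerate_path_odds(hmm: ProfileHMM, seq: str) -> list[float]:
    """Exhaustive enumeration of every legal local path's odds ratio.

    Independent of the DP: explicit recursion over (state, node, position),
    entry at any match state/target position, exit only from match states.
    """
    L, M = len(seq), hmm.M
    x = [AMINO_ACIDS.index(ch) for ch in seq]
    eo = hmm.match_emissions[:, x].T / hmm.background[x][:, None]   # (L, M)
    io = hmm.insert_emissions[:-1][:, x].T / hmm.background[x][:, None]
    out: list[float] = []

    def from_match(k: int, pos: int, odds: float) -> None:
        out.append(odds * hmm.t_me[k])
        if k + 1 < M:
            if pos + 1 < L and hmm.t_mm[k] > 0:
                from_match(k + 1, pos + 1, odds * hmm.t_mm[k] * eo[pos + 1, k + 1])
            if hmm.t_md[k] > 0:
                from_delete(k + 1, pos, odds * hmm.t_md[k])
        if pos + 1 < L and hmm.t_mi[k] > 0 and k + 1 < M:
            from_insert(k, pos + 1, odds * hmm.t_mi[k] * io[pos + 1, k])

    def from_insert(k: int, pos: int, odds: float) -> None:
        if k + 1 < M and pos + 1 < L and hmm.t_im[k] > 0:
            from_match(k + 1, pos + 1, odds * hmm.t_im[k] * eo[pos + 1, k + 1])
        if pos + 1 < L and hmm.t_ii[k] > 0:
            from_insert(k, pos + 1, odds * hmm.t_ii[k] * io[pos + 1, k])

    def from_delete(k: int, pos: int, odds: float) -> None:
        if k + 1 < M:
            if pos + 1 < L and hmm.t_dm[k] > 0:
                from_match(k + 1, pos + 1, odds * hmm.t_dm[k] * eo[pos + 1, k + 1])
            if hmm.t_dd[k] > 0:
                from_delete(k + 1, pos, odds * hmm.t_dd[k])

    for k0 in range(M):
        for p0 in range(L):
            from_match(k0, p0, hmm.entry[k0] * eo[p0, k0])
    return out


class TestBuild:
    def test_emission_and_transition_rows_normalized(self):
        fam = simulate_domain_family(FamilyParams(n=6, domain_len=40), seed=3)
        c0, c1 = family_domain_columns(fam)
        seed_msa = fam.true_alignment.select_columns(range(c0, c1 + 1))
        hmm = build_profile(seed_msa, "BLOSUM90")
        # the ProfileHMM constructor validates normalization; spot-check anyway
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0)
        assert np.allclose(hmm.t_mm + hmm.t_mi + hmm.t_md + hmm.t_me, 1.0)

    def test_identical_rows_laplace_argmax_equals_seed(self):
        row = "MKVLATWQED"
        seed = Msa(tuple((f"s{i}", row) for i in range(5)))
        hmm = build_profile(seed, "laplace", weighting="none")
        for k, ch in enumerate(row):
            assert AMINO_ACIDS[int(np.argmax(hmm.match_emissions[k]))] == ch

    def test_count_ordering_preserved_by_pseudocounts(self):
        seed = Msa((("a", "AC"), ("b", "AC"), ("c", "AG")))
        hmm = build_profile(seed, "BLOSUM62", weighting="none")
        e = hmm.match_emissions[1]
        c, g = e[AMINO_ACIDS.index("C")], e[AMINO_ACIDS.index("G")]
        unseen = e[AMINO_ACIDS.index("W")]
        assert c > g > unseen

    def test_ungapped_seed_gives_one_state_per_column(self):
        fam = simulate_domain_family(FamilyParams(n=4, domain_len=193,
                                                  flank_len_range=(0, 0)), seed=1)
        hmm = build_profile(fam.true_alignment, "BLOSUM90")
        assert hmm.M == 193

    def test_mostly_gapped_columns_become_inserts(self):
        seed = Msa((("a", "AC-D"), ("b", "AC-D"), ("c", "ACWD")))
        hmm = build_profile(seed, "BLOSUM62")
        assert hmm.M == 3

    def test_single_record_seed_rejected(self):
        with pytest.raises(ValueError):
            build_profile(Msa((("a", "ACD"),)))


class TestLogo:
    def test_background_emission_has_zero_relative_entropy(self):
        m = sharp_model("ACDEF")
        emis = m.match_emissions.copy()
        emis[2] = m.background
        m2 = ProfileHMM(
            match_emissions=emis, insert_emissions=m.insert_emissions,
            t_mm=m.t_mm, t_mi=m.t_mi, t_md=m.t_md, t_me=m.t_me,
            t_im=m.t_im, t_ii=m.t_ii, t_dm=m.t_dm, t_dd=m.t_dd,
            entry=m.entry, background=m.background,
        )
        logo = relative_entropy_logo(m2)
        assert logo.relative_entropy[2] == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_against_uniform_background_is_log2_20(self):
        M = 3
        emis = np.zeros((M, 20))
        emis[:, 0] = 1.0
        m = sharp_model("AAA")
        m2 = ProfileHMM(
            match_emissions=emis, insert_emissions=m.insert_emissions,
            t_mm=m.t_mm, t_mi=m.t_mi, t_md=m.t_md, t_me=m.t_me,
            t_im=m.t_im, t_ii=m.t_ii, t_dm=m.t_dm, t_dd=m.t_dd,
            entry=m.entry, background=UNIFORM_BACKGROUND.copy(),
        )
        logo = relative_entropy_logo(m2)
        assert logo.relative_entropy == pytest.approx([math.log2(20)] * 3)

    def test_matches_direct_summation_and_height_partition(self):
        rng = np.random.default_rng(8)
        hmm = random_profile_hmm(rng, 6)
        logo = relative_entropy_logo(hmm)
        for k in range(6):
            expected = sum(
                p * math.log2(p / q)
                for p, q in zip(hmm.match_emissions[k], hmm.background)
                if p > 0
            )
            assert logo.relative_entropy[k] == pytest.approx(expected)
            assert logo.letter_heights[k].sum() == pytest.approx(
                max(expected, 0.0), abs=1e-9
            )


class TestViterbi:
    def test_consensus_uses_every_match_state(self):
        consensus = "ACDEFGHIKLMNPQRSTVWY"
        m = sharp_model(consensus)
        r = viterbi_score(m, consensus)
        assert (r.envelope_start, r.envelope_end) == (1, 20)
        assert sorted(r.match_map) == list(range(20))

    def test_embedded_consensus_envelope_recovered(self):
        rng = np.random.default_rng(123)
        letters = np.array(list(AMINO_ACIDS))
        consensus = "".join(rng.choice(letters, size=20))
        m = sharp_model(consensus)
        hits = 0
        for rep in range(20):
            r2 = np.random.default_rng(1000 + rep)
            left = "".join(r2.choice(letters, size=50))
            right = "".join(r2.choice(letters, size=50))
            seq = left + consensus + right
            r = viterbi_score(m, seq)
            if abs(r.envelope_start - 51) <= 2 and abs(r.envelope_end - 70) <= 2:
                hits += 1
        assert hits == 20

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            viterbi_score(sharp_model("ACD"), "")


class TestForward:
    def test_single_path_model_forward_equals_viterbi(self):
        # one match state, deterministic emission and exit: exactly one path
        emis = np.zeros((1, 20))
        emis[0, AMINO_ACIDS.index("W")] = 1.0
        m = ProfileHMM(
            match_emissions=emis,
            insert_emissions=np.tile(UNIFORM_BACKGROUND, (2, 1)),
            t_mm=np.array([0.0]), t_mi=np.array([0.0]), t_md=np.array([0.0]),
            t_me=np.array([1.0]),
            t_im=np.array([1.0]), t_ii=np.array([0.0]),
            t_dm=np.array([1.0]), t_dd=np.array([0.0]),
            entry=np.array([1.0]), background=UNIFORM_BACKGROUND.copy(),
        )
        assert forward_score(m, "W") == pytest.approx(
            viterbi_score(m, "W").bit_score
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_forward_equals_exhaustive_path_sum(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(2, 6))
        L = int(rng.integers(3, 9))
        hmm = random_profile_hmm(rng, M)
        seq = "".join(rng.choice(np.array(list(AMINO_ACIDS)), size=L))
        odds = enumerate_path_odds(hmm, seq)
        assert forward_score(hmm, seq) == pytest.approx(
            math.log2(sum(odds)), abs=1e-6
        )
        assert viterbi_score(hmm, seq).bit_score == pytest.approx(
            math.log2(max(odds)), abs=1e-6
        )

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(77)
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(100):
            hmm = random_profile_hmm(rng, int(rng.integers(2, 10)))
            seq = "".join(rng.choice(letters, size=int(rng.integers(5, 30))))
            assert forward_score(hmm, seq) >= viterbi_score(hmm, seq).bit_score - 1e-9


class TestCalibration:
    def test_evalue_at_mu_closed_form(self):
        cal = GumbelCalibration(lam=0.7, mu=10.0, n_decoys=100, decoy_seed=0)
        assert cal.evalue(10.0, 1) == pytest.approx(1 - math.exp(-1), rel=1e-9)

    def test_evalue_strictly_decreasing_in_score(self):
        cal = GumbelCalibration(lam=0.7, mu=10.0, n_decoys=100, decoy_seed=0)
        evs = [cal.evalue(s, 1000) for s in np.linspace(-5, 60, 200)]
        assert all(a >= b for a, b in zip(evs, evs[1:]))
        # strictly decreasing once the survival function leaves saturation
        evs_hi = [cal.evalue(s, 1000) for s in np.linspace(10, 60, 200)]
        assert all(a > b for a, b in zip(evs_hi, evs_hi[1:]))

    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        draws = stats.gumbel_r.rvs(loc=10.0, scale=1 / 0.7, size=2000,
                                   random_state=rng)
        lam, mu = fit_gumbel(draws)
        assert abs(lam - 0.7) / 0.7 < 0.15
        assert abs(mu - 10.0) < 0.5

    def test_degenerate_scores_advise_more_decoys(self):
        with pytest.raises(ValueError, match="n_decoys"):
            fit_gumbel(np.full(100, 3.5))

    def test_calibration_reproducible_for_fixed_seed(self):
        m = sharp_model("ACDEFGHIKL")
        c1 = calibrate_evalues(m, n_decoys=60, decoy_len=40, seed=9)
        c2 = calibrate_evalues(m, n_decoys=60, decoy_len=40, seed=9)
        assert (c1.lam, c1.mu) == (c2.lam, c2.mu)


class TestSearch:
    def test_empty_database_gives_empty_hit_list(self):
        m = sharp_model("ACDEF")
        cal = GumbelCalibration(0.7, 5.0, 100, 0)
        assert search(m, [], cal, 1e-10) == []

    def test_nonpositive_cutoff_rejected(self):
        m = sharp_model("ACDEF")
        cal = GumbelCalibration(0.7, 5.0, 100, 0)
        with pytest.raises(ValueError):
            search(m, [("a", "ACDEF")], cal, 0.0)

    def test_stricter_cutoff_is_subset(self):
        fam = simulate_domain_family(FamilyParams(n=10, domain_len=60), seed=4)
        c0, c1 = family_domain_columns(fam)
        seed_msa = fam.true_alignment.select_columns(range(c0, c1 + 1))
        hmm = build_profile(seed_msa, "BLOSUM90")
        cal = calibrate_evalues(hmm, n_decoys=80, seed=1)
        db, _, _ = make_search_database(
            10, 20, FamilyParams(n=10, domain_len=60), seed=6,
            consensus=fam.consensus,
        )
        loose = {h.target_id for h in search(hmm, db, cal, 1e-10)}
        strict = {h.target_id for h in search(hmm, db, cal, 1e-100)}
        assert strict <= loose

    def test_database_order_does_not_change_hits(self):
        fam = simulate_domain_family(FamilyParams(n=8, domain_len=50), seed=9)
        c0, c1 = family_domain_columns(fam)
        seed_msa = fam.true_alignment.select_columns(range(c0, c1 + 1))
        hmm = build_profile(seed_msa, "BLOSUM90")
        cal = calibrate_evalues(hmm, n_decoys=80, seed=2)
        db, _, _ = make_search_database(
            8, 12, FamilyParams(n=8, domain_len=50), seed=10,
            consensus=fam.consensus,
        )
        hits1 = search(hmm, db, cal, 1e-5)
        hits2 = search(hmm, list(reversed(db)), cal, 1e-5)
        assert hits1 == hits2


class TestIterativeSearch:
    def _seed_and_db(self, seed):
        fam = simulate_domain_family(FamilyParams(n=8, domain_len=50), seed=seed)
        c0, c1 = family_domain_columns(fam)
        seed_msa = fam.true_alignment.select_columns(range(c0, c1 + 1))
        db, truth, _ = make_search_database(
            8, 16, FamilyParams(n=8, domain_len=50), seed=seed + 500,
            consensus=fam.consensus,
        )
        return seed_msa, db, truth

    def test_seed_only_database_is_a_fixed_point(self):
        fam = simulate_domain_family(FamilyParams(n=8, domain_len=50,
                                                  flank_len_range=(0, 0)), seed=2)
        db = list(fam.sequences)
        seed_msa = fam.true_alignment
        _, per_iter = iterative_search(
            seed_msa, db, max_iter=3, n_decoys=60, calibration_seed=0
        )
        assert len(per_iter) <= 2  # converges immediately after the first pass
        assert {h.target_id for h in per_iter[0]} == {sid for sid, _ in db}

    def test_hit_lists_monotone_non_shrinking(self):
        seed_msa, db, _ = self._seed_and_db(21)
        _, per_iter = iterative_search(
            seed_msa, db, max_iter=3, n_decoys=60, calibration_seed=1
        )
        sets = [{h.target_id for h in hits} for hits in per_iter]
        for a, b in zip(sets, sets[1:]):
            assert a <= b

    def test_remote_tier_recall_grows_with_iterations(self):
        """Seed enrichment never loses remote homologs and can gain them.

        A three-tier family (close seed p=0.10, mid-tier p=0.25, remote
        p=0.45 around one consensus): remote-tier recall is monotone over
        iterations in every run, and across a batch of seeds at least one
        run detects a remote member only after the seed has grown.
        """
        from domainscout.alphabet import UNIFORM_BACKGROUND
        from domainscout.synthetic import _draw_seq

        strict_gain = 0
        for seed in range(8):
            close = simulate_domain_family(
                FamilyParams(n=8, domain_len=40, p_sub=0.10), seed=seed * 10
            )
            mid = simulate_domain_family(
                FamilyParams(n=8, domain_len=40, p_sub=0.25),
                seed=seed * 10 + 1, consensus=close.consensus,
            )
            remote = simulate_domain_family(
                FamilyParams(n=4, domain_len=40, p_sub=0.45),
                seed=seed * 10 + 2, consensus=close.consensus,
            )
            db = [(f"mid_{i}", s) for i, (_, s) in enumerate(mid.sequences)]
            db += [(f"rem_{i}", s) for i, (_, s) in enumerate(remote.sequences)]
            rng = np.random.default_rng(seed * 10 + 3)
            db += [
                (f"bg_{i}", _draw_seq(rng, 150, UNIFORM_BACKGROUND))
                for i in range(15)
            ]
            c0, c1 = family_domain_columns(close)
            seed_msa = close.true_alignment.select_columns(range(c0, c1 + 1))
            _, per_iter = iterative_search(
                seed_msa, db, evalue_cutoff=1e-10, max_iter=3,
                n_decoys=80, calibration_seed=seed,
            )
            rem_ids = {f"rem_{i}" for i in range(4)}
            counts = [len({h.target_id for h in hs} & rem_ids) for hs in per_iter]
            assert counts == sorted(counts)  # never lose a remote hit
            if counts[-1] > counts[0]:
                strict_gain += 1
        assert strict_gain >= 1

    def test_empty_database_rejected(self):
        fam = simulate_domain_family(FamilyParams(n=4, domain_len=30), seed=0)
        with pytest.raises(ValueError):
            iterative_search(fam.true_alignment, [], max_iter=1)


def test_model_serialization_round_trip(tmp_path):
    fam = simulate_domain_family(FamilyParams(n=5, domain_len=30), seed=12)
    c0, c1 = family_domain_columns(fam)
    hmm = build_profile(fam.true_alignment.select_columns(range(c0, c1 + 1)),
                        "BLOSUM62")
    path = tmp_path / "m.hmm"
    save_hmm(hmm, path)
    loaded = load_hmm(path)
    assert np.allclose(loaded.match_emissions, hmm.match_emissions)
    assert np.allclose(loaded.t_mm, hmm.t_mm)
    seq = fam.sequences[0][1]
    assert viterbi_score(loaded, seq).bit_score == pytest.approx(
        viterbi_score(hmm, seq).bit_score
    )
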