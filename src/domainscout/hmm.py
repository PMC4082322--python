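"""Profile hidden Markov models for protein domain families.

A Plan7-like node topology (match/insert/delete per node) with uniform local
entry over match states and per-node local exit, scored in log2-odds bits
against an i.i.d. background null.  The design is HMMER-like but deliberately
not bit-compatible: no Dirichlet mixture priors, no heuristic filters, and
E-values come from an explicit, seeded Gumbel calibration against background
decoys rather than HMMER's lambda conventions.

Scoring semantics (shared by Viterbi, forward and the exhaustive-path oracle
used in the tests): a path chooses an entry match state k with probability
``entry[k]``, walks match/insert/delete states emitting a contiguous window
of the target, and exits from a match state with probability ``t_me[k]``.
Flanking residues outside the window are emitted by the null, so they
contribute zero bits; the path score is the log2 of (entry x transitions x
emission odds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, GAP, UNIFORM_BACKGROUND, encode
from .msa import Msa

_NEG = -np.inf

# Dirichlet-style prior counts for transition estimation (per node).
_PRIOR_M = np.array([1.0, 0.1, 0.1, 0.1])  # M->M, M->I, M->D, M->E
_PRIOR_I = np.array([1.0, 0.3])            # I->M, I->I
_PRIOR_D = np.array([1.0, 0.3])            # D->M, D->D


@dataclass(frozen=True)
class ProfileHMM:
    """Positional emission/transition model over ``M`` match states."""

    match_emissions: np.ndarray   # (M, 20)
    insert_emissions: np.ndarray  # (M + 1, 20)
    t_mm: np.ndarray              # M_k -> M_{k+1}
    t_mi: np.ndarray              # M_k -> I_k
    t_md: np.ndarray              # M_k -> D_{k+1}
    t_me: np.ndarray              # M_k -> E (local exit; == 1 at the last node)
    t_im: np.ndarray              # I_k -> M_{k+1}
    t_ii: np.ndarray              # I_k -> I_k
    t_dm: np.ndarray              # D_k -> M_{k+1} (-> E at the last node)
    t_dd: np.ndarray              # D_k -> D_{k+1}
    entry: np.ndarray             # B -> M_k, uniform local entry
    background: np.ndarray        # (20,)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = self.M
        if M < 1:
            raise ValueError("model must have at least one match state")
        if (self.background <= 0).any():
            raise ValueError("background must be strictly positive")
        for name, arr in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
        ):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        trans = np.stack([self.t_mm, self.t_mi, self.t_md, self.t_me], axis=1)
        if not np.allclose(trans.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match transition rows must sum to 1")
        if not np.allclose(self.t_im + self.t_ii, 1.0, atol=1e-9):
            raise ValueError("insert transition rows must sum to 1")
        if not np.allclose(self.t_dm + self.t_dd, 1.0, atol=1e-9):
            raise ValueError("delete transition rows must sum to 1")
        if not np.isclose(self.entry.sum(), 1.0, atol=1e-9):
            raise ValueError("entry distribution must sum to 1")

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]


@dataclass(frozen=True)
class GumbelCalibration:
    """Gumbel (EVD) fit to decoy bit scores; the basis of E-values."""

    lam: float
    mu: float
    n_decoys: int
    decoy_seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.n_decoys < 50:
            raise ValueError("need at least 50 decoys for calibration")

    def evalue(self, bit_score: float, n_database: int) -> float:
        """Expected count of scores >= *bit_score* in *n_database* sequences."""
        x = -self.lam * (bit_score - self.mu)
        # P(S >= s) = 1 - exp(-exp(-lam (s - mu)))
        p = -math.expm1(-math.exp(min(x, 700.0)))
        return n_database * p


@dataclass(frozen=True)
class SearchHit:
    target_id: str
    envelope_start: int
    envelope_end: int
    bit_score: float
    evalue: float
    iteration_found: int = 1

    def __post_init__(self) -> None:
        if self.envelope_start > self.envelope_end:
            raise ValueError("envelope start > end")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class ViterbiResult:
    bit_score: float
    envelope_start: int   # 1-based target coordinates
    envelope_end: int
    match_map: dict       # match state (0-based) -> target position (0-based)


@dataclass(frozen=True)
class LogoData:
    """Per-match-position relative entropy (bits) and letter heights."""

    relative_entropy: np.ndarray  # (M,)
    letter_heights: np.ndarray    # (M, 20)
    insert_probs: np.ndarray      # (M,) probability of M_k -> I_k
    delete_probs: np.ndarray      # (M,) probability of M_k -> D_{k+1}


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _blosum_conditionals(name: str, background: np.ndarray) -> np.ndarray:
    """P(a | b) matrix derived from a BLOSUM log-odds matrix (half-bit units)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    s = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = mat[a, b]
    # target frequency model: q(a,b) ~ bg_a bg_b 2^(s/2)
    joint = background[:, None] * background[None, :] * np.power(2.0, s / 2.0)
    cond = joint / joint.sum(axis=0, keepdims=True)  # P(a | b), columns sum to 1
    return cond


def position_based_weights(rows: Sequence[str]) -> np.ndarray:
    """Henikoff position-based sequence weights, scaled to sum to n."""
    n = len(rows)
    w = np.zeros(n)
    for col in zip(*rows):
        kinds: dict[str, int] = {}
        for ch in col:
            kinds[ch] = kinds.get(ch, 0) + 1
        r = len(kinds)
        for i, ch in enumerate(col):
            w[i] += 1.0 / (r * kinds[ch])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def match_columns(msa: Msa, max_gap_fraction: float = 0.5) -> list[int]:
    """1-based columns treated as match states (gap fraction <= threshold)."""
    n = len(msa)
    cols = []
    for c in range(1, msa.n_cols + 1):
        gaps = sum(1 for ch in msa.column(c) if ch == GAP)
        if gaps / n <= max_gap_fraction:
            cols.append(c)
    return cols


def build_profile(
    seed: Msa,
    pseudocount_matrix: str = "BLOSUM62",
    weighting: str = "position-based",
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Build a profile HMM from an ungapped or lightly gapped seed alignment.

    Columns with more than 50% gaps become insert columns; the rest are match
    states.  Match emissions mix weighted observed frequencies with
    substitution-matrix pseudocounts, ``p = (1 - alpha) f + alpha g`` with
    ``alpha = 20 / (20 + n_eff)`` and ``g_a = sum_b f_b P(a|b)``; pass
    ``pseudocount_matrix="laplace"`` for plain add-one pseudocounts.
    """
    if len(seed) < 2:
        raise ValueError("seed alignment needs at least 2 records")
    if background is None:
        background = UNIFORM_BACKGROUND.copy()
    rows = [row for _, row in seed.records]
    mcols = match_columns(seed)
    M = len(mcols)
    if M < 1:
        raise ValueError("no match columns in seed alignment")
    if weighting == "none":
        w = np.ones(len(rows))
    elif weighting == "position-based":
        w = position_based_weights(rows)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    n_eff = float(len(rows))
    alpha = 20.0 / (20.0 + n_eff)
    if pseudocount_matrix.lower() != "laplace":
        cond = _blosum_conditionals(pseudocount_matrix, background)

    memis = np.zeros((M, 20))
    # transition counts per node: MM MI MD ; IM II ; DM DD
    cnt_m = np.tile(_PRIOR_M, (M, 1))
    cnt_i = np.tile(_PRIOR_I, (M, 1))
    cnt_d = np.tile(_PRIOR_D, (M, 1))
    mset = set(mcols)

    for row, wt in zip(rows, w):
        # emission counts
        for k, c in enumerate(mcols):
            ch = row[c - 1]
            if ch in ("-",):
                continue
            if ch == "X":
                memis[k] += wt * background
            else:
                memis[k, AMINO_ACIDS.index(ch)] += wt
        # transition counts along this sequence's path through the columns
        state, node = "B", -1  # node = index of last match/delete column
        for c in range(1, seed.n_cols + 1):
            ch = row[c - 1]
            if c in mset:
                new_state = "D" if ch == GAP else "M"
                if state in ("M", "D") and node >= 0 and node < M - 1:
                    if state == "M":
                        cnt_m[node, 0 if new_state == "M" else 2] += wt
                    else:
                        cnt_d[node, 0 if new_state == "M" else 1] += wt
                elif state == "I" and node < M - 1:
                    cnt_i[node, 0] += wt
                state, node = new_state, node + 1
            elif ch != GAP:  # insert column with a residue
                if state == "M" and node < M - 1:
                    cnt_m[node, 1] += wt
                    state = "I"
                elif state == "I":
                    cnt_i[node, 1] += wt
                # inserts following deletes are rare; folded into the prior

    freqs = memis / np.maximum(memis.sum(axis=1, keepdims=True), 1e-12)
    if pseudocount_matrix.lower() == "laplace":
        emis = (memis + 1.0) / (memis.sum(axis=1, keepdims=True) + 20.0)
    else:
        g = freqs @ cond.T  # g_a = sum_b f_b P(a|b)
        emis = (1.0 - alpha) * freqs + alpha * g
    emis = emis / emis.sum(axis=1, keepdims=True)

    t_m = cnt_m / cnt_m.sum(axis=1, keepdims=True)
    # final node: exit is certain
    t_m[M - 1] = [0.0, 0.0, 0.0, 1.0]
    t_i = cnt_i / cnt_i.sum(axis=1, keepdims=True)
    t_d = cnt_d / cnt_d.sum(axis=1, keepdims=True)
    t_d[M - 1] = [1.0, 0.0]  # D at the last node can only leave (to E)

    return ProfileHMM(
        match_emissions=emis,
        insert_emissions=np.tile(background, (M + 1, 1)),
        t_mm=t_m[:, 0], t_mi=t_m[:, 1], t_md=t_m[:, 2], t_me=t_m[:, 3],
        t_im=t_i[:, 0], t_ii=t_i[:, 1],
        t_dm=t_d[:, 0], t_dd=t_d[:, 1],
        entry=np.full(M, 1.0 / M),
        background=background,
        metadata={
            "seed_ids": list(seed.ids),
            "pseudocount_matrix": pseudocount_matrix,
            "weighting": weighting,
            "match_columns": mcols,
        },
    )


def relative_entropy_logo(hmm: ProfileHMM) -> LogoData:
    """Relative entropy (bits) per match state and per-letter logo heights."""
    p = hmm.match_emissions
    q = hmm.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    rel = terms.sum(axis=1)
    rel = np.maximum(rel, 0.0)
    heights = p * rel[:, None]
    return LogoData(
        relative_entropy=rel,
        letter_heights=heights,
        insert_probs=hmm.t_mi.copy(),
        delete_probs=hmm.t_md.copy(),
    )


# ---------------------------------------------------------------------------
# Dynamic programming
# ---------------------------------------------------------------------------

def _log2(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(p > 0, np.log2(np.maximum(p, 1e-320)), _NEG)


def _emission_odds(hmm: ProfileHMM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(L, M) match log-odds and (L, M) insert log-odds; 'X' scores 0."""
    x = encode(seq)
    lg_m = _log2(hmm.match_emissions) - _log2(hmm.background)[None, :]
    lg_i = _log2(hmm.insert_emissions[:-1]) - _log2(hmm.background)[None, :]
    L, M = len(seq), hmm.M
    eo = np.zeros((L, M))
    io = np.zeros((L, M))
    known = x >= 0
    eo[known] = lg_m[:, x[known]].T
    io[known] = lg_i[:, x[known]].T
    return eo, io


def _scan_max(A: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max-plus prefix scan: D_k = max(A_k, D_{k-1} + c_k).

    Returns (D, from_direct) where from_direct[k] is True when D_k == A_k.
    """
    C = np.cumsum(c)
    shifted = A - C
    run = np.maximum.accumulate(shifted)
    D = C + run
    return D, shifted >= run - 1e-12


def _scan_logsum(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Log-sum-exp prefix scan: D_k = logadd2(A_k, D_{k-1} + c_k)."""
    C = np.cumsum(c)
    with np.errstate(invalid="ignore"):
        run = np.logaddexp2.accumulate(A - C)
    return C + run


def _prepare(hmm: ProfileHMM):
    return (
        _log2(hmm.t_mm), _log2(hmm.t_mi), _log2(hmm.t_md), _log2(hmm.t_me),
        _log2(hmm.t_im), _log2(hmm.t_ii), _log2(hmm.t_dm), _log2(hmm.t_dd),
        _log2(hmm.entry),
    )


def viterbi_score(hmm: ProfileHMM, seq: str) -> ViterbiResult:
    """Best local-alignment path score in bits, with envelope and match map.

    Ties are broken toward the smaller start coordinate (the earliest entry
    achieving the optimum).
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    eo, io = _emission_odds(hmm, seq)
    lmm, lmi, lmd, lme, lim, lii, ldm, ldd, lentry = _prepare(hmm)
    L, M = len(seq), hmm.M

    Vm = np.full((L, M), _NEG)
    Vi = np.full((L, M), _NEG)
    Vd = np.full((L, M), _NEG)
    d_from_m = np.zeros((L, M), dtype=bool)

    m_prev = np.full(M, _NEG)
    i_prev = np.full(M, _NEG)
    d_prev = np.full(M, _NEG)
    for t in range(L):
        from_m = np.full(M, _NEG)
        from_i = np.full(M, _NEG)
        from_d = np.full(M, _NEG)
        from_m[1:] = m_prev[:-1] + lmm[:-1]
        from_i[1:] = i_prev[:-1] + lim[:-1]
        from_d[1:] = d_prev[:-1] + ldm[:-1]
        best_in = np.maximum.reduce([lentry, from_m, from_i, from_d])
        m_cur = eo[t] + best_in
        i_cur = io[t] + np.maximum(m_prev + lmi, i_prev + lii)
        # deletes advance columns without consuming residues
        A = np.full(M, _NEG)
        A[1:] = m_cur[:-1] + lmd[:-1]
        c = np.zeros(M)
        c[1:] = ldd[:-1]
        d_cur, from_direct = _scan_max(A, c)
        Vm[t], Vi[t], Vd[t] = m_cur, i_cur, d_cur
        d_from_m[t] = from_direct
        m_prev, i_prev, d_prev = m_cur, i_cur, d_cur

    ends = Vm + lme[None, :]
    best = np.argmax(ends)
    t_end, k_end = divmod(int(best), M)
    score = float(ends[t_end, k_end])
    if not np.isfinite(score):
        raise ValueError("no finite-scoring alignment path")

    # traceback
    match_map: dict[int, int] = {}
    state, t, k = "M", t_end, k_end
    start = t_end
    tol = 1e-9
    while True:
        if state == "M":
            match_map[k] = t
            start = t
            incoming = Vm[t, k] - eo[t, k]
            if abs(incoming - lentry[k]) <= tol:
                break
            if t == 0:
                break
            if k > 0 and abs(incoming - (Vm[t - 1, k - 1] + lmm[k - 1])) <= tol:
                state, t, k = "M", t - 1, k - 1
            elif k > 0 and abs(incoming - (Vi[t - 1, k - 1] + lim[k - 1])) <= tol:
                state, t, k = "I", t - 1, k - 1
            elif k > 0 and abs(incoming - (Vd[t - 1, k - 1] + ldm[k - 1])) <= tol:
                state, t, k = "D", t - 1, k - 1
            else:  # numerical fallback: treat as entry
                break
        elif state == "I":
            incoming = Vi[t, k] - io[t, k]
            if t == 0:
                break
            if abs(incoming - (Vm[t - 1, k] + lmi[k])) <= tol:
                state, t = "M", t - 1
            else:
                state, t = "I", t - 1
        else:  # D
            if d_from_m[t, k] and k > 0:
                state, k = "M", k - 1
            elif k > 0:
                k = k - 1
            else:
                break
    env_start = min(match_map.values()) + 1
    env_end = max(match_map.values()) + 1
    return ViterbiResult(score, env_start, env_end, match_map)


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """Log2 sum over all local alignment paths (bits vs the null)."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    eo, io = _emission_odds(hmm, seq)
    lmm, lmi, lmd, lme, lim, lii, ldm, ldd, lentry = _prepare(hmm)
    L, M = len(seq), hmm.M

    total = _NEG
    m_prev = np.full(M, _NEG)
    i_prev = np.full(M, _NEG)
    d_prev = np.full(M, _NEG)
    with np.errstate(invalid="ignore"):
        for t in range(L):
            from_m = np.full(M, _NEG)
            from_i = np.full(M, _NEG)
            from_d = np.full(M, _NEG)
            from_m[1:] = m_prev[:-1] + lmm[:-1]
            from_i[1:] = i_prev[:-1] + lim[:-1]
            from_d[1:] = d_prev[:-1] + ldm[:-1]
            acc = np.logaddexp2(np.logaddexp2(lentry, from_m),
                                np.logaddexp2(from_i, from_d))
            m_cur = eo[t] + acc
            i_cur = io[t] + np.logaddexp2(m_prev + lmi, i_prev + lii)
            A = np.full(M, _NEG)
            A[1:] = m_cur[:-1] + lmd[:-1]
            c = np.zeros(M)
            c[1:] = ldd[:-1]
            d_cur = _scan_logsum(A, c)
            ends = m_cur + lme
            total = np.logaddexp2(total, np.logaddexp2.reduce(ends))
            m_prev, i_prev, d_prev = m_cur, i_cur, d_cur
    return float(total)


# ---------------------------------------------------------------------------
# Calibration and search
# ---------------------------------------------------------------------------

def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (lambda, mu)."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() < 1e-9:
        raise ValueError(
            "degenerate decoy score variance; increase n_decoys or decoy length"
        )
    loc, scale = stats.gumbel_r.fit(scores)
    return 1.0 / scale, float(loc)


def calibrate_evalues(
    hmm: ProfileHMM,
    n_decoys: int = 200,
    decoy_len: int | None = None,
    seed: int = 0,
) -> GumbelCalibration:
    """Fit a Gumbel law to Viterbi scores of background decoy sequences."""
    if n_decoys < 50:
        raise ValueError("n_decoys must be >= 50")
    if decoy_len is None:
        decoy_len = max(2 * hmm.M, 50)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    letters = np.array(list(AMINO_ACIDS))
    for i in range(n_decoys):
        seq = "".join(rng.choice(letters, size=decoy_len, p=hmm.background))
        scores[i] = viterbi_score(hmm, seq).bit_score
    lam, mu = fit_gumbel(scores)
    return GumbelCalibration(lam=lam, mu=mu, n_decoys=n_decoys, decoy_seed=seed)


def search(
    hmm: ProfileHMM,
    database: Sequence[tuple[str, str]],
    calibration: GumbelCalibration,
    evalue_cutoff: float = 1e-10,
    iteration: int = 1,
) -> list[SearchHit]:
    """Score every database sequence; keep hits with E-value <= cutoff.

    Hits are sorted by increasing E-value, then target id (the documented
    tie-break); permuting the database changes nothing but that tie order.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue cutoff must be positive")
    n_db = len(database)
    hits = []
    for tid, seq in database:
        vr = viterbi_score(hmm, seq)
        ev = calibration.evalue(vr.bit_score, n_db)
        if ev <= evalue_cutoff:
            hits.append(
                SearchHit(tid, vr.envelope_start, vr.envelope_end,
                          vr.bit_score, ev, iteration)
            )
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.target_id, h.envelope_start))
    return hits


def _match_aligned_row(hmm: ProfileHMM, seq: str) -> str:
    """Project a sequence onto the model's match columns (inserts dropped)."""
    vr = viterbi_score(hmm, seq)
    chars = ["-"] * hmm.M
    for k, t in vr.match_map.items():
        chars[k] = seq[t]
    return "".join(chars)


def _core_alignment(hmm: ProfileHMM, seed: Msa) -> Msa:
    """Seed alignment restricted to the model's match columns."""
    return seed.select_columns(hmm.metadata["match_columns"])


def iterative_search(
    seed: Msa,
    database: Sequence[tuple[str, str]],
    evalue_cutoff: float = 1e-10,
    max_iter: int = 3,
    pseudocount_matrix: str = "BLOSUM90",
    weighting: str = "position-based",
    n_decoys: int = 200,
    calibration_seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[ProfileHMM, list[list[SearchHit]]]:
    """Jackhmmer-style iterative profile search.

    Each iteration builds a model from the current seed, searches the
    database, and grows the seed with the Viterbi match-aligned rows of all
    hits so far.  Hit lists are cumulative (each iteration's list contains
    every target found at any earlier iteration, with its best E-value), so
    they are monotone non-shrinking; iteration stops at *max_iter* or when
    the hit set no longer changes.
    """
    if not database:
        raise ValueError("empty database")
    hmm = build_profile(seed, pseudocount_matrix, weighting, background)
    current = _core_alignment(hmm, seed)
    seen: dict[str, SearchHit] = {}
    per_iteration: list[list[SearchHit]] = []
    for it in range(1, max_iter + 1):
        hmm = build_profile(current, pseudocount_matrix, weighting, background)
        calib = calibrate_evalues(hmm, n_decoys=n_decoys, seed=calibration_seed)
        hits = search(hmm, database, calib, evalue_cutoff, iteration=it)
        new_ids = []
        for h in hits:
            old = seen.get(h.target_id)
            if old is None:
                seen[h.target_id] = h
                new_ids.append(h.target_id)
            elif h.evalue < old.evalue:
                seen[h.target_id] = replace(h, iteration_found=old.iteration_found)
        cumulative = sorted(
            seen.values(),
            key=lambda h: (h.evalue, -h.bit_score, h.target_id, h.envelope_start),
        )
        per_iteration.append(cumulative)
        if not new_ids:
            break
        db_by_id = dict(database)
        seed_ids = set(current.ids)
        added = [
            (tid, _match_aligned_row(hmm, db_by_id[tid]))
            for tid in sorted(seen)
            if tid not in seed_ids
        ]
        if added:
            current = Msa(tuple(current.records) + tuple(added))
    return hmm, per_iteration


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FMT_VERSION = 1


def save_hmm(hmm: ProfileHMM, path: str | Path) -> None:
    """Plain-text model serialization (versioned, lossless floats)."""
    with open(path, "w") as fh:
        fh.write(f"domainscout-hmm\t{_FMT_VERSION}\n")
        fh.write(f"M\t{hmm.M}\n")
        fh.write("alphabet\t" + AMINO_ACIDS + "\n")
        fh.write("background\t" + " ".join(f"{x:.17g}" for x in hmm.background) + "\n")
        for name in ("t_mm", "t_mi", "t_md", "t_me", "t_im", "t_ii", "t_dm", "t_dd", "entry"):
            arr = getattr(hmm, name)
            fh.write(f"{name}\t" + " ".join(f"{x:.17g}" for x in arr) + "\n")
        for k in range(hmm.M):
            fh.write(f"match\t{k}\t" + " ".join(f"{x:.17g}" for x in hmm.match_emissions[k]) + "\n")
        for k in range(hmm.M + 1):
            fh.write(f"insert\t{k}\t" + " ".join(f"{x:.17g}" for x in hmm.insert_emissions[k]) + "\n")


def load_hmm(path: str | Path) -> ProfileHMM:
    fields: dict[str, np.ndarray] = {}
    match_rows: dict[int, np.ndarray] = {}
    insert_rows: dict[int, np.ndarray] = {}
    M = None
    with open(path) as fh:
        header = fh.readline().split("\t")
        if header[0] != "domainscout-hmm":
            raise ValueError("not a domainscout HMM file")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "M":
                M = int(parts[1])
            elif parts[0] == "alphabet":
                if parts[1] != AMINO_ACIDS:
                    raise ValueError("alphabet mismatch")
            elif parts[0] == "match":
                match_rows[int(parts[1])] = np.fromstring(parts[2], sep=" ")
            elif parts[0] == "insert":
                insert_rows[int(parts[1])] = np.fromstring(parts[2], sep=" ")
            else:
                fields[parts[0]] = np.fromstring(parts[1], sep=" ")
    if M is None:
        raise ValueError("missing M record")
    return ProfileHMM(
        match_emissions=np.stack([match_rows[k] for k in range(M)]),
        insert_emissions=np.stack([insert_rows[k] for k in range(M + 1)]),
        t_mm=fields["t_mm"], t_mi=fields["t_mi"], t_md=fields["t_md"],
        t_me=fields["t_me"], t_im=fields["t_im"], t_ii=fields["t_ii"],
        t_dm=fields["t_dm"], t_dd=fields["t_dd"], entry=fields["entry"],
        background=fields["background"],
    )


def write_hits_tsv(hits: Sequence[SearchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tstart\tend\tbits\tevalue\titeration\n")
        for h in hits:
            fh.write(
                f"{h.target_id}\t{h.envelope_start}\t{h.envelope_end}\t"
                f"{h.bit_score:.4f}\t{h.evalue:.6g}\t{h.iteration_found}\n"
            )


def write_logo_tsv(logo: LogoData, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\trelative_entropy_bits\tinsert_prob\tdelete_prob\t"
                 + "\t".join(AMINO_ACIDS) + "\n")
        for k in range(len(logo.relative_entropy)):
            heights = "\t".join(f"{x:.5f}" for x in logo.letter_heights[k])
            fh.write(
                f"{k + 1}\t{logo.relative_entropy[k]:.5f}\t{logo.insert_probs[k]:.5f}\t"
                f"{logo.delete_probs[k]:.5f}\t{heights}\n"
            )
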