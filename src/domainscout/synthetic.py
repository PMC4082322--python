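"""Ground-truthed synthetic inputs for every pipeline stage.

Generators are pure functions of (parameters, seed) and write the exact file
dialects the pipeline consumes, so they double as format-writer tests.  The
defaults emulate the study conditions of the discovery workflow: a family of
14 sequences sharing one conserved 193-residue domain in divergent flanks
(per-site substitution probability 0.16 from the consensus, which puts the
expected pairwise domain identity near 70%), an architecture catalogue with
the published census shape (single-copy mass 0.858, target-only 0.219, GRAM
co-occurrence 0.703), Jukes–Cantor-like evolution along known trees, and
group-structured Cα traces under rigid motion plus Gaussian noise.  Indel
processes and database taxonomy are deliberately not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .alphabet import AMINO_ACIDS, GAP, UNIFORM_BACKGROUND
from .architecture import DomainHit, ProteinArchitecture
from .msa import Msa
from .structphylo import StructureModel, _ONE_TO_THREE
from .trees import DistanceMatrix, PhyloTree


@dataclass(frozen=True)
class FamilyParams:
    n: int = 14
    domain_len: int = 193
    flank_len_range: tuple[int, int] = (30, 120)
    p_sub: float = 0.16
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        if self.domain_len < 10:
            raise ValueError("domain_len must be >= 10")
        if not 0 <= self.p_sub < 0.5:
            raise ValueError("p_sub must lie in [0, 0.5)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.flank_len_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid flank_len_range")


@dataclass(frozen=True)
class SimulatedFamily:
    sequences: tuple[tuple[str, str], ...]
    true_alignment: Msa
    true_domain_coords: dict[str, tuple[int, int]]  # 1-based inclusive
    consensus: str
    params: FamilyParams
    seed: int


def _draw_seq(rng: np.random.Generator, length: int, background: np.ndarray) -> str:
    letters = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(letters, size=length, p=background))


def simulate_domain_family(
    params: FamilyParams = FamilyParams(),
    seed: int = 0,
    consensus: str | None = None,
) -> SimulatedFamily:
    """One conserved domain embedded in divergent flanks, with truth.

    The consensus domain is drawn from the background; each member copies it,
    substitutes each position independently with probability ``p_sub``
    (replacement drawn from the background, so it may silently restore the
    consensus), and gets background flanks of uniform random length.  The
    true alignment pads flanks with gaps around the known domain columns.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    if consensus is None:
        consensus = _draw_seq(rng, params.domain_len, params.background)
    elif len(consensus) != params.domain_len:
        raise ValueError("consensus length must equal domain_len")
    lo, hi = params.flank_len_range
    members = []
    for i in range(params.n):
        dom = list(consensus)
        sub_mask = rng.random(params.domain_len) < params.p_sub
        repl = rng.choice(letters, size=params.domain_len, p=params.background)
        for j in np.nonzero(sub_mask)[0]:
            dom[j] = repl[j]
        left = _draw_seq(rng, int(rng.integers(lo, hi + 1)), params.background)
        right = _draw_seq(rng, int(rng.integers(lo, hi + 1)), params.background)
        members.append((f"seq{i + 1:02d}", left, "".join(dom), right))

    max_left = max(len(l) for _, l, _, _ in members)
    max_right = max(len(r) for _, _, _, r in members)
    sequences, coords, rows = [], {}, []
    for sid, left, dom, right in members:
        seq = left + dom + right
        sequences.append((sid, seq))
        coords[sid] = (len(left) + 1, len(left) + len(dom))
        row = (
            GAP * (max_left - len(left)) + left + dom + right
            + GAP * (max_right - len(right))
        )
        rows.append((sid, row))
    return SimulatedFamily(
        sequences=tuple(sequences),
        true_alignment=Msa(tuple(rows)),
        true_domain_coords=coords,
        consensus=consensus,
        params=params,
        seed=seed,
    )


def family_domain_columns(fam: SimulatedFamily) -> tuple[int, int]:
    """1-based alignment columns spanned by the planted domain."""
    # flanks are padded, so the domain block starts at the same column in
    # every row: right after the widest left flank
    sid = fam.true_alignment.ids[0]
    start = fam.true_alignment.residue_to_column(sid, fam.true_domain_coords[sid][0])
    return start, start + fam.params.domain_len - 1


def expected_pairwise_domain_identity(params: FamilyParams) -> float:
    """Exact expected fractional identity between two domain copies."""
    q = params.background
    p = params.p_sub
    # P(member residue == a | consensus c): (1-p) + p q_c at a==c, else p q_a
    total = 0.0
    for c in range(20):
        pc = q[c]
        probs = p * q.copy()
        probs[c] = (1 - p) + p * q[c]
        total += pc * float((probs ** 2).sum())
    return total


def make_search_database(
    n_family: int = 20,
    n_background: int = 80,
    params: FamilyParams = FamilyParams(),
    seed: int = 0,
    consensus: str | None = None,
) -> tuple[list[tuple[str, str]], dict[str, tuple[int, int]], SimulatedFamily]:
    """Planted-domain targets mixed with pure-background decoy sequences.

    Returns (database, truth coords for planted targets, the family used to
    derive the planted members).  Background sequences match the length
    distribution of the planted ones.  Pass the *consensus* of an existing
    family to plant members of that same domain.
    """
    fam = simulate_domain_family(
        FamilyParams(
            n=n_family,
            domain_len=params.domain_len,
            flank_len_range=params.flank_len_range,
            p_sub=params.p_sub,
            background=params.background,
        ),
        seed=seed,
        consensus=consensus,
    )
    rng = np.random.default_rng(seed + 1)
    lengths = [len(s) for _, s in fam.sequences]
    db = [(f"fam_{sid}", s) for sid, s in fam.sequences]
    truth = {f"fam_{sid}": c for sid, c in fam.true_domain_coords.items()}
    for i in range(n_background):
        L = int(rng.choice(lengths))
        db.append((f"bg{i + 1:03d}", _draw_seq(rng, L, params.background)))
    order = rng.permutation(len(db))
    db = [db[i] for i in order]
    return db, truth, fam


# ---------------------------------------------------------------------------
# Architecture sets
# ---------------------------------------------------------------------------

#: Default per-domain length ranges (residues).
DOMAIN_LENGTHS = {
    "VASt": (180, 200),
    "GRAM": (60, 80),
    "C2": (80, 110),
    "Pex24p": (90, 130),
}


@dataclass(frozen=True)
class ArchitectureCatalogue:
    """Architecture strings with sampling frequencies and length ranges."""

    entries: tuple[tuple[str, float], ...]
    domain_lengths: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DOMAIN_LENGTHS)
    )

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"catalogue frequencies sum to {total}, not 1")
        for arch, _ in self.entries:
            for name in arch.split("-"):
                if name not in self.domain_lengths:
                    raise ValueError(f"no length range for domain {name!r}")

    @classmethod
    def default(cls) -> "ArchitectureCatalogue":
        # census shape: single-copy 0.858, target-only 0.219, GRAM 0.703
        return cls(
            entries=(
                ("VASt", 0.219),
                ("GRAM-VASt", 0.561),
                ("C2-VASt", 0.048),
                ("Pex24p-VASt", 0.030),
                ("GRAM-VASt-VASt", 0.100),
                ("C2-VASt-C2-GRAM-VASt", 0.042),
            )
        )


def simulate_architecture_set(
    catalogue: ArchitectureCatalogue | None = None,
    n: int = 500,
    seed: int = 0,
) -> list[ProteinArchitecture]:
    """Multinomial draw of architectures with randomly laid-out coordinates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if catalogue is None:
        catalogue = ArchitectureCatalogue.default()
    rng = np.random.default_rng(seed)
    freqs = np.array([f for _, f in catalogue.entries])
    draws = rng.multinomial(n, freqs)
    out = []
    pid = 0
    for (arch, _), count in zip(catalogue.entries, draws):
        names = arch.split("-")
        for _ in range(count):
            pid += 1
            pos = int(rng.integers(1, 40))
            hits = []
            for name in names:
                lo, hi = catalogue.domain_lengths[name]
                length = int(rng.integers(lo, hi + 1))
                hits.append(
                    DomainHit(
                        name=name, start=pos, end=pos + length - 1,
                        score=float(rng.uniform(30, 300)),
                    )
                )
                pos += length + int(rng.integers(5, 50))  # linker
            out.append(ProteinArchitecture(f"prot{pid:04d}", tuple(hits)))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


# ---------------------------------------------------------------------------
# Evolution on trees
# ---------------------------------------------------------------------------

def evolve_on_tree(
    tree: PhyloTree, length: int = 200, rate: float = 1.0, seed: int = 0
) -> Msa:
    """Jukes–Cantor-like evolution of a protein alignment along a tree.

    The root sequence is drawn from the uniform background; along a branch of
    length t each site substitutes with probability ``1 - exp(-rate * t)`` to
    a background-drawn residue (which may coincide with the current one).
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    q = UNIFORM_BACKGROUND
    root_seq = rng.choice(letters, size=length, p=q)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    rows = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            cur = root_seq
        else:
            parent = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            p_change = 1.0 - np.exp(-rate * t)
            mask = rng.random(length) < p_change
            cur = parent.copy()
            if mask.any():
                cur[mask] = rng.choice(letters, size=int(mask.sum()), p=q)
            seqs[id(node)] = cur
        if node.is_leaf():
            rows.append((node.taxon.label, "".join(cur)))
    return Msa(tuple(rows))


def additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (an additive metric)."""
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    labels = sorted(labels)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(tuple(labels), d)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _base_trace(
    rng: np.random.Generator, n_res: int, step: float = 3.8, max_turn_deg: float = 40.0
) -> np.ndarray:
    """Smooth random-walk Cα trace: fixed step length, bounded turning angle."""
    coords = np.zeros((n_res, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n_res):
        coords[i] = coords[i - 1] + step * direction
        # rotate direction by a bounded random angle about a random axis
        angle = np.deg2rad(rng.uniform(0, max_turn_deg))
        axis = np.cross(direction, rng.normal(size=3))
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        axis /= norm
        direction = (
            direction * np.cos(angle) + np.cross(axis, direction) * np.sin(angle)
        )
        direction /= np.linalg.norm(direction)
    return coords


def _random_rigid_motion(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return coords @ R.T + t


def simulate_structures(
    n_per_group: int = 5,
    n_groups: int = 2,
    sigma: float = 0.5,
    n_res: int = 150,
    seed: int = 0,
) -> tuple[list[StructureModel], list[str], Msa]:
    """Group-structured Cα traces under noise and random rigid motions.

    Each group has its own smooth base trace; members add iid Gaussian(0,
    sigma^2) noise per coordinate and a random rotation+translation.  All
    structures share one residue sequence so MSA-based pairing is total;
    returns (structures, group labels, that trivial alignment).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    seq = "".join(rng.choice(letters, size=n_res, p=UNIFORM_BACKGROUND))
    residues = tuple((_ONE_TO_THREE[ch], i + 1) for i, ch in enumerate(seq))
    structs, groups, rows = [], [], []
    for g in range(n_groups):
        base = _base_trace(rng, n_res)
        for m in range(n_per_group):
            coords = base + rng.normal(0.0, sigma, size=base.shape)
            coords = _random_rigid_motion(rng, coords)
            sid = f"g{g + 1}_m{m + 1}"
            structs.append(StructureModel(id=sid, residues=residues, coords=coords))
            groups.append(f"g{g + 1}")
            rows.append((sid, seq))
    return structs, groups, Msa(tuple(rows))


def write_params_json(path: str | Path, **params) -> None:
    """Provenance sidecar written by every CLI simulation run."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(params, indent=2, default=default) + "\n")
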