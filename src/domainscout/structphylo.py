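"""Structure-based clustering: Cα superposition, normalized RMSD, FM trees.

Pairwise residue correspondence comes from a sequence MSA (columns where
both rows are non-gap), Kabsch superposition gives the optimal rigid-body
RMSD, distances are normalized as ``100 * RMSD / n_aligned``, and the tree
is estimated by weighted least squares (Fitch–Margoliash, default power 2)
with stepwise taxon addition, non-negative branch lengths, and
nearest-neighbor-interchange refinement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .alphabet import GAP
from .msa import Msa
from .trees import DistanceMatrix, PhyloTree, TreeGraph, clamp_negative_branches

log = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class StructureModel:
    """Labeled Cα trace: one coordinate triple per residue, in Å."""

    id: str
    residues: tuple[tuple[str, int], ...]  # (three-letter name, residue number)
    coords: np.ndarray                     # (n, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.residues) < 3:
            raise ValueError("structure needs at least 3 residues")
        if coords.shape != (len(self.residues), 3):
            raise ValueError("one coordinate triple required per residue")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")

    @property
    def sequence(self) -> str:
        return "".join(_THREE_TO_ONE.get(name, "X") for name, _ in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, proper (det +1)
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_aligned: int

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("negative rmsd")
        if self.n_aligned < 3:
            raise ValueError("need at least 3 aligned residues")


# ---------------------------------------------------------------------------
# PDB-subset I/O
# ---------------------------------------------------------------------------

def read_calpha(path: str | Path, chain: str = "A", model_id: str | None = None) -> StructureModel:
    """Extract Cα atoms of one chain from a PDB file (altloc '' or 'A')."""
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    residues, coords, seen = [], [], set()
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not found in {path}")
    for res in model[chain]:
        if res.id[0] != " ":  # skip HETATM/water
            continue
        if "CA" not in res:
            continue
        atom = res["CA"]
        if atom.is_disordered():
            if "A" in atom.disordered_get_id_list():
                atom = atom.disordered_get("A")
            else:
                continue
        elif atom.get_altloc() not in (" ", "", "A"):
            continue
        num = res.id[1]
        if num in seen:
            raise ValueError(f"duplicate residue number {num} after altloc filtering")
        seen.add(num)
        residues.append((res.get_resname().strip(), num))
        coords.append(atom.get_coord())
    if not residues:
        raise ValueError(f"no Calpha atoms found in {path} chain {chain!r}")
    order = np.argsort([n for _, n in residues], kind="stable")
    residues = [residues[i] for i in order]
    coords = np.asarray(coords, dtype=float)[order]
    return StructureModel(id=model_id or path.stem, residues=tuple(residues), coords=coords)


def write_calpha(struct: StructureModel, path: str | Path, chain: str = "A") -> None:
    """Write a Cα-only PDB subset (fixed-width ATOM records)."""
    with open(path, "w") as fh:
        for i, ((name, num), (x, y, z)) in enumerate(
            zip(struct.residues, struct.coords), start=1
        ):
            fh.write(
                f"ATOM  {i:5d}  CA  {name:<3s} {chain}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition and distances
# ---------------------------------------------------------------------------

def paired_coordinates(
    msa: Msa, a: StructureModel, b: StructureModel
) -> tuple[np.ndarray, np.ndarray, int]:
    """Matched Cα pairs at alignment columns where both rows are non-gap."""
    row_a, row_b = msa.row(a.id), msa.row(b.id)
    for struct, row in ((a, row_a), (b, row_b)):
        ungapped = row.replace(GAP, "")
        if ungapped != struct.sequence:
            for pos, (x, y) in enumerate(zip(ungapped, struct.sequence), start=1):
                if x != y:
                    raise ValueError(
                        f"sequence/structure mismatch for {struct.id!r} at residue "
                        f"{pos}: alignment {x!r} vs structure {y!r}"
                    )
            raise ValueError(
                f"sequence/structure length mismatch for {struct.id!r}: "
                f"{len(ungapped)} vs {len(struct.sequence)}"
            )
    idx_a = idx_b = 0
    xa, xb = [], []
    for ca, cb in zip(row_a, row_b):
        if ca != GAP and cb != GAP:
            xa.append(a.coords[idx_a])
            xb.append(b.coords[idx_b])
        if ca != GAP:
            idx_a += 1
        if cb != GAP:
            idx_b += 1
    n = len(xa)
    if n < 3:
        raise ValueError(f"only {n} aligned residue pairs; need at least 3")
    return np.asarray(xa), np.asarray(xb), n


def kabsch_superpose(X: np.ndarray, Y: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of Y onto X (Kabsch/SVD).

    Returns the proper rotation R and translation t minimizing
    ``||X - (Y R^T + t)||`` and the residual RMSD.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both be (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    if np.linalg.matrix_rank(X0, tol=1e-8) < 2 or np.linalg.matrix_rank(Y0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Y0.T @ X0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = xc - R @ yc
    diff = X - (Y @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_aligned=n)


def normalized_structural_distance(rmsd: float, n_aligned: int) -> float:
    """Length-normalized structural distance: ``100 * RMSD / n_aligned``."""
    if n_aligned == 0:
        raise ValueError("n_aligned must be positive")
    return 100.0 * rmsd / n_aligned


def structural_distance_matrix(
    structs: Sequence[StructureModel], msa: Msa
) -> tuple[DistanceMatrix, list[dict]]:
    """All-pairs normalized structural distances plus a per-pair report."""
    if len(structs) < 3:
        raise ValueError("need at least 3 structures")
    labels = tuple(s.id for s in structs)
    n = len(structs)
    d = np.zeros((n, n))
    report = []
    for i in range(n):
        for j in range(i + 1, n):
            xa, xb, na = paired_coordinates(msa, structs[i], structs[j])
            sup = kabsch_superpose(xa, xb)
            dist = normalized_structural_distance(sup.rmsd, na)
            d[i, j] = d[j, i] = dist
            report.append(
                {
                    "a": labels[i], "b": labels[j], "n_aligned": na,
                    "rmsd": sup.rmsd, "distance": dist,
                }
            )
    return DistanceMatrix(labels, d), report


def write_superposition_report(report: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("a\tb\tn_aligned\trmsd\tdistance\n")
        for r in report:
            fh.write(
                f"{r['a']}\t{r['b']}\t{r['n_aligned']}\t{r['rmsd']:.4f}\t{r['distance']:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Fitch–Margoliash weighted least squares
# ---------------------------------------------------------------------------

def fit_branch_lengths(
    graph: TreeGraph, dm: DistanceMatrix, power: float = 2.0
) -> float:
    """Weighted non-negative least-squares branch lengths for a fixed topology.

    Minimizes ``E = sum_{i<j} (d_ij - p_ij)^2 / d_ij^power`` and stores the
    fitted lengths on *graph*; returns E.
    """
    labels = list(dm.labels)
    pairs = [
        (i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))
    ]
    d = np.array([dm.values[i, j] for i, j in pairs])
    w = np.power(np.maximum(d, 1e-12), -power) if power != 0 else np.ones_like(d)
    A = graph.edge_pair_incidence(labels)
    sw = np.sqrt(w)
    x, _ = nnls(A * sw[:, None], d * sw)
    for (a, b), ln in zip(graph.edges(), x):
        graph.set_length(a, b, float(ln))
    resid = d - A @ x
    return float((w * resid ** 2).sum())


def _nni_neighbors(graph: TreeGraph):
    """Yield copies of *graph* one nearest-neighbor interchange away."""
    for u, v in graph.internal_edges():
        u_nb = [x for x in sorted(graph.adj[u]) if x != v]
        v_nb = [x for x in sorted(graph.adj[v]) if x != u]
        if not u_nb or not v_nb:
            continue
        b = u_nb[0]
        for c in v_nb:
            g = graph.copy()
            g.remove_edge(u, b)
            g.remove_edge(v, c)
            g.add_edge(u, c, 0.0)
            g.add_edge(v, b, 0.0)
            yield g


@dataclass(frozen=True)
class FitchMargoliashResult:
    tree: PhyloTree
    error: float
    graph: TreeGraph


def fitch_margoliash_tree(dm: DistanceMatrix, power: float = 2.0) -> FitchMargoliashResult:
    """Weighted least-squares (Fitch–Margoliash) distance tree.

    Stepwise taxon addition in input-label order with non-negative
    least-squares branch lengths at every step, then NNI hill-climbing until
    no rearrangement lowers E.  Zero off-diagonal distances are replaced by
    1e-8 (the 1/d^power weight is undefined at zero) with a log entry.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    vals = dm.values.copy()
    off = ~np.eye(len(labels), dtype=bool)
    n_zero = int((vals[off] <= 0).sum())
    if n_zero:
        log.info("replacing %d zero off-diagonal distance(s) with 1e-8", n_zero)
        vals[off & (vals <= 0)] = 1e-8
    dm = DistanceMatrix(tuple(labels), vals)

    # 3-taxon star seed
    graph = TreeGraph()
    leaf_nodes = {}
    graph_center = graph.new_node()
    for lab in labels[:3]:
        ln = graph.new_node(lab)
        graph.add_edge(graph_center, ln, 0.0)
        leaf_nodes[lab] = ln
    sub = dm.reordered(labels[:3])
    best_e = fit_branch_lengths(graph, sub, power)

    for idx in range(3, len(labels)):
        lab = labels[idx]
        sub = dm.reordered(labels[: idx + 1])
        best = None
        for a, b in graph.edges():
            g = graph.copy()
            mid = g.new_node()
            g.remove_edge(a, b)
            g.add_edge(a, mid, 0.0)
            g.add_edge(mid, b, 0.0)
            leaf = g.new_node(lab)
            g.add_edge(mid, leaf, 0.0)
            e = fit_branch_lengths(g, sub, power)
            if best is None or e < best[0] - 1e-15:
                best = (e, g)
        best_e, graph = best

    # NNI refinement
    full = dm
    best_e = fit_branch_lengths(graph, full, power)
    improved = True
    while improved:
        improved = False
        for g in _nni_neighbors(graph):
            e = fit_branch_lengths(g, full, power)
            if e < best_e - 1e-12:
                best_e, graph = e, g
                improved = True
                break

    fit_branch_lengths(graph, full, power)
    clamp_negative_branches(graph, "(FM tree)")
    return FitchMargoliashResult(tree=graph.to_dendropy(), error=best_e, graph=graph)
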