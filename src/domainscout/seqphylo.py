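"""Sequence-side tree pipeline: filtering, trimming, distances, NJ, bootstrap.

A desk-scale distance pipeline: incomplete sequences are dropped by model
coverage, redundancy is removed by greedy identity clustering (CD-HIT-like
but exact, computed on shared alignment columns), columns are trimmed by gap
fraction (a single-rule simplification of TrimAl's automated heuristic; the
kept/total counts are reported), pairwise distances use the p or Kimura
protein correction, and trees come from Saitou–Nei neighbor joining with
column-resampling bootstrap supports.  Maximum-likelihood inference is
deliberately out of scope; externally computed newick trees can be ingested
via :func:`domainscout.trees.tree_from_newick`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import GAP
from .msa import Msa
from .trees import (
    DistanceMatrix,
    PhyloTree,
    TreeGraph,
    bipartitions,
    clamp_negative_branches,
)

log = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Raised when a pairwise p-distance is too large to correct (p >= 0.85)."""


@dataclass(frozen=True)
class FilterReport:
    kept: tuple[str, ...]
    dropped: tuple[str, ...]
    coverage: dict


def filter_incomplete(
    seqs: Sequence[tuple[str, str]],
    model_length: int,
    min_coverage: float = 0.7,
) -> tuple[list[tuple[str, str]], FilterReport]:
    """Keep sequences whose non-gap length covers >= min_coverage of the model."""
    if model_length < 1:
        raise ValueError("model_length must be >= 1")
    kept, dropped, cov = [], [], {}
    for sid, seq in seqs:
        c = len(seq.replace(GAP, "")) / model_length
        cov[sid] = c
        if c >= min_coverage:
            kept.append((sid, seq))
        else:
            dropped.append(sid)
    if not kept:
        log.warning("all %d sequences dropped as incomplete", len(seqs))
    return kept, FilterReport(
        kept=tuple(i for i, _ in kept), dropped=tuple(dropped), coverage=cov
    )


def _shared_identity(a: str, b: str) -> float:
    """Fractional identity over columns where both rows are non-gap (0 if none)."""
    same = comp = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            comp += 1
            if x == y:
                same += 1
    return same / comp if comp else 0.0


def remove_redundant(
    msa: Msa, identity_threshold: float = 0.95
) -> tuple[Msa, dict[str, list[str]]]:
    """Greedy identity clustering; returns representatives + cluster map.

    Records are visited by descending ungapped length (ties by id); a record
    joins the first existing representative with identity >= threshold on
    their shared alignment columns, otherwise it founds a new cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must lie in (0, 1]")
    order = sorted(
        msa.records, key=lambda r: (-len(r[1].replace(GAP, "")), r[0])
    )
    reps: list[tuple[str, str]] = []
    clusters: dict[str, list[str]] = {}
    for sid, row in order:
        for rid, rrow in reps:
            if _shared_identity(row, rrow) >= identity_threshold:
                clusters[rid].append(sid)
                break
        else:
            reps.append((sid, row))
            clusters[sid] = [sid]
    keep = {rid for rid, _ in reps}
    kept_records = tuple(r for r in msa.records if r[0] in keep)
    return Msa(kept_records), clusters


def trim_columns(
    msa: Msa, max_gap_fraction: float = 0.2
) -> tuple[Msa, list[int]]:
    """Keep columns whose gap fraction is <= max_gap_fraction.

    Returns the trimmed alignment and the kept 1-based column indices, so the
    kept/total ratio can be compared against external trimmers.
    """
    n = len(msa)
    kept = []
    for c in range(1, msa.n_cols + 1):
        gaps = sum(1 for ch in msa.column(c) if ch == GAP)
        if gaps / n <= max_gap_fraction:
            kept.append(c)
    if not kept:
        raise ValueError(
            "all columns removed; raise max_gap_fraction or check the alignment"
        )
    return msa.select_columns(kept), kept


def pairwise_distance(msa: Msa, model: str = "kimura") -> DistanceMatrix:
    """Pairwise distances: p-distance or the Kimura protein correction.

    ``p`` is 1 - fractional identity over comparable (both non-gap) columns;
    ``kimura`` applies ``d = -ln(1 - p - 0.2 p^2)`` and raises
    :class:`SaturationError` at p >= 0.85.
    """
    if model not in ("p", "kimura"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa) < 3:
        raise ValueError("need at least 3 records")
    rows = [row for _, row in msa.records]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = comp = 0
            for x, y in zip(rows[i], rows[j]):
                if x != GAP and y != GAP:
                    comp += 1
                    if x == y:
                        same += 1
            if comp == 0:
                raise ValueError(
                    f"no comparable positions between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            p = 1.0 - same / comp
            if model == "p":
                d[i, j] = d[j, i] = p
            else:
                if p >= 0.85:
                    raise SaturationError(
                        f"p-distance {p:.3f} between {msa.ids[i]!r} and "
                        f"{msa.ids[j]!r} is saturated (>= 0.85)"
                    )
                d[i, j] = d[j, i] = -math.log(1.0 - p - 0.2 * p * p)
    return DistanceMatrix(tuple(msa.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_graph(dm: DistanceMatrix) -> TreeGraph:
    """Saitou–Nei neighbor joining on a :class:`TreeGraph`.

    The standard Q criterion; ties are broken by the lexicographically
    smallest (label_i, label_j) pair, where an internal node carries the
    smallest leaf label beneath it.  Negative branch lengths are clamped to
    zero (logged).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    graph = TreeGraph()
    nodes = {lab: graph.new_node(lab) for lab in dm.labels}
    active = list(dm.labels)
    D = {a: {b: dm.get(a, b) for b in active} for a in active}
    gid = dict(nodes)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * D[a][b] - r[a] - r[b]
                key = tuple(sorted((a, b)))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, a, b)
        _, _, a, b = best
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = D[a][b] - la
        new_label = min(a, b)
        u = graph.new_node()
        graph.add_edge(u, gid[a], max(la, 0.0))
        graph.add_edge(u, gid[b], max(lb, 0.0))
        if la < 0 or lb < 0:
            log.info("clamped negative NJ branch length at join (%s, %s)", a, b)
        newd = {}
        for c in active:
            if c in (a, b):
                continue
            newd[c] = max(0.5 * (D[a][c] + D[b][c] - D[a][b]), 0.0)
        active = [c for c in active if c not in (a, b)]
        for c in active:
            D[c][new_label] = newd[c]
        D[new_label] = newd
        active.append(new_label)
        active.sort()
        gid[new_label] = u

    # resolve the final three nodes around a center
    a, b, c = active
    center = graph.new_node()
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        if ln < 0:
            log.info("clamped negative terminal NJ branch for %s", lab)
        graph.add_edge(center, gid[lab], max(ln, 0.0))
    return graph


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree as a dendropy object (see :func:`nj_graph`)."""
    return nj_graph(dm).to_dendropy()


def bootstrap_support(
    msa: Msa,
    model: str = "kimura",
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[PhyloTree, int]:
    """NJ tree with column-resampling bootstrap supports.

    Supports (fraction of replicates containing each internal bipartition,
    in [0, 1]) are attached as internal node labels of the NJ tree of the
    original alignment.  Replicates whose distances saturate are skipped and
    counted; returns (tree, number of replicates used).
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    dm = pairwise_distance(msa, model)
    tree = nj_tree(dm)
    universe = frozenset(msa.ids)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(1, msa.n_cols + 1, size=msa.n_cols)
        rep = msa.select_columns([int(c) for c in cols])
        try:
            rdm = pairwise_distance(rep, model)
        except (SaturationError, ValueError) as exc:
            log.warning("bootstrap replicate skipped: %s", exc)
            continue
        used += 1
        for split in bipartitions(nj_tree(rdm)):
            counts[split] = counts.get(split, 0) + 1
    if used == 0:
        raise ValueError("every bootstrap replicate failed")
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if not 2 <= len(side) <= len(universe) - 2:
            continue
        split = frozenset({side, universe - side})
        node.label = f"{counts.get(split, 0) / used:.3f}"
    return tree, used
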