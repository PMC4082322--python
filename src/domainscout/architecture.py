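"""Domain architectures and census statistics.

An architecture is the N→C ordered list of non-overlapping domain hits on
one protein (e.g. ``GRAM-VASt`` or ``C2-VASt-C2-GRAM-VASt``).  The census
summarizes a protein set with respect to one target domain: the copy-number
histogram, the fraction of target-containing proteins with a single copy,
the fraction carrying the target as their only domain, and co-occurrence
percentages for every other domain.  Hits may come from our own HMM search
or from any externally annotated TSV table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainHit:
    name: str
    start: int  # 1-based inclusive
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"malformed coordinates ({self.start}, {self.end}) for {self.name!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinArchitecture:
    protein_id: str
    hits: tuple[DomainHit, ...]

    def __post_init__(self) -> None:
        starts = [h.start for h in self.hits]
        if starts != sorted(starts):
            raise ValueError("hits must be sorted by start")

    def domain_names(self) -> list[str]:
        return [h.name for h in self.hits]


@dataclass(frozen=True)
class ArchitectureSummary:
    target: str
    n_proteins: int
    n_with_target: int
    copy_histogram: dict[int, int]
    fraction_single_copy: float      # % of target-containing proteins
    fraction_target_only: float      # % of target-containing proteins
    cooccurrence: dict[str, float]   # % of target-containing proteins
    architecture_counts: dict[str, int]
    # same fractions over *all* proteins, for tables whose denominator
    # convention is unknown
    fraction_single_copy_all: float
    fraction_target_only_all: float


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def resolve_overlaps(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Greedy overlap resolution by descending score.

    A candidate is dropped when it overlaps an already-kept hit by more than
    ``max(10 residues, 20% of the shorter hit)``.  Tie-break: score
    descending, then start, then name.
    """
    ordered = sorted(hits, key=lambda h: (-h.score, h.start, h.name))
    kept: list[DomainHit] = []
    for h in ordered:
        ok = True
        for k in kept:
            limit = max(10, int(0.2 * min(h.length, k.length)))
            if _overlap(h, k) > limit:
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.name))
    return kept


def architecture_string(arch: ProteinArchitecture) -> str:
    """Domain names joined N→C with '-'; empty architectures warn."""
    if not arch.hits:
        log.warning("protein %r has no domain hits", arch.protein_id)
        return ""
    return "-".join(arch.domain_names())


def architecture_summary(
    archs: Sequence[ProteinArchitecture], target: str
) -> ArchitectureSummary:
    """Census of a protein set with respect to *target* (see module doc)."""
    n = len(archs)
    copy_hist: dict[int, int] = {}
    single = only = 0
    cooc: dict[str, int] = {}
    arch_counts: dict[str, int] = {}
    n_with = 0
    for a in archs:
        names = a.domain_names()
        copies = names.count(target)
        copy_hist[copies] = copy_hist.get(copies, 0) + 1
        s = architecture_string(a) if a.hits else ""
        arch_counts[s] = arch_counts.get(s, 0) + 1
        if copies >= 1:
            n_with += 1
            if copies == 1:
                single += 1
            others = {x for x in names if x != target}
            if not others:
                only += 1
            for o in others:
                cooc[o] = cooc.get(o, 0) + 1
    if n_with == 0:
        raise ValueError(f"target domain {target!r} absent from all proteins")
    return ArchitectureSummary(
        target=target,
        n_proteins=n,
        n_with_target=n_with,
        copy_histogram=dict(sorted(copy_hist.items())),
        fraction_single_copy=100.0 * single / n_with,
        fraction_target_only=100.0 * only / n_with,
        cooccurrence={
            k: 100.0 * v / n_with for k, v in sorted(cooc.items())
        },
        architecture_counts=dict(
            sorted(arch_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
        fraction_single_copy_all=100.0 * single / n,
        fraction_target_only_all=100.0 * only / n,
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("protein_id", "domain", "start", "end", "score")


def read_hits_tsv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[ProteinArchitecture]:
    """Read a per-region annotation table and build resolved architectures.

    The header must provide (possibly via *column_map*, ours→theirs) the
    columns ``protein_id, domain, start, end, score``.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {k: (column_map or {}).get(k, k) for k in _REQUIRED}
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"hits table missing column(s): {missing}")
    out = []
    for pid, group in df.groupby(colmap["protein_id"], sort=True):
        hits = [
            DomainHit(
                name=str(r[colmap["domain"]]),
                start=int(r[colmap["start"]]),
                end=int(r[colmap["end"]]),
                score=float(r[colmap["score"]]),
            )
            for _, r in group.iterrows()
        ]
        out.append(ProteinArchitecture(str(pid), tuple(resolve_overlaps(hits))))
    return out


def write_hits_tsv(
    archs: Sequence[ProteinArchitecture], path: str | Path
) -> None:
    rows = [
        {
            "protein_id": a.protein_id, "domain": h.name,
            "start": h.start, "end": h.end, "score": h.score,
        }
        for a in archs
        for h in a.hits
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED)).to_csv(path, sep="\t", index=False)


def summary_to_json(summary: ArchitectureSummary) -> str:
    payload = {
        "target": summary.target,
        "n_proteins": summary.n_proteins,
        "n_with_target": summary.n_with_target,
        "copy_histogram": {str(k): v for k, v in summary.copy_histogram.items()},
        "fraction_single_copy": round(summary.fraction_single_copy, 1),
        "fraction_target_only": round(summary.fraction_target_only, 1),
        "cooccurrence": {k: round(v, 1) for k, v in summary.cooccurrence.items()},
        "fraction_single_copy_all": round(summary.fraction_single_copy_all, 1),
        "fraction_target_only_all": round(summary.fraction_target_only_all, 1),
        "architecture_counts": summary.architecture_counts,
    }
    return json.dumps(payload, indent=2)


def summary_table(summary: ArchitectureSummary) -> str:
    lines = [
        f"proteins analysed        {summary.n_proteins}",
        f"containing {summary.target:<14s}{summary.n_with_target}",
        f"single {summary.target} copy     {summary.fraction_single_copy:.1f}%",
        f"{summary.target} as only domain  {summary.fraction_target_only:.1f}%",
    ]
    for name, pct in summary.cooccurrence.items():
        lines.append(f"co-occurring {name:<12s}{pct:.1f}%")
    return "\n".join(lines)
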