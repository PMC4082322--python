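"""Property-based column conservation, profile smoothing and domain delimitation.

The conservation score of an alignment column is the number of physicochemical
residue classes (out of the ten Taylor/Zvelebil classes shipped as package
data) whose membership status — present in every residue, or absent from every
residue — is uniform down the column.  An identical column scores the maximum
of 10; gaps and unknown residues belong to no class, so they break every
"uniformly present" property while leaving "uniformly absent" ones intact.

Domain delimitation thresholds the smoothed (moving-average) profile and maps
segment boundaries onto a named reference sequence by counting its non-gap
characters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, GAP, UNKNOWN
from .msa import Msa


@dataclass(frozen=True)
class PropertyTable:
    """Named residue classes with fixed membership.

    The default table (``PropertyTable.default()``) is the ten-class
    Taylor/Zvelebil scheme used by the AMAS conservation score; it is shipped
    as package data and versioned.
    """

    name: str
    version: int
    properties: tuple[str, ...]
    membership: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.properties) != 10:
            raise ValueError("property table must define exactly 10 classes")
        covered = set().union(*self.membership.values())
        missing = set(AMINO_ACIDS) - covered
        if missing:
            raise ValueError(f"amino acids missing from every class: {sorted(missing)}")

    @classmethod
    def default(cls) -> "PropertyTable":
        with resources.files("domainscout.data").joinpath("properties.json").open() as fh:
            raw = json.load(fh)
        return cls(
            name=raw["name"],
            version=raw["version"],
            properties=tuple(p["name"] for p in raw["properties"]),
            membership={
                p["name"]: frozenset(p["members"]) for p in raw["properties"]
            },
        )

    def fingerprint(self, aa: str) -> frozenset[str]:
        """The set of classes containing *aa* (empty for gap/unknown)."""
        return frozenset(p for p in self.properties if aa in self.membership[p])

    def as_text(self) -> str:
        lines = [f"# property table {self.name} v{self.version}"]
        for p in self.properties:
            lines.append(f"{p}\t{''.join(sorted(self.membership[p]))}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ConservationProfile:
    """Raw and smoothed per-column conservation scores of one alignment."""

    raw: tuple[int, ...]
    smoothed: tuple[float, ...]
    window: int
    step: int

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.smoothed):
            raise ValueError("raw and smoothed profiles differ in length")
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")
        if any(not 0 <= s <= 10 for s in self.raw):
            raise ValueError("raw scores must lie in [0, 10]")

    def __len__(self) -> int:
        return len(self.raw)


@dataclass(frozen=True)
class DomainSegment:
    """A delimited conserved region, in alignment and reference coordinates.

    All coordinates are 1-based inclusive; reference positions count only
    non-gap characters of the reference row.
    """

    start_col: int
    end_col: int
    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if self.start_col > self.end_col:
            raise ValueError("segment start_col > end_col")
        if self.start_res > self.end_res:
            raise ValueError("segment start_res > end_res")

    @property
    def length_res(self) -> int:
        return self.end_res - self.start_res + 1


def column_conservation_score(
    column: Sequence[str], table: PropertyTable | None = None
) -> int:
    """Score one alignment column: count of classes uniform down the column.

    A class counts when it either contains every character of the column or
    contains none of them.  ``-`` and ``X`` belong to no class.
    """
    if len(column) == 0:
        raise ValueError("empty column")
    if table is None:
        table = PropertyTable.default()
    legal = set(AMINO_ACIDS) | {GAP, UNKNOWN}
    for ch in column:
        if ch not in legal:
            raise ValueError(f"illegal character {ch!r} in column")
    score = 0
    for prop in table.properties:
        members = table.membership[prop]
        inside = [ch in members for ch in column]
        if all(inside) or not any(inside):
            score += 1
    return score


def conservation_profile(msa: Msa, table: PropertyTable | None = None) -> ConservationProfile:
    """Raw conservation score for every column of *msa* (smoothed == raw)."""
    if table is None:
        table = PropertyTable.default()
    raw = []
    for col in range(1, msa.n_cols + 1):
        try:
            raw.append(column_conservation_score(msa.column(col), table))
        except ValueError as exc:
            raise ValueError(f"column {col}: {exc}") from exc
    return ConservationProfile(
        raw=tuple(raw), smoothed=tuple(float(r) for r in raw), window=1, step=1
    )


def smooth_profile(
    profile: ConservationProfile, window: int = 10, step: int = 1
) -> ConservationProfile:
    """Centered moving average with edge truncation.

    For window ``w`` the window at column ``i`` covers
    ``[i - (w-1)//2, i + w//2]`` intersected with the profile; with
    ``step > 1`` the output is indexed by window start (stride over columns).
    """
    if window <= 0:
        raise ValueError("window must be >= 1")
    if step <= 0:
        raise ValueError("step must be >= 1")
    raw = np.asarray(profile.raw, dtype=float)
    n = len(raw)
    left = (window - 1) // 2
    right = window // 2
    means = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        means[i] = raw[lo:hi].mean()
    if step == 1:
        smoothed = means
        raw_out = profile.raw
    else:
        idx = np.arange(0, n, step)
        smoothed = means[idx]
        raw_out = tuple(profile.raw[i] for i in idx)
    return ConservationProfile(
        raw=tuple(raw_out), smoothed=tuple(float(x) for x in smoothed),
        window=window, step=step,
    )


def _runs_above(smoothed: Sequence[float], threshold: float) -> list[list[int]]:
    runs: list[list[int]] = []
    for i, s in enumerate(smoothed, start=1):
        if s > threshold:
            if runs and runs[-1][1] == i - 1:
                runs[-1][1] = i
            else:
                runs.append([i, i])
    return runs


def delimit_domains(
    profile: ConservationProfile,
    msa: Msa,
    reference_id: str,
    threshold: float = 4.0,
    min_len: int = 25,
    merge_gap: int = 10,
    anchors: Iterable[int] = (),
) -> list[DomainSegment]:
    """Delimit conserved domains on the smoothed profile.

    Maximal runs of columns with smoothed score strictly above *threshold*
    are merged when separated by at most *merge_gap* columns, runs shorter
    than *min_len* are discarded, and each surviving segment is minimally
    extended to include any anchor reference position that falls within
    *merge_gap* columns of one of its boundaries.
    """
    if not 0 <= threshold <= 10:
        raise ValueError("threshold must lie in [0, 10]")
    ref_row = msa.row(reference_id)  # raises KeyError for unknown ids
    ref_len = len(ref_row) - ref_row.count(GAP)
    anchors = list(anchors)
    for a in anchors:
        if not 1 <= a <= ref_len:
            raise ValueError(
                f"anchor {a} outside reference length {ref_len} of {reference_id!r}"
            )
    if len(profile) != msa.n_cols:
        raise ValueError("profile length does not match alignment width")

    runs = _runs_above(profile.smoothed, threshold)
    # merge runs separated by <= merge_gap columns
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    merged = [r for r in merged if r[1] - r[0] + 1 >= min_len]

    anchor_cols = [msa.residue_to_column(reference_id, a) for a in anchors]
    for run in merged:
        for col in anchor_cols:
            if run[0] - merge_gap <= col < run[0]:
                run[0] = col
            elif run[1] < col <= run[1] + merge_gap:
                run[1] = col

    segments = []
    for start_col, end_col in merged:
        start_res = _nearest_residue(msa, reference_id, start_col, forward=True)
        end_res = _nearest_residue(msa, reference_id, end_col, forward=False)
        if start_res is None or end_res is None or start_res > end_res:
            continue  # segment covers no reference residue
        segments.append(
            DomainSegment(
                start_col=start_col, end_col=end_col,
                start_res=start_res, end_res=end_res,
            )
        )
    return segments


def _nearest_residue(msa: Msa, seq_id: str, col: int, forward: bool) -> int | None:
    """Reference residue at *col*, or the nearest one inward of it."""
    row = msa.row(seq_id)
    cols = range(col, msa.n_cols + 1) if forward else range(col, 0, -1)
    for c in cols:
        if row[c - 1] != GAP:
            return msa.column_to_residue(seq_id, c)
    return None


def _pair_identity(a: str, b: str, denominator: str = "comparable") -> float | None:
    """Percent identity of two aligned rows.

    ``comparable`` divides by positions where both rows are non-gap (the
    default convention); ``alignment`` divides by full alignment length.
    Returns None when no position is comparable.
    """
    same = 0
    comparable = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            comparable += 1
            if x == y:
                same += 1
    if denominator == "alignment":
        return 100.0 * same / len(a)
    if comparable == 0:
        return None
    return 100.0 * same / comparable


def mean_pairwise_identity(
    msa: Msa,
    col_range: tuple[int, int] | None = None,
    denominator: str = "comparable",
) -> float:
    """Mean percent identity over all unordered record pairs.

    Pairs with zero comparable positions are excluded from the mean.
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 records for pairwise identity")
    if col_range is not None:
        lo, hi = col_range
        msa = msa.select_columns(range(lo, hi + 1))
    vals = []
    rows = [row for _, row in msa.records]
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            pid = _pair_identity(rows[i], rows[j], denominator)
            if pid is not None:
                vals.append(pid)
    if not vals:
        raise ValueError("no record pair has comparable positions")
    return float(np.mean(vals))


def min_identity_to_reference(
    msa: Msa, reference_id: str, denominator: str = "comparable"
) -> float:
    """Minimum percent identity of any non-reference record to the reference."""
    if len(msa) < 2:
        raise ValueError("need at least 2 records")
    ref_row = msa.row(reference_id)
    vals = []
    for sid, row in msa.records:
        if sid == reference_id:
            continue
        pid = _pair_identity(ref_row, row, denominator)
        if pid is not None:
            vals.append(pid)
    if not vals:
        raise ValueError("no comparable non-reference record")
    return float(min(vals))


# -- I/O -------------------------------------------------------------------

def write_profile_tsv(profile: ConservationProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\traw\tsmoothed\n")
        for i, (r, s) in enumerate(zip(profile.raw, profile.smoothed), start=1):
            fh.write(f"{i}\t{r}\t{s:.6g}\n")


def read_profile_tsv(path: str | Path) -> ConservationProfile:
    raws, smooths = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("column"):
            raise ValueError("profile TSV must start with a 'column' header")
        for line in fh:
            _, r, s = line.rstrip("\n").split("\t")
            raws.append(int(r))
            smooths.append(float(s))
    return ConservationProfile(tuple(raws), tuple(smooths), window=1, step=1)


def write_segments_tsv(
    segments: Sequence[DomainSegment], path: str | Path, reference_id: str
) -> None:
    """Segments as BED-like TSV; both coordinate systems 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(
            "# coordinates: alignment columns and reference "
            f"({reference_id}) residues, both 1-based inclusive\n"
        )
        fh.write("start_col\tend_col\tstart_res\tend_res\tlength_res\n")
        for s in segments:
            fh.write(
                f"{s.start_col}\t{s.end_col}\t{s.start_res}\t{s.end_res}\t{s.length_res}\n"
            )
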