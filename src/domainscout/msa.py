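"""Rectangular gapped protein alignments and FASTA I/O.

The :class:`Msa` is the substrate of conservation scoring, column trimming,
identity statistics and distance computation.  Rows are plain strings over the
20 amino-acid letters plus ``-`` (gap) and ``X`` (unknown); ``.`` gaps are
converted on input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, check_sequence


@dataclass(frozen=True)
class Msa:
    """An immutable multiple sequence alignment.

    Parameters
    ----------
    records
        Ordered ``(id, row)`` pairs.  All rows must have equal length, ids
        must be unique, and rows may contain only AA letters, ``-`` and ``X``.
    """

    records: tuple[tuple[str, str], ...]
    n_cols: int = field(init=False)

    def __post_init__(self) -> None:
        recs = tuple((str(i), str(r).upper().replace(".", GAP)) for i, r in self.records)
        object.__setattr__(self, "records", recs)
        if not recs:
            raise ValueError("alignment must contain at least one record")
        n_cols = len(recs[0][1])
        if n_cols < 1:
            raise ValueError("alignment rows must be non-empty")
        ids = [i for i, _ in recs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        for sid, row in recs:
            if len(row) != n_cols:
                raise ValueError(
                    f"row {sid!r} has length {len(row)}, expected {n_cols}"
                )
            check_sequence(row, allow_gap=True)
        object.__setattr__(self, "n_cols", n_cols)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def row(self, seq_id: str) -> str:
        for sid, row in self.records:
            if sid == seq_id:
                return row
        raise KeyError(f"unknown sequence id {seq_id!r}")

    def column(self, col: int) -> list[str]:
        """1-based alignment column as a list of characters."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside [1, {self.n_cols}]")
        return [row[col - 1] for _, row in self.records]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def select_columns(self, cols: Sequence[int]) -> "Msa":
        """New alignment keeping the given 1-based columns, in the given order."""
        return Msa(
            tuple(
                (sid, "".join(row[c - 1] for c in cols)) for sid, row in self.records
            )
        )

    def column_to_residue(self, seq_id: str, col: int) -> int | None:
        """1-based residue index of (seq, column), or None on a gap."""
        row = self.row(seq_id)
        if row[col - 1] == GAP:
            return None
        return sum(1 for ch in row[:col] if ch != GAP)

    def residue_to_column(self, seq_id: str, res: int) -> int:
        """1-based alignment column holding residue *res* of *seq_id*."""
        row = self.row(seq_id)
        count = 0
        for i, ch in enumerate(row, start=1):
            if ch != GAP:
                count += 1
                if count == res:
                    return i
        raise IndexError(
            f"residue {res} outside ungapped length of {seq_id!r} ({count})"
        )


def read_fasta_msa(path: str | Path | io.TextIOBase) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Msa(tuple(records))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (works for aligned rows too)."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read unaligned FASTA sequences as ``(id, sequence)`` pairs."""
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out
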