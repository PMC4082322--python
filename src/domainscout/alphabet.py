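"""Amino-acid alphabet constants shared across the package."""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet, fixed ordering used for all
#: emission/background vectors.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Gap character in alignments ('.' is converted to '-' on input).
GAP = "-"

#: Unknown residue.
UNKNOWN = "X"

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Uniform background distribution over the 20 amino acids (default null).
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

# Robinson & Robinson-style marginal frequencies derived from the BLOSUM62
# target distribution; offered as a preset, uniform stays the default.
BLOSUM62_MARGINALS = np.array(
    [
        0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
        0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
    ]
)
BLOSUM62_MARGINALS = BLOSUM62_MARGINALS / BLOSUM62_MARGINALS.sum()


def check_sequence(seq: str, allow_gap: bool = False, allow_unknown: bool = True) -> None:
    """Raise ``ValueError`` naming the first illegal character in *seq*."""
    allowed = set(AMINO_ACIDS)
    if allow_gap:
        allowed.add(GAP)
    if allow_unknown:
        allowed.add(UNKNOWN)
    for ch in seq:
        if ch not in allowed:
            raise ValueError(f"illegal character {ch!r} in sequence")


def encode(seq: str) -> np.ndarray:
    """Encode an ungapped AA string as int indices; 'X' maps to -1."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch == UNKNOWN:
            out[i] = -1
        else:
            try:
                out[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"illegal character {ch!r} in sequence") from None
    return out
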