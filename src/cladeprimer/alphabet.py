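"""IUPAC nucleotide alphabet semantics.

Every degenerate symbol is represented as a 4-bit mask (A=1, C=2, G=4, T=8);
two symbols are compatible iff their masks intersect. All sequence text is
normalized on ingest: uppercased, U mapped to T.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "IUPAC_SETS",
    "MASKS",
    "GC_FRACTION",
    "InvalidSymbolError",
    "normalize",
    "validate",
    "seq_to_masks",
    "revcomp",
    "degeneracy",
    "expand_random",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: symbol -> 4-bit membership mask
MASKS: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

#: expected G+C fraction of each symbol under a uniform mixture of its bases
GC_FRACTION: dict[str, float] = {
    code: len(bases & {"G", "C"}) / len(bases) for code, bases in IUPAC_SETS.items()
}

GAP_CHARS = frozenset("-.")

# mask -> concrete base tuple, for expansion/substitution draws
_MASK_BASES: dict[int, tuple[str, ...]] = {
    mask: tuple(sorted(IUPAC_SETS[code])) for code, mask in MASKS.items()
}


class InvalidSymbolError(ValueError):
    """A character outside the IUPAC nucleotide alphabet (plus gaps, where allowed)."""


def normalize(seq: str) -> str:
    """Uppercase and map RNA U to T. Does not validate."""
    return seq.upper().replace("U", "T")


def validate(seq: str, allow_gaps: bool = False) -> None:
    """Raise :class:`InvalidSymbolError` on the first symbol outside the alphabet."""
    allowed = set(IUPAC_SETS)
    if allow_gaps:
        allowed |= GAP_CHARS
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise InvalidSymbolError(
                f"invalid nucleotide symbol {ch!r} at position {i + 1}"
            )


_MASK_LUT = np.zeros(128, dtype=np.uint8)
for _code, _mask in MASKS.items():
    _MASK_LUT[ord(_code)] = _mask


def seq_to_masks(seq: str) -> np.ndarray:
    """Encode a normalized IUPAC string as a uint8 array of 4-bit masks."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    if (masks == 0).any():
        bad = int(np.nonzero(masks == 0)[0][0])
        raise InvalidSymbolError(
            f"invalid nucleotide symbol {seq[bad]!r} at position {bad + 1}"
        )
    return masks


def revcomp(seq: str) -> str:
    """Reverse complement under IUPAC pairing (A-T, C-G, R-Y, K-M, S-S, W-W, B-V, D-H, N-N)."""
    seq = normalize(seq)
    validate(seq)
    return str(Seq(seq).reverse_complement())


def degeneracy(seq: str) -> int:
    """Number of concrete oligonucleotides encoded: the product of per-position set sizes."""
    validate(seq)
    return math.prod(len(IUPAC_SETS[ch]) for ch in seq)


def expand_random(seq: str, rng: np.random.Generator) -> str:
    """One concrete (ACGT-only) realization of a degenerate sequence, drawn uniformly."""
    validate(seq)
    out = []
    for ch in seq:
        choices = _MASK_BASES[MASKS[ch]]
        out.append(choices[int(rng.integers(len(choices)))] if len(choices) > 1 else ch)
    return "".join(out)
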