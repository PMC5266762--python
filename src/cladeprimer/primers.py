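"""Primer objects, physical properties, and IUPAC-aware template scanning.

A primer base matches a template base iff their IUPAC sets intersect, so a
degenerate primer position matching any compatible template base is not a
mismatch. Matching models substitutions only — no indels — which is the
convention used when published primers are screened against reference genes.

Coordinates are 1-based inclusive on the + strand of the template. A forward
primer is compared as written against + strand windows; a reverse primer is
compared 5'->3' against the reverse complement of each + strand window (its
footprint is still reported in + strand coordinates, with strand '-').
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import (
    GC_FRACTION,
    MASKS,
    InvalidSymbolError,
    degeneracy as seq_degeneracy,
    normalize,
    revcomp,
    seq_to_masks,
    validate,
)
from .io import NucleotideSequence

__all__ = [
    "Primer",
    "PrimerProperties",
    "BindingHit",
    "base_match",
    "count_mismatches",
    "scan_binding_sites",
    "window_mismatch_counts",
    "primer_properties",
    "wallace_tm",
    "read_primer_table",
    "write_primer_table",
]

ORIENTATIONS = ("forward", "reverse")

# Sanity bounds applied to user-supplied primer tables, not to internal motifs.
PRIMER_MIN_LENGTH = 10
PRIMER_MAX_LENGTH = 50


@dataclass(frozen=True)
class Primer:
    """A named IUPAC oligonucleotide, written 5'->3', with an orientation."""

    name: str
    seq: str
    orientation: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize(self.seq))
        validate(self.seq)
        if not self.seq:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"primer {self.name!r}: orientation must be one of {ORIENTATIONS}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerProperties:
    """Length, expected GC%, Wallace-rule Tm and degeneracy of a primer."""

    length: int
    gc_percent: float
    tm_wallace: float
    degeneracy: int


@dataclass(frozen=True)
class BindingHit:
    """A located primer footprint on a template (+ strand coordinates, 1-based inclusive)."""

    template_id: str
    strand: str  # '+' (forward primer) or '-' (reverse primer)
    start: int
    end: int
    mismatches: int
    mismatch_positions: tuple[int, ...]  # primer-relative, 1-based, 5'->3'


def base_match(primer_base: str, template_base: str) -> bool:
    """True iff the two IUPAC sets intersect."""
    try:
        return bool(MASKS[primer_base.upper()] & MASKS[template_base.upper()])
    except KeyError as exc:
        raise InvalidSymbolError(f"invalid IUPAC symbol {exc.args[0]!r}") from None


def count_mismatches(primer: Primer, window: str) -> tuple[int, list[int]]:
    """Mismatch count and primer-relative 1-based positions against a window.

    The window must already be strand-adjusted: for a reverse primer, pass the
    reverse complement of the + strand footprint so the comparison runs 5'->3'
    of the primer.
    """
    window = normalize(window)
    if len(window) != len(primer):
        raise ValueError(
            f"window length {len(window)} != primer length {len(primer)}"
        )
    pm = seq_to_masks(primer.seq)
    wm = seq_to_masks(window)
    miss = (pm & wm) == 0
    positions = [int(i) + 1 for i in np.nonzero(miss)[0]]
    return len(positions), positions


def window_mismatch_counts(primer: Primer, template_seq: str) -> np.ndarray:
    """Per-window mismatch counts along a template, strand-adjusted by orientation.

    Entry ``k`` is the mismatch count of the footprint starting at + strand
    position ``k + 1``. Empty array when the template is shorter than the primer.
    """
    L = len(primer)
    if len(template_seq) < L:
        return np.zeros(0, dtype=np.int64)
    tmask = seq_to_masks(template_seq)
    query = primer.seq if primer.orientation == "forward" else revcomp(primer.seq)
    pmask = seq_to_masks(query)
    windows = sliding_window_view(tmask, L)
    return ((windows & pmask) == 0).sum(axis=1)


def scan_binding_sites(
    primer: Primer, template: NucleotideSequence, max_mismatches: int
) -> list[BindingHit]:
    """Exhaustive sliding-window scan for footprints with <= max_mismatches.

    Forward primers match the + strand as written; reverse primers match
    footprints whose reverse complement equals the primer 5'->3'. Hits are
    sorted by (mismatches, start). No indels are modeled.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    L = len(primer)
    seq = template.seq
    if len(seq) < L:
        return []
    tmask = seq_to_masks(seq)
    forward = primer.orientation == "forward"
    query = primer.seq if forward else revcomp(primer.seq)
    pmask = seq_to_masks(query)
    windows = sliding_window_view(tmask, L)
    miss = (windows & pmask) == 0
    counts = miss.sum(axis=1)
    hits: list[BindingHit] = []
    for k in np.nonzero(counts <= max_mismatches)[0]:
        offsets = np.nonzero(miss[k])[0]
        if forward:
            positions = tuple(int(o) + 1 for o in offsets)
        else:
            positions = tuple(sorted(L - int(o) for o in offsets))
        hits.append(
            BindingHit(
                template_id=template.id,
                strand="+" if forward else "-",
                start=int(k) + 1,
                end=int(k) + L,
                mismatches=int(counts[k]),
                mismatch_positions=positions,
            )
        )
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C), on expected base counts."""
    gc = sum(GC_FRACTION[ch] for ch in seq)
    at = len(seq) - gc
    return 2.0 * at + 4.0 * gc


def primer_properties(
    primer: Primer, tm: Callable[[str], float] = wallace_tm
) -> PrimerProperties:
    """Length, GC%, Tm and degeneracy of a primer.

    GC% is the expected G+C fraction over the uniform mixture of concrete
    oligos a degenerate primer encodes (S counts 1, M/R/Y/K/W count 1/2, ...).
    The Tm calculator is pluggable; the Wallace rule is the default.
    """
    seq = primer.seq
    gc = sum(GC_FRACTION[ch] for ch in seq)
    return PrimerProperties(
        length=len(seq),
        gc_percent=100.0 * gc / len(seq),
        tm_wallace=tm(seq),
        degeneracy=seq_degeneracy(seq),
    )


def read_primer_table(path: str | Path) -> list[Primer]:
    """Read a primer TSV with columns name, sequence, orientation.

    Length bounds (10-50 nt) are enforced here, at the user-input boundary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"name", "sequence", "orientation"}
    if not required.issubset(df.columns):
        raise ValueError(f"primer table must have columns {sorted(required)}")
    primers = []
    for row in df.itertuples(index=False):
        primer = Primer(row.name, row.sequence, row.orientation)
        if not PRIMER_MIN_LENGTH <= len(primer) <= PRIMER_MAX_LENGTH:
            raise ValueError(
                f"primer {primer.name!r}: length {len(primer)} outside "
                f"[{PRIMER_MIN_LENGTH}, {PRIMER_MAX_LENGTH}]"
            )
        primers.append(primer)
    return primers


def write_primer_table(primers: Iterable[Primer], path: str | Path) -> None:
    pd.DataFrame(
        [(p.name, p.seq, p.orientation) for p in primers],
        columns=["name", "sequence", "orientation"],
    ).to_csv(path, sep="\t", index=False)
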