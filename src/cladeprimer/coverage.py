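"""Coverage and specificity analysis of primers against a labeled database.

Two reports mirror the standard in-silico primer evaluation tables:

* a mismatch report — for each primer, the minimum mismatch count against a
  reference sequence (optionally restricted to a published binding window);
* a coverage table — for allowed-mismatch levels m in {0, 1, 2, 3+}, the
  percentage of in-group sequences carrying at least one binding site at
  <= m mismatches, and the count of out-group (non-target) sequences hit at
  the same allowance. Levels are cumulative, so both columns are monotone
  non-decreasing in m.

A sequence shorter than the primer counts as not covered, not as an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import DEFAULT_MAX_PRODUCT, predict_amplicons
from .io import NucleotideSequence, ReferenceDatabase
from .primers import Primer, window_mismatch_counts

__all__ = [
    "CoverageTable",
    "mismatch_report",
    "coverage_table",
    "pair_coverage",
    "min_mismatches",
]

MISMATCH_LEVELS = (0, 1, 2, 3)
LEVEL_LABELS = ("0", "1", "2", "3+")


@dataclass(frozen=True)
class CoverageTable:
    """Intra-group coverage (%) and out-group hit counts at 0..3+ mismatches."""

    intra_group_percent: tuple[float, ...]
    out_group_hits: tuple[int, ...]
    in_group_size: int
    out_group_size: int
    levels: tuple[int, ...] = MISMATCH_LEVELS

    def to_frame(self) -> pd.DataFrame:
        labels = [str(m) for m in self.levels[:-1]] + [f"{self.levels[-1]}+"]
        return pd.DataFrame(
            {
                "mismatches": labels,
                "intra_group_percent": self.intra_group_percent,
                "out_group_hits": self.out_group_hits,
            }
        )


def min_mismatches(
    primer: Primer,
    reference: NucleotideSequence,
    window: tuple[int, int] | None = None,
) -> int | None:
    """Minimum mismatch count of a primer over all strand-appropriate footprints.

    ``window`` restricts the search to footprints intersecting the given
    1-based inclusive coordinate range (published binding windows are
    occasionally off by one against the primer length, so intersection rather
    than containment is required). Returns None when no footprint exists.
    """
    counts = window_mismatch_counts(primer, reference.seq)
    if counts.size == 0:
        return None
    if window is not None:
        lo, hi = window
        L = len(primer)
        starts = np.arange(1, counts.size + 1)
        keep = (starts <= hi) & (starts + L - 1 >= lo)
        if not keep.any():
            return None
        counts = counts[keep]
    return int(counts.min())


def mismatch_report(
    primers: Sequence[Primer],
    reference: NucleotideSequence,
    sites: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-primer minimum mismatch counts against one reference sequence.

    ``sites`` optionally maps primer names to published binding windows; the
    search is then restricted to footprints intersecting that window. Primers
    without any possible footprint are flagged ``no_site``.
    """
    rows = []
    for primer in primers:
        window = sites.get(primer.name) if sites else None
        best = min_mismatches(primer, reference, window=window)
        if best is None:
            rows.append((primer.name, len(primer), None, None, np.nan, True))
            continue
        # best-footprint coordinates: first window attaining the minimum
        counts = window_mismatch_counts(primer, reference.seq)
        starts = np.arange(1, counts.size + 1)
        if window is not None:
            lo, hi = window
            mask = (starts <= hi) & (starts + len(primer) - 1 >= lo)
            counts, starts = counts[mask], starts[mask]
        k = int(np.flatnonzero(counts == best)[0])
        start = int(starts[k])
        rows.append((primer.name, len(primer), start, start + len(primer) - 1, best, False))
    return pd.DataFrame(
        rows,
        columns=["primer", "length", "start", "end", "min_mismatches", "no_site"],
    )


def _per_sequence_min(
    primer: Primer, records: Sequence[NucleotideSequence]
) -> list[int | None]:
    out: list[int | None] = []
    for rec in records:
        counts = window_mismatch_counts(primer, rec.seq)
        out.append(int(counts.min()) if counts.size else None)
    return out


def _table_from_minima(
    in_minima: Sequence[int | None],
    out_minima: Sequence[int | None],
    max_mm: int,
) -> CoverageTable:
    levels = tuple(range(max_mm + 1))
    n_in = len(in_minima)
    intra = tuple(
        100.0 * sum(1 for v in in_minima if v is not None and v <= m) / n_in
        for m in levels
    )
    out_hits = tuple(
        sum(1 for v in out_minima if v is not None and v <= m) for m in levels
    )
    return CoverageTable(
        intra_group_percent=intra,
        out_group_hits=out_hits,
        in_group_size=n_in,
        out_group_size=len(out_minima),
        levels=levels,
    )


def coverage_table(
    primer: Primer,
    db: ReferenceDatabase,
    in_group: str | None = None,
    max_mm: int = 3,
) -> CoverageTable:
    """Intra-group coverage and out-group hits of a single primer at 0..max_mm."""
    in_records = db.in_group_records(in_group)
    out_records = db.out_group_records(in_group)
    if not in_records:
        raise ValueError("in-group is empty")
    return _table_from_minima(
        _per_sequence_min(primer, in_records),
        _per_sequence_min(primer, out_records),
        max_mm,
    )


def _pair_minima(
    fwd: Primer,
    rev: Primer,
    records: Sequence[NucleotideSequence],
    max_mm: int,
    max_product: int,
) -> list[int | None]:
    """Per sequence: smallest m at which an amplifiable pair of hits exists."""
    out: list[int | None] = []
    for rec in records:
        preds = predict_amplicons(fwd, rev, rec, max_mismatches=max_mm,
                                  max_product=max_product)
        if not preds:
            out.append(None)
        else:
            out.append(min(max(p.fwd_hit.mismatches, p.rev_hit.mismatches)
                           for p in preds))
    return out


def pair_coverage(
    fwd: Primer,
    rev: Primer,
    db: ReferenceDatabase,
    in_group: str | None = None,
    max_mm: int = 3,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> CoverageTable:
    """Coverage where a sequence counts only if both primers hit in amplifiable orientation."""
    in_records = db.in_group_records(in_group)
    out_records = db.out_group_records(in_group)
    if not in_records:
        raise ValueError("in-group is empty")
    return _table_from_minima(
        _pair_minima(fwd, rev, in_records, max_mm, max_product),
        _pair_minima(fwd, rev, out_records, max_mm, max_product),
        max_mm,
    )
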