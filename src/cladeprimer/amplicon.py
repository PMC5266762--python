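"""In-silico PCR: pairing forward/reverse binding hits into predicted amplicons.

Two product-size conventions are carried side by side. The inclusive size
(rev_end - fwd_start + 1) is the physical length of the amplified fragment;
the "reported" size (rev_end - fwd_start) is the convention under which the
published clade-primer products come out as 186, 1191 and 212 bp, and is the
one used when comparing against published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import NucleotideSequence, write_fasta
from .primers import BindingHit, Primer, scan_binding_sites

__all__ = [
    "AmpliconPrediction",
    "AmpliconError",
    "predict_amplicons",
    "extract_amplicon",
    "predictions_to_frame",
    "write_amplicon_fasta",
]

DEFAULT_MAX_PRODUCT = 5000  # nt; bounds pairing combinatorics, typical PCR limit


class AmpliconError(ValueError):
    """Invalid primer pair geometry (overlapping or inverted footprints)."""


@dataclass(frozen=True)
class AmpliconPrediction:
    """A paired forward/reverse hit with product sizes and the + strand amplicon."""

    template_id: str
    fwd_hit: BindingHit
    rev_hit: BindingHit
    product_size_reported: int  # rev_end - fwd_start (published-table convention)
    product_size_inclusive: int  # rev_end - fwd_start + 1 (physical length)
    amplicon_seq: str


def extract_amplicon(
    template: NucleotideSequence, fwd_hit: BindingHit, rev_hit: BindingHit
) -> str:
    """The + strand subsequence from fwd_hit.start to rev_hit.end inclusive."""
    if fwd_hit.template_id != rev_hit.template_id:
        raise AmpliconError("hits are on different templates")
    if fwd_hit.template_id != template.id:
        raise AmpliconError(
            f"hits are for template {fwd_hit.template_id!r}, not {template.id!r}"
        )
    if fwd_hit.end >= rev_hit.start:
        raise AmpliconError(
            f"forward footprint {fwd_hit.start}-{fwd_hit.end} does not lie "
            f"upstream of reverse footprint {rev_hit.start}-{rev_hit.end}"
        )
    return template.seq[fwd_hit.start - 1 : rev_hit.end]


def predict_amplicons(
    fwd: Primer,
    rev: Primer,
    template: NucleotideSequence,
    max_mismatches: int = 0,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[AmpliconPrediction]:
    """All amplifiable forward/reverse hit pairs on a template.

    A pair is amplifiable when the forward footprint lies strictly upstream of
    the reverse footprint and the inclusive product length is <= max_product.
    Predictions are sorted by (product size, forward start).
    """
    if fwd.orientation != "forward":
        raise ValueError(f"primer {fwd.name!r} is not a forward primer")
    if rev.orientation != "reverse":
        raise ValueError(f"primer {rev.name!r} is not a reverse primer")
    fwd_hits = scan_binding_sites(fwd, template, max_mismatches)
    rev_hits = scan_binding_sites(rev, template, max_mismatches)
    predictions = []
    for fh in fwd_hits:
        for rh in rev_hits:
            if fh.end >= rh.start:
                continue
            inclusive = rh.end - fh.start + 1
            if inclusive > max_product:
                continue
            predictions.append(
                AmpliconPrediction(
                    template_id=template.id,
                    fwd_hit=fh,
                    rev_hit=rh,
                    product_size_reported=rh.end - fh.start,
                    product_size_inclusive=inclusive,
                    amplicon_seq=extract_amplicon(template, fh, rh),
                )
            )
    predictions.sort(key=lambda p: (p.product_size_inclusive, p.fwd_hit.start))
    return predictions


def predictions_to_frame(predictions: Iterable[AmpliconPrediction]) -> pd.DataFrame:
    rows = [
        {
            "template_id": p.template_id,
            "fwd_start": p.fwd_hit.start,
            "fwd_end": p.fwd_hit.end,
            "fwd_mismatches": p.fwd_hit.mismatches,
            "rev_start": p.rev_hit.start,
            "rev_end": p.rev_hit.end,
            "rev_mismatches": p.rev_hit.mismatches,
            "product_size_reported": p.product_size_reported,
            "product_size_inclusive": p.product_size_inclusive,
        }
        for p in predictions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "template_id", "fwd_start", "fwd_end", "fwd_mismatches",
            "rev_start", "rev_end", "rev_mismatches",
            "product_size_reported", "product_size_inclusive",
        ],
    )


def write_amplicon_fasta(
    predictions: Iterable[AmpliconPrediction], path: str | Path
) -> None:
    """Write predicted amplicons as FASTA with template|start-end|size headers."""
    records = [
        NucleotideSequence(
            id=f"{p.template_id}|{p.fwd_hit.start}-{p.rev_hit.end}|{p.product_size_inclusive}",
            seq=p.amplicon_seq,
        )
        for p in predictions
    ]
    write_fasta(records, path)
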