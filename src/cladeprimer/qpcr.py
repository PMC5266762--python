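"""qPCR standard-curve calibration and absolute copy quantification.

The calibration is the ordinary least-squares line Ct = slope * log10(copies)
+ intercept fitted to a tenfold serial dilution of a known-copy standard.
Amplification efficiency is reported with the field-standard convention
E = 10^(-1/slope) - 1 (E = 1, i.e. 100%, at the ideal slope -log2(10) ~ -3.32).

Unknown reactions are converted to copies per reaction by inverting the
curve, then scaled to copies per gram wet weight via the extraction metadata
(copies_reaction * elution_volume / template_volume / mass_extracted).
Non-detects are the string "ND" in plate tables; they are excluded from
means and reported separately.

Quartiles use linear interpolation (numpy default, the "type 7" definition).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "simulate_ct",
    "quantify",
    "aggregate",
    "read_plate",
    "analyze_plate",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = ["sample", "extraction", "replicate", "role", "known_copies", "ct"]


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line: Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency 10^(-1/slope) - 1 (1.0 = 100%); NaN if slope >= 0."""
        if self.slope >= 0:
            return float("nan")
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class QuantResult:
    """Replicate-aggregated copies per gram wet weight for one sample."""

    sample: str
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n_reactions: int
    n_extractions: int
    n_nd: int = 0


def fit_standard_curve(
    log10_copies: Sequence[float], ct: Sequence[float]
) -> StandardCurve:
    """Least-squares Ct vs log10(copies) line over the dilution points."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape:
        raise ValueError("log10_copies and ct must have equal length")
    if x.size < 2:
        raise ValueError("need at least two dilution points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x-values: all dilution points identical")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=min(r2, 1.0))


def simulate_ct(copies: float, curve: StandardCurve) -> float:
    """Noise-free Ct predicted by a curve for a given copy number."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return curve.slope * np.log10(copies) + curve.intercept


def quantify(
    ct: float,
    curve: StandardCurve,
    template_volume: float = 1.0,
    elution_volume: float = 1.0,
    mass_extracted: float = 1.0,
) -> float:
    """Copies per gram wet weight from one Ct value.

    copies_reaction = 10^((ct - intercept)/slope); the result scales by
    elution_volume / template_volume (fraction of the extract in the
    reaction) and divides by the extracted mass in grams.
    """
    if curve.slope >= 0:
        raise ValueError("invalid standard curve: slope must be negative")
    if template_volume <= 0 or elution_volume <= 0 or mass_extracted <= 0:
        raise ValueError("volumes and mass must be positive")
    copies_reaction = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return copies_reaction * (elution_volume / template_volume) / mass_extracted


def aggregate(
    values: Sequence[float],
    sample: str = "",
    n_extractions: int | None = None,
    n_nd: int = 0,
) -> QuantResult:
    """Mean, sample SD, median and type-7 quartiles over replicate values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty replicate group")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    return QuantResult(
        sample=sample,
        mean=float(np.mean(v)),
        sd=sd,
        median=med,
        q1=q1,
        q3=q3,
        n_reactions=int(v.size),
        n_extractions=n_extractions if n_extractions is not None else 1,
        n_nd=n_nd,
    )


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate TSV (sample, extraction, replicate, role, known_copies, ct).

    'ND' Ct entries become NaN with ``nd`` set True.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    df["nd"] = df["ct"].str.upper().eq("ND")
    df["ct"] = pd.to_numeric(df["ct"].where(~df["nd"]), errors="raise")
    df["known_copies"] = pd.to_numeric(df["known_copies"], errors="coerce")
    return df


def analyze_plate(
    plate: pd.DataFrame,
    template_volume: float = 1.0,
    elution_volume: float = 1.0,
    mass_extracted: float = 1.0,
) -> tuple[StandardCurve, list[QuantResult]]:
    """Fit the standard curve from 'standard' rows and quantify all 'unknown' samples."""
    standards = plate[(plate["role"] == "standard") & ~plate["nd"]]
    if standards.empty:
        raise ValueError("plate contains no detectable standard reactions")
    curve = fit_standard_curve(
        np.log10(standards["known_copies"].astype(float)),
        standards["ct"].astype(float),
    )
    results = []
    unknowns = plate[plate["role"] == "unknown"]
    for sample, group in unknowns.groupby("sample", sort=True):
        detected = group[~group["nd"]]
        n_nd = int(group["nd"].sum())
        if detected.empty:
            results.append(
                QuantResult(sample=str(sample), mean=float("nan"), sd=float("nan"),
                            median=float("nan"), q1=float("nan"), q3=float("nan"),
                            n_reactions=0,
                            n_extractions=int(group["extraction"].nunique()),
                            n_nd=n_nd)
            )
            continue
        values = [
            quantify(ct, curve, template_volume, elution_volume, mass_extracted)
            for ct in detected["ct"].astype(float)
        ]
        results.append(
            aggregate(values, sample=str(sample),
                      n_extractions=int(detected["extraction"].nunique()),
                      n_nd=n_nd)
        )
    return curve, results


def results_to_frame(results: Iterable[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
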