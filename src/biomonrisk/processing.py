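"""Censoring handling, creatinine adjustment and descriptive summaries.

Raw urinary concentrations (µg/L) are turned into analysis-ready
creatinine-adjusted values (µg/g-creatinine): concentrations below the
analytical limit of detection are substituted by LOD/2 on the raw scale,
then divided by the subject's urinary creatinine (g/L) to correct for
urine dilution. Values exactly at the LOD count as detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DistributionSummary",
    "substitute_below_lod",
    "creatinine_adjust",
    "detection_rate",
    "summarize_distribution",
    "compare_groups",
    "process_measurements",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number summary of a measured quantity."""

    n: int
    min: float
    p25: float
    p50: float
    p75: float
    max: float
    units: str = ""

    def __post_init__(self) -> None:
        q = (self.min, self.p25, self.p50, self.p75, self.max)
        if any(a > b for a, b in zip(q, q[1:])):
            raise ValueError("summary quantiles out of order")


def substitute_below_lod(value, lod):
    """Replace concentrations below the LOD by LOD/2 (scalar or array).

    Detected values (>= LOD) pass through unchanged; the operation is
    idempotent because LOD/2 is itself below the LOD.
    """
    value = np.asarray(value, dtype=float)
    lod = np.asarray(lod, dtype=float)
    if np.any(value < 0) or np.any(lod <= 0):
        raise ValueError("concentrations must be >= 0 and LOD > 0")
    out = np.where(value < lod, lod / 2.0, value)
    return float(out) if out.ndim == 0 else out


def creatinine_adjust(concentration, creatinine, subject_id=None):
    """Concentration (µg/L) divided by urinary creatinine (g/L) → µg/g-cre."""
    concentration = np.asarray(concentration, dtype=float)
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        if subject_id is not None:
            bad = np.asarray(subject_id)[np.asarray(creatinine <= 0)]
            raise ValueError(
                f"non-positive creatinine for subject(s): {', '.join(map(str, bad[:5]))}"
            )
        raise ValueError("creatinine must be positive")
    out = concentration / creatinine
    return float(out) if out.ndim == 0 else out


def detection_rate(measurements: pd.DataFrame) -> float:
    """Fraction of measurements with raw concentration at/above the LOD."""
    if len(measurements) == 0:
        raise ValueError("no measurements")
    detected = measurements["raw_concentration"] >= measurements["lod"]
    return float(detected.mean())


def summarize_distribution(values, units: str = "") -> DistributionSummary:
    """Empirical min/quartiles/max with linear interpolation between order stats."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return DistributionSummary(
        n=int(values.size),
        min=float(values.min()),
        p25=float(q25),
        p50=float(q50),
        p75=float(q75),
        max=float(values.max()),
        units=units,
    )


def compare_groups(*groups) -> tuple[float, float]:
    """Kruskal–Wallis rank test across age strata: (H statistic, p-value)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def process_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """LOD/2 substitution followed by creatinine adjustment, per row.

    Adds ``substituted`` (µg/L) and ``adjusted`` (µg/g-creatinine)
    columns to a tidy measurement table with columns subject_id,
    analyte_id, raw_concentration, lod, creatinine.
    """
    out = measurements.copy()
    out["substituted"] = substitute_below_lod(
        out["raw_concentration"].to_numpy(), out["lod"].to_numpy()
    )
    out["adjusted"] = creatinine_adjust(
        out["substituted"].to_numpy(),
        out["creatinine"].to_numpy(),
        subject_id=out["subject_id"].to_numpy(),
    )
    return out
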