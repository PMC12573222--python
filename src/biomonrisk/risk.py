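"""Deterministic hazard quotient / hazard index risk characterization.

HQ = EDI / reference dose, with EDI and reference dose first reconciled
to a common canonical unit (µg/kg-bw/day). The hazard index for the
parabens is the dose-additive sum HQ_MP + HQ_EP + HQ_PP; BPA is assessed
on its own TDI and is never folded into the paraben HI. HQ or HI ≥ 1
flags potential risk.

Default reference doses: EFSA group ADI 10 mg/kg-bw/day for MP and EP,
EMA ADI 1.25 mg/kg-bw/day for PP, and the 2023 EFSA TDI of
0.2 ng/kg-bw/day for BPA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import surveydata

__all__ = [
    "ReferenceDose",
    "DEFAULT_REFERENCE_DOSES",
    "load_reference_doses",
    "hazard_quotient",
    "hazard_index",
    "exceeds",
    "exceedance_fraction",
    "risk_table",
]

#: mass-unit prefixes convertible to µg (per kg-bw per day implied).
_TO_UG = {"ng": 1e-3, "ug": 1.0, "µg": 1.0, "mg": 1e3, "g": 1e6}


def _unit_to_ug(value: float, units: str) -> float:
    mass = units.split("/", 1)[0].strip()
    try:
        return value * _TO_UG[mass]
    except KeyError:
        raise ValueError(f"unknown mass unit {mass!r} in {units!r}") from None


@dataclass(frozen=True)
class ReferenceDose:
    """Health-based reference dose (ADI or TDI) for one analyte."""

    analyte_id: str
    value: float
    units: str = "ug/kg-bw/day"
    dose_type: str = "ADI"
    source: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"{self.analyte_id}: reference dose must be positive")
        _unit_to_ug(self.value, self.units)  # validate unit early

    @property
    def value_ug(self) -> float:
        """Reference dose on the canonical µg/kg-bw/day scale."""
        return _unit_to_ug(self.value, self.units)


DEFAULT_REFERENCE_DOSES: Mapping[str, ReferenceDose] = {
    a: ReferenceDose(a, v, units=u, dose_type=t, source=s)
    for a, (v, u, t, s) in surveydata.REFERENCE_DOSES.items()
}


def load_reference_doses(path) -> dict[str, ReferenceDose]:
    """Read a YAML registry {analyte: {value, units, dose_type, source}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        a: ReferenceDose(
            a,
            float(d["value"]),
            units=d.get("units", "ug/kg-bw/day"),
            dose_type=d.get("dose_type", "ADI"),
            source=d.get("source", ""),
        )
        for a, d in raw.items()
    }


def hazard_quotient(edi, rfd: ReferenceDose, edi_units: str = "ug/kg-bw/day"):
    """HQ = EDI / reference dose after conversion to µg/kg-bw/day."""
    edi = np.asarray(edi, dtype=float)
    if np.any(edi < 0):
        raise ValueError("EDI must be non-negative")
    edi_ug = _unit_to_ug(1.0, edi_units) * edi
    out = edi_ug / rfd.value_ug
    return float(out) if out.ndim == 0 else out


def hazard_index(hqs: Mapping[str, float] | Mapping[str, np.ndarray]):
    """Dose-additive paraben hazard index: HQ_MP + HQ_EP + HQ_PP.

    Exactly the three parabens must be supplied; BPA has its own TDI and
    is rejected here.
    """
    if set(hqs) != set(surveydata.PARABENS):
        raise ValueError(
            f"hazard index is defined for exactly {set(surveydata.PARABENS)}, "
            f"got {set(hqs)}"
        )
    out = sum(np.asarray(hqs[a], dtype=float) for a in surveydata.PARABENS)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def exceeds(hq_or_hi) -> bool | np.ndarray:
    """Potential-risk flag: HQ or HI at/above 1."""
    arr = np.asarray(hq_or_hi, dtype=float) >= 1.0
    return bool(arr) if arr.ndim == 0 else arr


def exceedance_fraction(
    edis: Iterable[float], rfd: ReferenceDose, edi_units: str = "ug/kg-bw/day"
) -> float:
    """Fraction of exposure estimates whose HQ is at/above 1."""
    edis = np.asarray(list(edis) if not isinstance(edis, np.ndarray) else edis)
    if edis.size == 0:
        raise ValueError("no exposure estimates")
    hq = hazard_quotient(edis, rfd, edi_units=edi_units)
    return float(np.mean(np.asarray(hq) >= 1.0))


def risk_table(
    edi: pd.DataFrame, reference_doses: Mapping[str, ReferenceDose] | None = None
) -> pd.DataFrame:
    """Per-subject HQs (wide by analyte) plus the paraben HI.

    Input is the tidy per subject × analyte EDI table from
    :func:`biomonrisk.dosimetry.edi_table`.
    """
    doses = dict(reference_doses or DEFAULT_REFERENCE_DOSES)
    missing = set(edi["analyte_id"]) - set(doses)
    if missing:
        raise KeyError(f"no reference dose for analyte(s): {sorted(missing)}")
    wide = edi.pivot_table(index="subject_id", columns="analyte_id", values="edi")
    out = pd.DataFrame(index=wide.index)
    for a in wide.columns:
        out[f"HQ_{a}"] = hazard_quotient(wide[a].to_numpy(), doses[a])
    if all(f"HQ_{a}" in out for a in surveydata.PARABENS):
        out["HI_parabens"] = hazard_index(
            {a: out[f"HQ_{a}"].to_numpy() for a in surveydata.PARABENS}
        )
        out["exceeds"] = (
            out[[c for c in out.columns if c.startswith("HQ_")]].ge(1.0).any(axis=1)
            | (out["HI_parabens"] >= 1.0)
        )
    return out.reset_index()
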