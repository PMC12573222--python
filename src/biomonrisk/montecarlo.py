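"""Distribution fitting and seeded Monte Carlo probabilistic risk.

The probabilistic layer mirrors single-loop Monte Carlo risk software:
candidate parametric families (normal, lognormal, gamma, Weibull) are
fitted by maximum likelihood, the best family is selected by the
smallest Kolmogorov–Smirnov statistic, and 10,000 seeded draws propagate
exposure variability — urinary concentration (UE), daily creatinine
excretion (CE, computed from sampled anthropometry), and body weight —
through the dose equation EDI = UE × CE / (F_UE × BW) into hazard
quotient / hazard index distributions.

When only printed percentile summaries of EDI are available (no raw
data), :func:`fit_lognormal_from_quantiles` recovers lognormal
parameters by least squares of log-quantiles on standard-normal scores,
and the simulation can draw EDI directly from that fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import creatinine_excretion, estimate_daily_intake
from .risk import ReferenceDose, hazard_index, hazard_quotient
from . import surveydata

__all__ = [
    "FittedDistribution",
    "MonteCarloResult",
    "fit_best_distribution",
    "fit_lognormal_from_quantiles",
    "monte_carlo_edi",
    "monte_carlo_from_edi_distribution",
    "probabilistic_risk_summary",
]

_FAMILIES: Mapping[str, stats.rv_continuous] = {
    "normal": stats.norm,
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
    "weibull": stats.weibull_min,
}
#: positive-support families are fitted with location pinned at zero
_POSITIVE = {"lognormal", "gamma", "weibull"}

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class FittedDistribution:
    """One ML-fitted candidate family with its K-S goodness of fit."""

    family: str
    params: tuple[float, ...]
    ks_statistic: float
    ks_p: float

    def frozen(self) -> stats.rv_continuous:
        return _FAMILIES[self.family](*self.params)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.frozen().rvs(size=size, random_state=rng)

    @classmethod
    def lognormal(cls, log_mean: float, log_sd: float) -> "FittedDistribution":
        """Lognormal from log-scale parameters (scipy shape/loc/scale)."""
        if log_sd <= 0:
            raise ValueError("log-scale SD must be positive")
        return cls(
            family="lognormal",
            params=(log_sd, 0.0, float(np.exp(log_mean))),
            ks_statistic=float("nan"),
            ks_p=float("nan"),
        )


@dataclass
class MonteCarloResult:
    """Draws and summaries from one Monte Carlo exposure simulation."""

    analyte_id: str
    age_group: str
    iterations: int
    edi_draws: np.ndarray
    seed: int
    resampled_bw: int = 0
    hq_draws: np.ndarray | None = None
    hi_draws: np.ndarray | None = None
    percentile_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.edi_draws) != self.iterations:
            raise ValueError("draw count does not match requested iterations")


def fit_best_distribution(
    values, families: Sequence[str] = ("normal", "lognormal", "gamma", "weibull")
) -> FittedDistribution:
    """ML-fit each candidate family; return the smallest-K-S one.

    Positive-support families pin the location at zero so the fit is the
    two-parameter form practitioners expect. Selection is invariant to
    the ordering of the input sample.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(values) == 0:
        raise ValueError("degenerate (constant) sample")
    unknown = set(families) - set(_FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    best: FittedDistribution | None = None
    errors = []
    for fam in families:
        dist = _FAMILIES[fam]
        try:
            if fam in _POSITIVE:
                if np.any(values <= 0):
                    raise ValueError("positive-support family on non-positive data")
                params = dist.fit(values, floc=0.0)
            else:
                params = dist.fit(values)
            ks = stats.kstest(values, dist.name, args=params)
        except Exception as exc:  # keep trying the remaining families
            errors.append(f"{fam}: {exc}")
            continue
        cand = FittedDistribution(
            family=fam,
            params=tuple(float(p) for p in params),
            ks_statistic=float(ks.statistic),
            ks_p=float(ks.pvalue),
        )
        if best is None or cand.ks_statistic < best.ks_statistic:
            best = cand
    if best is None:
        raise RuntimeError("all candidate fits failed: " + "; ".join(errors))
    return best


def fit_lognormal_from_quantiles(quantiles: Mapping[float, float]) -> tuple[float, float]:
    """Lognormal (log-mean, log-sd) from printed {probability: value} pairs.

    Ordinary least squares of ln(value) on the standard-normal score
    Φ⁻¹(p); the slope is the log-sd and the intercept the log-mean. At
    least two distinct probabilities are required and the values must
    increase with p.
    """
    if len(quantiles) < 2:
        raise ValueError("need at least two quantile points")
    probs = np.asarray(sorted(quantiles), dtype=float)
    vals = np.asarray([quantiles[p] for p in probs], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("quantile values must be positive")
    if np.any(np.diff(vals) <= 0):
        raise ValueError("quantile values must increase with probability")
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probabilities must lie in (0, 1)")
    z = stats.norm.ppf(probs)
    sigma, mu = np.polyfit(z, np.log(vals), 1)
    return float(mu), float(sigma)


def monte_carlo_edi(
    ue_dist: FittedDistribution,
    population_sampler: Callable[[int, np.random.Generator], pd.DataFrame],
    f_ue: float,
    iterations: int = 10_000,
    seed: int = 0,
    analyte_id: str = "",
    age_group: str = "",
) -> MonteCarloResult:
    """Single-loop Monte Carlo of the dose equation.

    Per iteration: draw UE (µg/g-cre.) from the fitted distribution and
    an (age, sex, body_weight, height) tuple from ``population_sampler``;
    compute CE from the Mage equations and then the EDI. Non-positive UE
    or body-weight draws are resampled (truncation at zero); the number
    of resampled anthropometry rows is recorded.
    """
    if iterations < 1000:
        raise ValueError("use at least 1,000 iterations")
    rng = np.random.default_rng(seed)
    ue = ue_dist.sample(iterations, rng)
    tries = 0
    while np.any(ue <= 0):
        bad = ue <= 0
        ue[bad] = ue_dist.sample(int(bad.sum()), rng)
        tries += 1
        if tries > 1000:
            raise RuntimeError("UE distribution has no positive mass")
    anthro = population_sampler(iterations, rng).reset_index(drop=True)
    resampled = 0
    bad = (anthro["body_weight"].to_numpy() <= 0) | (anthro["height"].to_numpy() <= 0)
    while bad.any():
        resampled += int(bad.sum())
        redraw = population_sampler(int(bad.sum()), rng).reset_index(drop=True)
        anthro.loc[bad, ["age", "sex", "body_weight", "height"]] = redraw[
            ["age", "sex", "body_weight", "height"]
        ].to_numpy()
        bad = (anthro["body_weight"].to_numpy() <= 0) | (
            anthro["height"].to_numpy() <= 0
        )
    ce = creatinine_excretion(
        anthro["age"].to_numpy(),
        anthro["sex"].to_numpy(),
        anthro["body_weight"].to_numpy(),
        anthro["height"].to_numpy(),
    )
    edi = estimate_daily_intake(ue, ce, f_ue, anthro["body_weight"].to_numpy())
    return MonteCarloResult(
        analyte_id=analyte_id,
        age_group=age_group,
        iterations=iterations,
        edi_draws=np.asarray(edi, dtype=float),
        seed=seed,
        resampled_bw=resampled,
    )


def monte_carlo_from_edi_distribution(
    edi_dist: FittedDistribution,
    iterations: int = 10_000,
    seed: int = 0,
    analyte_id: str = "",
    age_group: str = "",
) -> MonteCarloResult:
    """Draw EDI directly from a fitted distribution (summary-statistics mode).

    Used when the exposure distribution itself was parameterized from
    printed percentiles rather than rebuilt from UE/CE/BW components.
    """
    if iterations < 1000:
        raise ValueError("use at least 1,000 iterations")
    rng = np.random.default_rng(seed)
    draws = edi_dist.sample(iterations, rng)
    return MonteCarloResult(
        analyte_id=analyte_id,
        age_group=age_group,
        iterations=iterations,
        edi_draws=np.asarray(draws, dtype=float),
        seed=seed,
    )


def probabilistic_risk_summary(
    results: MonteCarloResult | Sequence[MonteCarloResult],
    reference_doses: Mapping[str, ReferenceDose],
) -> pd.DataFrame:
    """HQ (and paraben HI where possible) percentiles and exceedance.

    One row per analyte (plus an ``HI_parabens`` row when results for
    all three parabens of one age group are supplied), with the P5–P95
    percentiles of the draw distribution and the fraction of draws at or
    above the reference dose (HQ ≥ 1).
    """
    if isinstance(results, MonteCarloResult):
        results = [results]
    if not results:
        raise ValueError("no Monte Carlo results supplied")
    rows = []
    hq_by_analyte: dict[str, np.ndarray] = {}
    for res in results:
        if res.analyte_id not in reference_doses:
            raise KeyError(f"no reference dose for analyte {res.analyte_id!r}")
        hq = hazard_quotient(res.edi_draws, reference_doses[res.analyte_id])
        res.hq_draws = hq
        hq_by_analyte[res.analyte_id] = hq
        pct = {f"p{p}": float(np.percentile(hq, p)) for p in PERCENTILES}
        res.percentile_summary = pct
        rows.append(
            {
                "quantity": f"HQ_{res.analyte_id}",
                "age_group": res.age_group,
                **pct,
                "exceedance": float(np.mean(hq >= 1.0)),
            }
        )
    if set(surveydata.PARABENS) <= set(hq_by_analyte):
        hi = hazard_index({a: hq_by_analyte[a] for a in surveydata.PARABENS})
        pct = {f"p{p}": float(np.percentile(hi, p)) for p in PERCENTILES}
        rows.append(
            {
                "quantity": "HI_parabens",
                "age_group": results[0].age_group,
                **pct,
                "exceedance": float(np.mean(hi >= 1.0)),
            }
        )
    return pd.DataFrame(rows)
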