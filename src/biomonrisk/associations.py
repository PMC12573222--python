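"""Diet → biomarker association layers.

Three layers of increasing adjustment, run per analyte within each age
stratum:

1. Spearman rank screening of each food group against the
   creatinine-adjusted concentration;
2. mutually adjusted multiple linear regression of the untransformed
   concentration on the screened food groups plus sex;
3. g-computation: an outcome model of the natural-log concentration on
   all 12 food groups plus sex, used to predict every subject's outcome
   under the observed diet and under a counterfactual intake of the
   target group (zero intake by default; P75-vs-P25 and +100 g/day
   shifts are available), averaged on the back-transformed scale into a
   population-average percent change with a subject-level bootstrap
   percentile CI and a CI-inversion p-value.

Signed effect weights summarize a family of g-computation effects as
each group's share of the total absolute effect, carrying its sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .surveydata import FOOD_GROUPS

__all__ = [
    "AssociationResult",
    "GCompEffect",
    "spearman_matrix",
    "mlr_food_groups",
    "gcomputation_effect",
    "effect_weights",
    "benjamini_hochberg",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH false-discovery-rate adjusted p-values (reported alongside raw p)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


@dataclass(frozen=True)
class AssociationResult:
    """One association estimate (rho or regression β) with inference."""

    analyte_id: str
    food_group: str
    age_group: str
    estimate: float
    p_value: float
    method: str
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class GCompEffect:
    """Population-average percent-change effect of one food group."""

    analyte_id: str
    food_group: str
    age_group: str
    percent_change: float
    ci_low: float
    ci_high: float
    p_value: float
    contrast: str
    n_boot: int
    weight: float = float("nan")


def spearman_matrix(
    adjusted: pd.DataFrame,
    intakes: pd.DataFrame,
    analyte_id: str,
    age_group: str = "all",
    food_groups: Sequence[str] = FOOD_GROUPS,
) -> list[AssociationResult]:
    """Spearman rank correlation of one analyte against each food group.

    ``adjusted`` is the tidy processed-measurement table (subject_id,
    analyte_id, adjusted); ``intakes`` is wide by food group. Requires
    at least 10 complete pairs; constant columns are rejected.
    """
    sub = adjusted.loc[adjusted["analyte_id"] == analyte_id]
    merged = sub.merge(intakes, on="subject_id")
    results = []
    for fg in food_groups:
        pair = merged[["adjusted", fg]].dropna()
        if len(pair) < 10:
            raise ValueError(f"{fg}: fewer than 10 complete pairs")
        x = pair[fg].to_numpy(float)
        y = pair["adjusted"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"{fg}: constant column")
        rho, p = stats.spearmanr(x, y)
        results.append(
            AssociationResult(
                analyte_id=analyte_id,
                food_group=fg,
                age_group=age_group,
                estimate=float(rho),
                p_value=float(p),
                method="spearman",
            )
        )
    return results


def _design(
    merged: pd.DataFrame, food_groups: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols = list(food_groups)
    x = merged[cols].to_numpy(float)
    sex = (merged["sex"].to_numpy() == "male").astype(float)
    design = np.column_stack([np.ones(len(merged)), x, sex])
    return design, ["const", *cols, "sex_male"]


def mlr_food_groups(
    adjusted: pd.DataFrame,
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    analyte_id: str,
    food_groups: Sequence[str],
    age_group: str = "all",
) -> tuple[list[AssociationResult], dict]:
    """Mutually adjusted linear regression of one analyte on food groups + sex.

    The food groups entered are typically those flagged by the Spearman
    screen. Returns per-group β with 95% CI and p, plus a fit dict with
    multiple R and R². Rank-deficient designs are rejected with the
    offending columns named.
    """
    sub = adjusted.loc[adjusted["analyte_id"] == analyte_id]
    merged = sub.merge(intakes, on="subject_id").merge(
        participants[["subject_id", "sex"]], on="subject_id"
    )
    design, names = _design(merged, food_groups)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns not adding rank, scanning left to right
        bad = []
        kept = design[:, [0]]
        for j in range(1, design.shape[1]):
            trial = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = trial
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    model = sm.OLS(merged["adjusted"].to_numpy(float), design).fit()
    ci = model.conf_int(alpha=0.05)
    results = []
    for j, name in enumerate(names):
        if name in ("const", "sex_male"):
            continue
        results.append(
            AssociationResult(
                analyte_id=analyte_id,
                food_group=name,
                age_group=age_group,
                estimate=float(model.params[j]),
                p_value=float(model.pvalues[j]),
                ci_low=float(ci[j, 0]),
                ci_high=float(ci[j, 1]),
                method="mlr",
            )
        )
    fit = {
        "r_squared": float(model.rsquared),
        "multiple_r": float(np.sqrt(model.rsquared)),
        "n": int(model.nobs),
    }
    return results, fit


def _counterfactual_intake(
    x: np.ndarray, target_col: int, contrast: str
) -> tuple[np.ndarray, np.ndarray]:
    """(intake under scenario a, under scenario b) for the target column."""
    obs = x[:, target_col]
    if contrast == "observed_vs_zero":
        return obs, np.zeros_like(obs)
    if contrast == "p75_vs_p25":
        return (
            np.full_like(obs, np.percentile(obs, 75)),
            np.full_like(obs, np.percentile(obs, 25)),
        )
    if contrast == "plus_100g":
        return obs + 100.0, obs
    raise ValueError(f"unknown contrast {contrast!r}")


def gcomputation_effect(
    adjusted: pd.DataFrame,
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    analyte_id: str,
    target_group: str,
    age_group: str = "all",
    food_groups: Sequence[str] = FOOD_GROUPS,
    contrast: str = "observed_vs_zero",
    n_boot: int = 1000,
    seed: int = 0,
) -> GCompEffect:
    """Population-average percent change in one analyte for one food group.

    Fits ln(adjusted) ~ all food groups + sex, standardizes over the
    empirical covariate distribution under the two intake scenarios of
    the contrast, and reports 100 × (mean_a / mean_b − 1) on the
    back-transformed scale, with a subject-resampling bootstrap
    percentile CI and a p-value by CI inversion. Deterministic given
    the seed.
    """
    if target_group not in food_groups:
        raise ValueError(f"target {target_group!r} not among the food groups")
    if n_boot < 200:
        raise ValueError("use at least 200 bootstrap replicates")
    sub = adjusted.loc[adjusted["analyte_id"] == analyte_id]
    merged = sub.merge(intakes, on="subject_id").merge(
        participants[["subject_id", "sex"]], on="subject_id"
    )
    n = len(merged)
    if n < 30:
        raise ValueError("need at least 30 subjects")
    y = np.log(merged["adjusted"].to_numpy(float))
    design, names = _design(merged, food_groups)
    t_col = names.index(target_group)

    x_a, x_b = _counterfactual_intake(design[:, 1:-1].copy(), t_col - 1, contrast)
    if contrast == "plus_100g":
        obs_max = design[:, t_col].max()
        if np.any(x_a > obs_max):
            import warnings

            warnings.warn(
                f"{target_group}: counterfactual intake outside observed support "
                "(extrapolation)",
                stacklevel=2,
            )

    def estimate(idx: np.ndarray) -> float:
        d = design[idx]
        beta, *_ = np.linalg.lstsq(d, y[idx], rcond=None)
        d_a = d.copy()
        d_b = d.copy()
        d_a[:, t_col] = x_a[idx]
        d_b[:, t_col] = x_b[idx]
        mean_a = np.mean(np.exp(d_a @ beta))
        mean_b = np.mean(np.exp(d_b @ beta))
        return 100.0 * (mean_a / mean_b - 1.0)

    all_idx = np.arange(n)
    point = estimate(all_idx)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = estimate(rng.integers(0, n, size=n))
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    # CI-inversion p: twice the smaller tail mass of the bootstrap
    # distribution relative to the null value 0.
    tail = min(np.mean(boots <= 0.0), np.mean(boots >= 0.0))
    p = float(min(1.0, 2.0 * tail))
    return GCompEffect(
        analyte_id=analyte_id,
        food_group=target_group,
        age_group=age_group,
        percent_change=float(point),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        contrast=contrast,
        n_boot=n_boot,
    )


def effect_weights(effects: Sequence[GCompEffect]) -> list[GCompEffect]:
    """Signed share of the total absolute effect for each food group.

    weight_j = |effect_j| / Σ_k |effect_k|, carrying the sign of the
    effect; absolute weights sum to 1. All-zero effect sets are
    undefined and rejected.
    """
    if not effects:
        raise ValueError("no effects supplied")
    total = sum(abs(e.percent_change) for e in effects)
    if total == 0:
        raise ValueError("all effects are zero; weights are undefined")
    out = []
    for e in effects:
        w = abs(e.percent_change) / total * np.sign(e.percent_change)
        out.append(
            GCompEffect(
                analyte_id=e.analyte_id,
                food_group=e.food_group,
                age_group=e.age_group,
                percent_change=e.percent_change,
                ci_low=e.ci_low,
                ci_high=e.ci_high,
                p_value=e.p_value,
                contrast=e.contrast,
                n_boot=e.n_boot,
                weight=float(w),
            )
        )
    return out
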