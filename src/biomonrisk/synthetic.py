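"""Synthetic NAHSIT-like population generator.

Individual-level data from the survey are not deposited, so downstream
stages (censoring handling, reverse dosimetry, risk characterization,
dietary association) are exercised on synthetic populations whose
marginal structure matches the printed summaries:

* four age strata (6–11, 12–18, 19–64, ≥65 y) with sizes 189/230/137/150
  and a near-equal sex ratio;
* per-stratum creatinine-adjusted analyte medians, with residual
  geometric SDs calibrated so that the fraction of raw concentrations
  falling below the analytical LOD reproduces the published detection
  rates (censoring oracle: detection = Σ_s w_s Φ((ln GM_s·cre_GM − ln
  LOD)/σ_tot));
* zero-inflated lognormal 24-h recall intakes fitted to the published
  per-stratum median/mean/SD of each of the 12 food groups;
* an optional log-linear diet → biomarker dependence (coefficient per
  100 g/day on the natural-log concentration scale) with closed-form
  ground truth, so association estimators can be validated against
  known effects.

All draws are routed through one :class:`numpy.random.Generator`, so a
given (spec, seed) pair is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import surveydata

__all__ = [
    "AnalyteSpec",
    "FoodGroupSpec",
    "StratumSpec",
    "PopulationSpec",
    "default_population_spec",
    "generate_population",
    "generate_intakes",
    "generate_biomarkers",
    "fit_zero_inflated_lognormal",
    "solve_residual_sigma",
]


@dataclass
class AnalyteSpec:
    """One urinary analyte: detection limits and lognormal concentration model.

    ``geometric_mean`` is the whole-population geometric mean on the
    creatinine-adjusted scale (µg/g-cre.); ``stratum_geometric_mean``
    optionally overrides it per age group. ``geometric_sd`` is the
    residual geometric SD of the creatinine-adjusted concentration
    (dimensionless, > 1).
    """

    analyte_id: str
    lod: float
    loq: float
    geometric_mean: float
    geometric_sd: float
    stratum_geometric_mean: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.lod < self.loq:
            raise ValueError(f"{self.analyte_id}: LOD must be below LOQ")
        if self.geometric_mean <= 0:
            raise ValueError(f"{self.analyte_id}: geometric mean must be positive")
        if self.geometric_sd <= 1:
            raise ValueError(f"{self.analyte_id}: geometric SD must exceed 1")

    def gm_for(self, age_group: str) -> float:
        if self.stratum_geometric_mean is not None:
            return self.stratum_geometric_mean[age_group]
        return self.geometric_mean


@dataclass
class FoodGroupSpec:
    """Zero-inflated lognormal intake model for one food group.

    Each field maps age group → parameter: probability of any consumption
    in the recall day, and the log-scale mean/SD of the consumer intake
    distribution (log g/day).
    """

    group_id: str
    consumption_probability: Mapping[str, float]
    intake_log_mean: Mapping[str, float]
    intake_log_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, p in self.consumption_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"{self.group_id}/{g}: consumption probability {p} outside [0, 1]"
                )
        for g, s in self.intake_log_sd.items():
            if s < 0:
                raise ValueError(f"{self.group_id}/{g}: negative intake log-sd")


@dataclass
class StratumSpec:
    """Demographic parameters for one age stratum."""

    name: str
    n: int
    age_range: tuple[float, float]
    bw_mean: float
    bw_sd: float
    ht_mean: float
    ht_sd: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"stratum {self.name}: sample size must be positive")
        if self.bw_sd < 0 or self.ht_sd < 0:
            raise ValueError(f"stratum {self.name}: negative SD")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"stratum {self.name}: empty age range")


@dataclass
class PopulationSpec:
    """Full description of a synthetic study population."""

    strata: Sequence[StratumSpec]
    sex_ratio_male: float
    analytes: Sequence[AnalyteSpec]
    food_groups: Sequence[FoodGroupSpec]
    #: {(food_group_id, analyte_id): coefficient} on the natural-log
    #: concentration scale per 100 g/day of intake.
    diet_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    creatinine_gm: float = 1.0  # g/L
    creatinine_gsd: float = 1.8
    bw_ht_corr: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sex_ratio_male <= 1.0:
            raise ValueError("sex ratio must lie in [0, 1]")
        if self.creatinine_gm <= 0 or self.creatinine_gsd <= 1:
            raise ValueError("creatinine GM must be > 0 and GSD > 1")
        if not -1.0 < self.bw_ht_corr < 1.0:
            raise ValueError("bw/ht correlation must lie in (-1, 1)")
        names = [s.name for s in self.strata]
        if len(set(names)) != len(names):
            raise ValueError("duplicate stratum names")
        spans = sorted(s.age_range for s in self.strata)
        for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError("overlapping stratum age ranges")

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.strata)

    def analyte(self, analyte_id: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.analyte_id == analyte_id:
                return a
        raise KeyError(analyte_id)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diet_effects"] = [
            {"food_group": fg, "analyte": an, "coefficient": float(c)}
            for (fg, an), c in self.diet_effects.items()
        ]
        for s in d["strata"]:
            s["age_range"] = list(s["age_range"])  # YAML has no tuples
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationSpec":
        strata = [
            StratumSpec(**{**s, "age_range": tuple(s["age_range"])})
            for s in d["strata"]
        ]
        analytes = [AnalyteSpec(**a) for a in d["analytes"]]
        food_groups = [FoodGroupSpec(**f) for f in d["food_groups"]]
        effects = {
            (e["food_group"], e["analyte"]): float(e["coefficient"])
            for e in d.get("diet_effects", [])
        }
        return cls(
            strata=strata,
            sex_ratio_male=d["sex_ratio_male"],
            analytes=analytes,
            food_groups=food_groups,
            diet_effects=effects,
            creatinine_gm=d.get("creatinine_gm", 1.0),
            creatinine_gsd=d.get("creatinine_gsd", 1.8),
            bw_ht_corr=d.get("bw_ht_corr", 0.6),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def fit_zero_inflated_lognormal(
    median: float, mean: float, sd: float, nonconsumer_probability: float = 0.6
) -> tuple[float, float, float]:
    """Fit (p, log-mean, log-sd) of a zero-inflated lognormal to summary stats.

    With a zero median the consumption probability is unidentified from
    (median, mean, SD) alone; ``1 - nonconsumer_probability`` is used and
    the consumer lognormal is matched to the implied consumer mean and
    variance by moments. With a positive median, most subjects consume
    (p = 0.97) and the consumer distribution is matched to the mixture
    median and the mean, which the downstream checks care about most.
    """
    if median < 0 or mean <= 0 or sd < 0:
        raise ValueError("summary statistics must be non-negative with mean > 0")
    if median == 0.0:
        p = 1.0 - nonconsumer_probability
        mean_c = mean / p
        second_moment_c = (mean**2 + sd**2) / p
        var_c = second_moment_c - mean_c**2
        if var_c <= 0:
            sigma = 0.5
        else:
            sigma = float(np.sqrt(np.log1p(var_c / mean_c**2)))
        mu = float(np.log(mean_c) - sigma**2 / 2)
        return p, mu, sigma
    p = 0.97
    # Mixture median m solves F_consumer(m) = 1 - 0.5/p.
    z_q = float(stats.norm.ppf(1.0 - 0.5 / p))
    c = float(np.log(mean / (p * median)))
    if c <= 0:  # mean at or below (scaled) median: fall back to a tight spread
        sigma = 0.25
    else:
        sigma = z_q + float(np.sqrt(z_q**2 + 2.0 * c))
    mu = float(np.log(median) - sigma * z_q)
    return p, mu, sigma


def solve_residual_sigma(
    stratum_gms: Mapping[str, float],
    weights: Mapping[str, float],
    lod: float,
    detection_rate: float,
    creatinine_gm: float = 1.0,
    creatinine_gsd: float = 1.8,
) -> float:
    """Residual log-sd reproducing a target detection rate under censoring.

    The raw (unadjusted) concentration is the creatinine-adjusted
    lognormal times an independent lognormal creatinine, so its log-SD is
    sqrt(σ_a² + ln(GSD_cre)²). The detection rate of the stratum mixture,

        Σ_s w_s Φ((ln(GM_s · cre_GM) − ln LOD) / σ_total),

    is inverted for σ_total by bisection; the analyte residual σ_a is
    returned. Requires every stratum GM above the LOD (detection > 0.5).
    """
    w = np.asarray([weights[g] for g in stratum_gms], dtype=float)
    w = w / w.sum()
    log_ratio = np.log(
        np.asarray([gm * creatinine_gm for gm in stratum_gms.values()]) / lod
    )
    if np.any(log_ratio <= 0):
        raise ValueError("every stratum geometric mean must exceed the LOD")

    def mixture_detection(sigma_total: float) -> float:
        return float(w @ stats.norm.cdf(log_ratio / sigma_total))

    if not 0.5 < detection_rate < 1.0:
        raise ValueError("target detection rate must lie in (0.5, 1)")
    f = lambda s: mixture_detection(s) - detection_rate
    sigma_total = optimize.brentq(f, 1e-3, 60.0, xtol=1e-10)
    sigma_cre = np.log(creatinine_gsd)
    if sigma_total <= sigma_cre:
        raise ValueError("creatinine variability alone exceeds the implied spread")
    return float(np.sqrt(sigma_total**2 - sigma_cre**2))


def default_population_spec(seed: int = 0) -> PopulationSpec:
    """Population spec emulating the published survey structure.

    Group sizes 189/230/137/150, sex ratio ≈ 0.5, per-stratum analyte
    geometric means set to the printed per-stratum medians (population
    ``geometric_mean`` set to the printed whole-population medians), and
    residual geometric SDs solved from the published detection rates via
    the censoring oracle. Diet effects default to zero (null structure).
    """
    strata = [
        StratumSpec(
            name=g,
            n=surveydata.GROUP_SIZES[g],
            age_range=surveydata.AGE_RANGES[g],
            bw_mean=surveydata.ANTHROPOMETRY[g][0],
            bw_sd=surveydata.ANTHROPOMETRY[g][1],
            ht_mean=surveydata.ANTHROPOMETRY[g][2],
            ht_sd=surveydata.ANTHROPOMETRY[g][3],
        )
        for g in surveydata.AGE_GROUPS
    ]
    weights = {g: surveydata.GROUP_SIZES[g] for g in surveydata.AGE_GROUPS}
    analytes = []
    for a in surveydata.ANALYTES:
        gms = dict(surveydata.STRATUM_MEDIANS[a])
        sigma = solve_residual_sigma(
            gms,
            weights,
            lod=surveydata.LOD[a],
            detection_rate=surveydata.DETECTION_RATES[a],
        )
        analytes.append(
            AnalyteSpec(
                analyte_id=a,
                lod=surveydata.LOD[a],
                loq=surveydata.LOQ[a],
                geometric_mean=surveydata.POPULATION_MEDIANS[a],
                geometric_sd=float(np.exp(sigma)),
                stratum_geometric_mean=gms,
            )
        )
    food_groups = []
    for fg in surveydata.FOOD_GROUPS:
        probs, mus, sds = {}, {}, {}
        for g in surveydata.AGE_GROUPS:
            median, mean, sd = surveydata.DIETARY_RECALL[fg][g]
            p, mu, s = fit_zero_inflated_lognormal(median, mean, sd)
            probs[g], mus[g], sds[g] = p, mu, s
        food_groups.append(
            FoodGroupSpec(
                group_id=fg,
                consumption_probability=probs,
                intake_log_mean=mus,
                intake_log_sd=sds,
            )
        )
    return PopulationSpec(
        strata=strata,
        sex_ratio_male=surveydata.SEX_RATIO_MALE,
        analytes=analytes,
        food_groups=food_groups,
        seed=seed,
    )


def _truncated_bivariate(
    rng: np.random.Generator,
    n: int,
    means: tuple[float, float],
    sds: tuple[float, float],
    corr: float,
) -> np.ndarray:
    """Positive-support bivariate normal draws (resampling negative rows)."""
    cov = np.array(
        [
            [sds[0] ** 2, corr * sds[0] * sds[1]],
            [corr * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    out = rng.multivariate_normal(means, cov, size=n)
    bad = (out <= 0).any(axis=1)
    while bad.any():
        out[bad] = rng.multivariate_normal(means, cov, size=int(bad.sum()))
        bad = (out <= 0).any(axis=1)
    return out


def generate_population(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Draw one subject table from the spec.

    Ages are uniform within each stratum; body weight and height are
    jointly normal (truncated positive) with the spec's correlation.
    Columns: subject_id, age_group, age, sex, body_weight, height.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for stratum in spec.strata:
        ages = rng.uniform(*stratum.age_range, size=stratum.n)
        sexes = np.where(rng.random(stratum.n) < spec.sex_ratio_male, "male", "female")
        bw_ht = _truncated_bivariate(
            rng,
            stratum.n,
            (stratum.bw_mean, stratum.ht_mean),
            (stratum.bw_sd, stratum.ht_sd),
            spec.bw_ht_corr,
        )
        for i in range(stratum.n):
            counter += 1
            rows.append(
                {
                    "subject_id": f"S{counter:04d}",
                    "age_group": stratum.name,
                    "age": float(ages[i]),
                    "sex": sexes[i],
                    "body_weight": float(bw_ht[i, 0]),
                    "height": float(bw_ht[i, 1]),
                }
            )
    return pd.DataFrame(rows)


def generate_intakes(
    participants: pd.DataFrame, spec: PopulationSpec, seed: int
) -> pd.DataFrame:
    """Zero-inflated lognormal 24-h recall intakes, one column per food group."""
    rng = np.random.default_rng(seed)
    out = participants[["subject_id", "age_group"]].copy()
    for fg in spec.food_groups:
        values = np.zeros(len(out))
        for g, idx in out.groupby("age_group", sort=False).groups.items():
            p = fg.consumption_probability[g]
            mu = fg.intake_log_mean[g]
            sd = fg.intake_log_sd[g]
            m = len(idx)
            consumes = rng.random(m) < p
            draws = np.exp(mu + sd * rng.standard_normal(m))
            values[out.index.get_indexer(idx)] = np.where(consumes, draws, 0.0)
        out[fg.group_id] = values
    return out.drop(columns="age_group")


def generate_biomarkers(
    participants: pd.DataFrame,
    spec: PopulationSpec,
    intakes: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Censored-lognormal urinary concentrations with optional diet effects.

    For each analyte the creatinine-adjusted log-concentration is

        ln C_adj = ln GM_stratum + Σ_j β_j · intake_j / 100 + σ_a · Z,

    the raw concentration is C_adj × creatinine (one lognormal creatinine
    draw per subject, shared across analytes), and the censored flag marks
    raw values below the LOD; the raw value itself is retained.
    """
    if set(participants["subject_id"]) != set(intakes["subject_id"]):
        raise ValueError("participants and intakes carry different subject ids")
    merged = participants.merge(intakes, on="subject_id", validate="1:1")
    n = len(merged)
    rng = np.random.default_rng(seed)
    sigma_cre = np.log(spec.creatinine_gsd)
    creatinine = np.exp(
        np.log(spec.creatinine_gm) + sigma_cre * rng.standard_normal(n)
    )
    frames = []
    for analyte in spec.analytes:
        log_gm = np.log(
            merged["age_group"].map(lambda g: analyte.gm_for(g)).to_numpy(float)
        )
        shift = np.zeros(n)
        for (fg_id, an_id), coef in spec.diet_effects.items():
            if an_id == analyte.analyte_id and coef != 0.0:
                shift += coef * merged[fg_id].to_numpy(float) / 100.0
        sigma_a = np.log(analyte.geometric_sd)
        adjusted = np.exp(log_gm + shift + sigma_a * rng.standard_normal(n))
        raw = adjusted * creatinine
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": merged["subject_id"],
                    "analyte_id": analyte.analyte_id,
                    "raw_concentration": raw,
                    "lod": analyte.lod,
                    "loq": analyte.loq,
                    "creatinine": creatinine,
                    "censored": raw < analyte.lod,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
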