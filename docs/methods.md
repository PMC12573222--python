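# Methods

## Dose model

The package back-calculates external dose from spot-urine biomarkers
(reverse dosimetry). The creatinine-adjusted concentration UE
(µg/g-creatinine) is multiplied by the subject's predicted daily
creatinine excretion CE (g/day) to estimate the analyte mass excreted
per day, scaled by the urinary excretion fraction F_UE to a daily
ingested mass, and normalized by body weight:

    EDI = UE · CE / (F_UE · BW)     [µg/kg-bw/day]

CE comes from the Mage equations, which predict creatinine excretion
from age, sex, body weight and height. Adults (age ≥ 18, the boundary
assigned to the adult branch) use `k·(140−age)·BW^1.5·ht^0.5·1e-6`
(k = 1.93 male / 1.64 female); ages ≥ 140 are rejected because the
formula would change sign. Minor males use a piecewise-linear height
formula with slopes 0.0564 (ht < 168 cm) and 0.2550 (ht ≥ 168 cm); the
two branches agree exactly at 168 cm. Minor females use
`2.045·ht·exp(0.01552·(ht−90))·1e-3`. The minor formulas depend on
height only, as published; no interpolation is applied at the adult
boundary. F_UE defaults are MP 17.4%, EP 13.7%, PP 8.6%, BPA 100%
(fully excreted as the measured species). CE is emitted in g/day and
UE in µg/g so the EDI lands in µg/kg-bw/day without unit juggling.

Assumptions worth keeping in mind: steady-state excretion (a single
spot urine stands in for a daily average), complete first-pass
glucuronide deconjugation in the assay, and no pharmacokinetic
modelling beyond the single excretion fraction.

## Censoring and processing

Concentrations below the analytical LOD are substituted by LOD/2 on
the raw µg/L scale, *before* creatinine adjustment (the published order
is unstated; substituting first keeps the substitution on the scale on
which the LOD is defined). Values exactly at the LOD count as detected.
Quantiles in all summaries use linear interpolation between order
statistics. Between-stratum differences are tested with the
Kruskal–Wallis rank test (tie-corrected H, chi-square reference).

## Deterministic and probabilistic risk

HQ = EDI / reference dose, after converting both to the canonical
µg/kg-bw/day (reference doses are registered with their native units:
10 mg → 10,000 µg; 0.2 ng → 0.0002 µg). HQ or HI ≥ 1 (inclusive)
flags potential risk. The paraben hazard index is the dose-additive
sum over exactly MP, EP and PP; BPA is assessed against its own TDI
and rejected from the HI.

The Monte Carlo layer fits candidate families {normal, lognormal,
gamma, Weibull} by maximum likelihood (positive-support families with
location pinned at zero) and selects the smallest Kolmogorov–Smirnov
statistic. Per iteration it draws UE from the fitted distribution and
an (age, sex, BW, ht) tuple from a population sampler, computes CE
deterministically, and evaluates the dose equation; 10,000 iterations
by default, all randomness through one seeded generator. UE is drawn
independently of anthropometry — the variability sources are treated
as separate, so the physiological UE–BW coupling is deliberately
ignored. Non-positive body-weight draws are resampled (truncation at
zero) and counted in the result. When only printed percentile
summaries are available, a two-parameter lognormal is recovered by
ordinary least squares of log-quantiles on standard-normal scores and
EDI is drawn from it directly (`monte_carlo_from_edi_distribution`).

## Dietary associations

Three layers, run per analyte within each age stratum:

1. **Spearman screening** of each of the 12 food-group intakes against
   the creatinine-adjusted concentration (≥ 10 complete pairs,
   tie-handled, two-sided p).
2. **Mutually adjusted regression**: untransformed concentration on
   the Spearman-flagged food groups plus sex, jointly; β with 95% CI,
   p, and multiple R/R². Rank-deficient designs are rejected with the
   offending columns named. Coefficients are in µg/g-creatinine per
   g/day of cooked intake.
3. **G-computation**: the outcome model is ln(concentration) on all 12
   food groups plus sex, so effects are population-average percent
   changes. For the default contrast (observed intake vs zero intake
   of the target group) every subject's outcome is predicted under
   both scenarios and averaged on the back-transformed scale:
   percent change = 100·(mean_a/mean_b − 1). P75-vs-P25 and
   +100 g/day contrasts are available; counterfactuals outside the
   observed support trigger an extrapolation warning. Inference is a
   subject-level nonparametric bootstrap (1,000 replicates default,
   percentile CI, p by CI inversion). Raw p-values are reported as the
   primary inference, with a Benjamini–Hochberg column alongside.

Signed effect weights summarize a set of g-computation effects as
|effect_j| / Σ|effect_k| carrying the sign of effect_j; absolute
weights sum to 1 and the all-zero case is reported as undefined.

The plug-in percent-change estimator carries a small finite-sample
convexity bias (exponentiating a noisy coefficient over a heavy-tailed
intake); at the default study scale (n ≈ 700, effects within ±20%)
the median bias is well under 2 percentage points and bootstrap CI
coverage is near nominal, as the calibration suite verifies.

## Synthetic population generator

The generator emulates the survey's printed structure so that every
downstream stage is testable without the (undeposited) individual
data:

* **Demographics**: strata 6–11/12–18/19–64/≥65 years with sizes
  189/230/137/150, sex ratio 0.4986 male, ages uniform within
  stratum (the open elderly stratum capped at 90 y). Body weight and
  height are jointly normal per stratum (correlation 0.6, truncated
  positive); the survey reports only aggregate age and BMI, so the
  stratum means/SDs are physiologic stand-ins, flagged in the config.
* **Creatinine**: lognormal, GM 1.0 g/L, GSD 1.8 — a stand-in, since
  the survey reports the assay but not the distribution.
* **Intakes**: zero-inflated lognormal per food group per stratum,
  fitted to the printed median/mean/SD. Zero-median groups (poultry,
  alcohol) get consumption probability 0.4 and a moment-matched
  consumer lognormal; positive-median groups get p = 0.97 with the
  consumer distribution matched to the mixture median and the mean.
* **Concentrations**: the creatinine-adjusted log-concentration is
  ln GM_stratum + Σ_j β_j·intake_j/100 + σ·Z, with per-stratum GMs set
  to the published per-stratum medians. The raw concentration is the
  adjusted value times the (independent) creatinine draw; values below
  the LOD are flagged censored with the raw value retained. The
  residual σ per analyte is solved from the censoring oracle —
  detection = Σ_s w_s Φ((ln(GM_s·cre_GM) − ln LOD)/σ_total) equated to
  the published detection rates. Diet effects default to zero (null
  structure); injected effects have a closed-form percent-change
  ground truth, which the association suite exploits.

**Known limitation.** For EP and PP the published medians sit far
above the LOD while detection rates are only ~65–71%; under a single
lognormal this forces extremely large geometric SDs (EP ~10³,
PP ~10⁴). Real data are almost certainly a mixture (user vs non-user
subpopulations), so the synthetic tails are much heavier than reality:
synthetic paraben EDI maxima, and hence the upper tail of the paraben
HI, overshoot the published ranges. Passing tests therefore validate
the pipeline's arithmetic, calibration and estimator behaviour — not
the tail realism of paraben exposure. The desk-scale risk numbers are
computed from the published percentile summaries, not from the
synthetic tails.

## Problem sizes and numerical choices

The test suite exercises the generator at the survey scale (706
subjects) and the estimator-calibration suites at n = 700 with 50
seeds (recovery) and n = 200 with 1,000 simulations (null
calibration) — n = 200 being representative of the survey's stratum
sizes (137–230). Monte Carlo runs use 10,000 iterations in the
acceptance computations and 1,000 in pipeline smoke tests. K-S family
selection is validated at n = 5,000 over 100 replicates. Degenerate
inputs (constant samples, empty groups, rank-deficient designs,
non-positive creatinine) raise informative errors rather than
propagating NaNs. All stages derive their randomness from one master
seed via `numpy.random.SeedSequence`, so pipeline outputs are
byte-identical across re-runs of the same config.
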