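"""Monte Carlo BPA risk from published EDI percentile summaries.

Fits a lognormal to the printed per-age-group BPA EDI quartiles (least
squares of log-quantiles on standard-normal scores), draws 10,000
exposure samples per group, and reports the fraction exceeding the EFSA
TDI of 0.2 ng/kg-bw/day.
"""

from biomonrisk import montecarlo, risk
from biomonrisk.montecarlo import FittedDistribution
from biomonrisk.surveydata import AGE_GROUPS, EDI_SUMMARY

print(f"{'group':8} {'log-mean':>9} {'log-sd':>7} {'% > TDI':>8}")
for group in AGE_GROUPS:
    s = EDI_SUMMARY["BPA"][group]
    mu, sigma = montecarlo.fit_lognormal_from_quantiles(
        {0.25: s["p25"], 0.5: s["p50"], 0.75: s["p75"]}
    )
    res = montecarlo.monte_carlo_from_edi_distribution(
        FittedDistribution.lognormal(mu, sigma),
        iterations=10_000, seed=1, analyte_id="BPA", age_group=group,
    )
    out = montecarlo.probabilistic_risk_summary(res, risk.DEFAULT_REFERENCE_DOSES)
    print(f"{group:8} {mu:9.3f} {sigma:7.3f} {100 * out.exceedance.iloc[0]:8.2f}")
# Essentially the entire simulated population exceeds the 2023 EFSA TDI
# in every age group; the elderly group, with the lowest exposure, still
# exceeds it in ~98% of draws.
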