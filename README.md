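# biomonrisk

Urinary-biomarker reverse dosimetry and probabilistic health-risk
assessment for parabens (methyl-, ethyl-, propyl-) and bisphenol A
(BPA), with dietary-association analysis. The package is aimed at
exposure scientists and environmental epidemiologists working with
spot-urine biomonitoring data of the kind collected by nationwide
nutrition and health surveys (the synthetic generator emulates the
NAHSIT survey structure in Taiwan: four age strata 6–11, 12–18, 19–64
and ≥65 years, 706 subjects, 24-h dietary recall for 12 food groups).

## The model

Creatinine-adjusted urinary concentrations UE (µg/g-creatinine) are
converted to estimated daily intakes by reverse dosimetry:

```
EDI = UE · CE / (F_UE · BW)        [µg/kg-bw/day]
```

where CE (g/day) is daily creatinine excretion from the Mage
age/sex/anthropometry equations — adults: `k·(140−age)·BW^1.5·ht^0.5·1e-6`
with k = 1.93 (male) / 1.64 (female); minor males:
`ht·(6.265 + s·(ht−168))·1e-3` with s = 0.0564 below 168 cm and 0.2550
above; minor females: `2.045·ht·exp(0.01552·(ht−90))·1e-3` — and F_UE is
the urinary excretion fraction (MP 17.4%, EP 13.7%, PP 8.6%, BPA 100%).

Risk is characterized by hazard quotients HQ = EDI/RfD against the EFSA
group ADI (10 mg/kg-bw/day, MP and EP), the EMA ADI (1.25 mg/kg-bw/day,
PP) and the 2023 EFSA TDI for BPA (0.2 ng/kg-bw/day), with the
dose-additive paraben hazard index HI = HQ_MP + HQ_EP + HQ_PP. A
seeded Monte Carlo layer (K-S best-fit family selection, 10,000 draws)
propagates exposure variability into HQ/HI distributions. Dietary
associations run in three layers per age stratum: Spearman screening,
mutually adjusted multiple regression, and g-computation
population-average percent changes with bootstrap CIs and signed
effect weights.

Concentrations below the analytical LOD are substituted by LOD/2
before creatinine adjustment.

## Worked example

```python
import biomonrisk as b

spec = b.default_population_spec(seed=0)
participants = b.generate_population(spec, seed=1)
intakes = b.generate_intakes(participants, spec, seed=2)
biomarkers = b.generate_biomarkers(participants, spec, intakes, seed=3)

processed = b.process_measurements(biomarkers)      # LOD/2 + creatinine
edi = b.edi_table(participants, processed)          # reverse dosimetry
table = b.risk_table(edi)                           # HQ / HI
print(f"BPA HQ >= 1: {(table.HQ_BPA >= 1).mean():.1%}")
```

prints `BPA HQ >= 1: 99.9%`: virtually every simulated subject's
estimated BPA intake exceeds the 2023 EFSA TDI, while the median
paraben hazard index (`table.HI_parabens.median()` ≈ 0.01) sits two
orders of magnitude below the risk threshold of 1. The scripts in
`examples/` walk through each capability (synthetic generation,
dosimetry and risk, probabilistic BPA risk from published percentile
summaries, and recovery of an injected diet effect) and print the
numbers they compute. A thin CLI mirrors the pipeline stages:
`biomonrisk all --seed 1 --out run1`.

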