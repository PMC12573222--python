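"""Published summary statistics from the NAHSIT paraben/BPA biomonitoring survey.

The individual-level data of the Nutrition and Health Survey in Taiwan
(NAHSIT) are not publicly deposited, so this module collects the printed
summary statistics — demographic structure, analyte detection limits and
detection rates, per-age-group median concentrations, 24-h dietary recall
summaries, and the percentile distributions of estimated daily intake
(EDI) — that parameterize the synthetic-population generator and the
desk-scale risk computations.

Units
-----
* urinary concentrations: µg/L (ng/mL); creatinine-adjusted: µg/g-creatinine
* dietary intakes: cooked weight, g/day
* EDI: µg/kg body weight/day
"""

from __future__ import annotations

ANALYTES = ("MP", "EP", "PP", "BPA")
PARABENS = ("MP", "EP", "PP")

AGE_GROUPS = ("6-11", "12-18", "19-64", ">=65")

#: Enrolled participants per age stratum (total 706).
GROUP_SIZES = {"6-11": 189, "12-18": 230, "19-64": 137, ">=65": 150}

#: Age ranges (years, inclusive lower bound). The open-ended elderly
#: stratum is capped at 90 y for simulation purposes.
AGE_RANGES = {
    "6-11": (6.0, 12.0),
    "12-18": (12.0, 19.0),
    "19-64": (19.0, 65.0),
    ">=65": (65.0, 90.0),
}

#: Fraction male (352/706 printed).
SEX_RATIO_MALE = 0.4986

#: Analytical limits of detection / quantification, µg/L.
LOD = {"MP": 0.03, "EP": 0.02, "PP": 0.02, "BPA": 0.11}
LOQ = {"MP": 0.11, "EP": 0.06, "PP": 0.07, "BPA": 0.37}

#: Whole-population detection rates (fraction of samples at/above LOD).
DETECTION_RATES = {"MP": 0.9830, "EP": 0.7125, "PP": 0.6544, "BPA": 0.8074}

#: Whole-population median creatinine-adjusted concentrations, µg/g-cre.
POPULATION_MEDIANS = {"MP": 17.54, "EP": 0.97, "PP": 1.60, "BPA": 1.19}

#: Per-age-group median creatinine-adjusted concentrations, µg/g-cre.
STRATUM_MEDIANS = {
    "MP": {"6-11": 14.23, "12-18": 13.94, "19-64": 23.64, ">=65": 21.10},
    "EP": {"6-11": 0.97, "12-18": 0.37, "19-64": 1.63, ">=65": 1.50},
    "PP": {"6-11": 1.59, "12-18": 2.00, "19-64": 2.31, ">=65": 0.18},
    "BPA": {"6-11": 2.05, "12-18": 1.12, "19-64": 0.71, ">=65": 0.68},
}

#: Urinary excretion fractions F_UE (fraction of ingested dose recovered
#: in urine as the measured analyte).
EXCRETION_FRACTIONS = {"MP": 0.174, "EP": 0.137, "PP": 0.086, "BPA": 1.0}

#: Health-based reference doses, expressed as (value, unit, dose type, source).
#: EFSA group ADI for MP/EP, EMA ADI for PP, EFSA 2023 TDI for BPA.
REFERENCE_DOSES = {
    "MP": (10.0, "mg/kg-bw/day", "ADI", "EFSA 2004 group ADI"),
    "EP": (10.0, "mg/kg-bw/day", "ADI", "EFSA 2004 group ADI"),
    "PP": (1.25, "mg/kg-bw/day", "ADI", "EMA ADI"),
    "BPA": (0.2, "ng/kg-bw/day", "TDI", "EFSA 2023 TDI"),
}

FOOD_GROUPS = (
    "grain",
    "oil",
    "poultry",
    "livestock",
    "fish_and_seafood",
    "protein",
    "vegetable",
    "fruit",
    "snack",
    "alcohol",
    "seasoning",
    "others",
)

#: 24-h dietary recall cooked weights (g/day), per age group:
#: (median, mean, SD) per food group.
DIETARY_RECALL = {
    "grain": {
        "6-11": (314.45, 354.46, 206.11),
        "12-18": (343.58, 409.20, 278.35),
        "19-64": (412.24, 483.75, 307.45),
        ">=65": (562.38, 645.64, 381.85),
    },
    "oil": {
        "6-11": (12.28, 17.82, 19.68),
        "12-18": (14.74, 19.64, 20.76),
        "19-64": (13.88, 22.24, 26.73),
        ">=65": (12.30, 14.84, 20.95),
    },
    "poultry": {
        "6-11": (0.00, 28.91, 49.64),
        "12-18": (9.48, 51.98, 79.56),
        "19-64": (0.00, 17.05, 33.05),
        ">=65": (0.00, 8.55, 23.67),
    },
    "livestock": {
        "6-11": (45.88, 69.85, 79.43),
        "12-18": (61.52, 82.27, 81.70),
        "19-64": (56.95, 76.72, 84.12),
        ">=65": (39.02, 60.29, 78.07),
    },
    "fish_and_seafood": {
        "6-11": (11.31, 33.21, 49.56),
        "12-18": (16.79, 41.92, 60.56),
        "19-64": (30.84, 62.41, 90.53),
        ">=65": (12.14, 33.68, 53.24),
    },
    "protein": {
        "6-11": (177.11, 231.57, 230.50),
        "12-18": (154.23, 218.67, 230.88),
        "19-64": (98.19, 196.90, 262.53),
        ">=65": (45.83, 110.18, 160.44),
    },
    "vegetable": {
        "6-11": (132.22, 174.52, 152.83),
        "12-18": (145.75, 180.47, 136.81),
        "19-64": (227.34, 293.97, 249.36),
        ">=65": (276.56, 325.66, 264.44),
    },
    "fruit": {
        "6-11": (84.86, 121.60, 147.90),
        "12-18": (23.25, 108.22, 151.04),
        "19-64": (182.42, 252.70, 259.83),
        ">=65": (120.23, 171.86, 194.54),
    },
    "snack": {
        "6-11": (238.29, 367.36, 394.63),
        "12-18": (528.93, 671.28, 604.33),
        "19-64": (433.77, 742.36, 840.68),
        ">=65": (284.43, 493.32, 745.35),
    },
    "alcohol": {
        "6-11": (0.00, 1.12, 4.04),
        "12-18": (0.00, 3.80, 24.30),
        "19-64": (0.10, 25.41, 124.49),
        ">=65": (0.00, 15.11, 76.14),
    },
    "seasoning": {
        "6-11": (26.45, 49.34, 69.38),
        "12-18": (30.17, 52.53, 60.91),
        "19-64": (22.92, 58.79, 165.23),
        ">=65": (15.01, 27.19, 36.56),
    },
    "others": {
        "6-11": (230.03, 312.48, 328.33),
        "12-18": (252.98, 326.78, 334.42),
        "19-64": (239.22, 332.43, 414.47),
        ">=65": (196.29, 276.54, 532.21),
    },
}

#: Estimated daily intake distributions (µg/kg-bw/day) by age group:
#: {analyte: {group: {"min", "p25", "p50", "p75", "max"}}}.
EDI_SUMMARY = {
    "MP": {
        "6-11": {"min": 0.002, "p25": 0.55, "p50": 1.53, "p75": 3.42, "max": 355.2},
        "12-18": {"min": 0.001, "p25": 0.58, "p50": 1.43, "p75": 4.02, "max": 47.9},
        "19-64": {"min": 0.003, "p25": 1.03, "p50": 2.46, "p75": 6.02, "max": 147.8},
        ">=65": {"min": 0.001, "p25": 0.56, "p50": 1.45, "p75": 3.36, "max": 142.7},
    },
    "EP": {
        "6-11": {"min": 0.001, "p25": 0.05, "p50": 0.13, "p75": 0.26, "max": 36.4},
        "12-18": {"min": 0.0003, "p25": 0.001, "p50": 0.05, "p75": 0.23, "max": 16.3},
        "19-64": {"min": 0.0007, "p25": 0.08, "p50": 0.20, "p75": 0.57, "max": 14.5},
        ">=65": {"min": 0.0006, "p25": 0.02, "p50": 0.11, "p75": 0.33, "max": 8.52},
    },
    "PP": {
        "6-11": {"min": 0.001, "p25": 0.01, "p50": 0.32, "p75": 1.19, "max": 24.3},
        "12-18": {"min": 0.0004, "p25": 0.004, "p50": 0.43, "p75": 1.75, "max": 31.9},
        "19-64": {"min": 0.0009, "p25": 0.003, "p50": 0.48, "p75": 2.03, "max": 29.9},
        ">=65": {"min": 0.0005, "p25": 0.002, "p50": 0.006, "p75": 1.21, "max": 23.7},
    },
    "BPA": {
        "6-11": {"min": 0.001, "p25": 0.02, "p50": 0.03, "p75": 0.05, "max": 0.64},
        "12-18": {"min": 0.0003, "p25": 0.01, "p50": 0.02, "p75": 0.03, "max": 0.69},
        "19-64": {"min": 0.0005, "p25": 0.002, "p50": 0.01, "p75": 0.03, "max": 0.34},
        ">=65": {"min": 0.0005, "p25": 0.002, "p50": 0.008, "p75": 0.02, "max": 0.64},
    },
}

#: Body weight / height moments per stratum used by the synthetic
#: generator: (bw_mean kg, bw_sd, ht_mean cm, ht_sd). The survey reports
#: only aggregate age and BMI, so these are physiologic stand-ins for a
#: Taiwanese population, not printed values.
ANTHROPOMETRY = {
    "6-11": (30.0, 8.0, 131.0, 10.0),
    "12-18": (55.0, 12.0, 161.0, 8.5),
    "19-64": (64.0, 12.0, 165.0, 8.0),
    ">=65": (60.0, 10.0, 158.0, 8.0),
}
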