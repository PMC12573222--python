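import numpy as np
import pandas as pd
import pytest

from biomonrisk import synthetic
from biomonrisk.surveydata import AGE_GROUPS, FOOD_GROUPS


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.default_population_spec(seed=0)


@pytest.fixture(scope="session")
def population(default_spec):
    """One full synthetic survey draw shared across tests."""
    participants = synthetic.generate_population(default_spec, seed=11)
    intakes = synthetic.generate_intakes(participants, default_spec, seed=12)
    biomarkers = synthetic.generate_biomarkers(
        participants, default_spec, intakes, seed=13
    )
    return {
        "spec": default_spec,
        "participants": participants,
        "intakes": intakes,
        "biomarkers": biomarkers,
    }


def single_stratum_spec(
    n=700,
    analyte_gsd=2.5,
    diet_effects=None,
    stratum="19-64",
):
    """Compact one-stratum spec for estimator-recovery studies.

    Residual geometric SD defaults to 2.5, representative biological
    variability for a urinary biomarker, rather than the detection-rate
    calibrated default (whose very heavy tails are a censoring artifact,
    not an estimation test bed).
    """
    base = synthetic.default_population_spec(seed=0)
    strat = next(s for s in base.strata if s.name == stratum)
    strat = synthetic.StratumSpec(
        name=stratum,
        n=n,
        age_range=strat.age_range,
        bw_mean=strat.bw_mean,
        bw_sd=strat.bw_sd,
        ht_mean=strat.ht_mean,
        ht_sd=strat.ht_sd,
    )
    analyte = synthetic.AnalyteSpec(
        analyte_id="EP",
        lod=0.02,
        loq=0.06,
        geometric_mean=0.97,
        geometric_sd=analyte_gsd,
    )
    return synthetic.PopulationSpec(
        strata=[strat],
        sex_ratio_male=0.5,
        analytes=[analyte],
        food_groups=list(base.food_groups),
        diet_effects=diet_effects or {},
    )
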