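"""Synthetic-population generator: structure, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biomonrisk import synthetic
from biomonrisk.surveydata import (
    AGE_GROUPS,
    ANALYTES,
    DETECTION_RATES,
    DIETARY_RECALL,
    FOOD_GROUPS,
    GROUP_SIZES,
    POPULATION_MEDIANS,
)

from conftest import single_stratum_spec


class TestDefaultSpec:
    def test_total_sample_size_and_strata(self, default_spec):
        assert default_spec.total_n == 706
        assert [s.name for s in default_spec.strata] == list(AGE_GROUPS)
        assert {s.name: s.n for s in default_spec.strata} == GROUP_SIZES

    def test_sex_ratio_near_half(self, default_spec):
        assert default_spec.sex_ratio_male == pytest.approx(0.5, abs=0.01)

    def test_population_geometric_means_match_published_medians(self, default_spec):
        for a in ANALYTES:
            assert default_spec.analyte(a).geometric_mean == POPULATION_MEDIANS[a]

    def test_all_food_groups_present(self, default_spec):
        assert [fg.group_id for fg in default_spec.food_groups] == list(FOOD_GROUPS)

    def test_yaml_round_trip(self, default_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        default_spec.to_yaml(path)
        back = synthetic.PopulationSpec.from_yaml(path)
        assert back.total_n == default_spec.total_n
        assert back.analyte("MP").geometric_sd == pytest.approx(
            default_spec.analyte("MP").geometric_sd
        )


class TestGeneratePopulation:
    def test_row_count_and_ages_within_strata(self, population):
        p = population["participants"]
        assert len(p) == 706
        for s in population["spec"].strata:
            sub = p[p.age_group == s.name]
            assert len(sub) == s.n
            lo, hi = s.age_range
            assert sub.age.between(lo, hi).all()

    def test_seeded_reproducibility(self, default_spec):
        a = synthetic.generate_population(default_spec, seed=5)
        b = synthetic.generate_population(default_spec, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_positive_anthropometry(self, population):
        p = population["participants"]
        assert (p.body_weight > 0).all() and (p.height > 0).all()

    def test_zero_group_size_rejected(self):
        with pytest.raises(ValueError):
            synthetic.StratumSpec(
                name="6-11", n=0, age_range=(6, 12),
                bw_mean=30, bw_sd=8, ht_mean=131, ht_sd=10,
            )

    def test_bw_ht_correlation_propagates(self, population):
        p = population["participants"]
        r = p.groupby("age_group").apply(
            lambda d: np.corrcoef(d.body_weight, d.height)[0, 1],
            include_groups=False,
        )
        assert (r > 0.3).all()


class TestGenerateIntakes:
    def test_zero_median_for_low_consumption_groups(self, population):
        merged = population["intakes"].merge(
            population["participants"][["subject_id", "age_group"]]
        )
        assert merged[merged.age_group == "6-11"].poultry.median() == 0.0

    def test_degenerate_consumer_distribution(self):
        fg = synthetic.FoodGroupSpec(
            group_id="grain",
            consumption_probability={"19-64": 1.0},
            intake_log_mean={"19-64": np.log(300.0)},
            intake_log_sd={"19-64": 0.0},
        )
        spec = single_stratum_spec(n=50)
        spec = synthetic.PopulationSpec(
            strata=spec.strata,
            sex_ratio_male=0.5,
            analytes=spec.analytes,
            food_groups=[fg],
        )
        p = synthetic.generate_population(spec, seed=1)
        i = synthetic.generate_intakes(p, spec, seed=2)
        assert np.allclose(i.grain, 300.0)

    def test_published_intake_medians_recovered(self, population):
        merged = population["intakes"].merge(
            population["participants"][["subject_id", "age_group"]]
        )
        med = merged[merged.age_group == "6-11"].grain.median()
        target = DIETARY_RECALL["grain"]["6-11"][0]
        assert med == pytest.approx(target, rel=0.20)

    def test_all_intakes_non_negative(self, population):
        assert (population["intakes"][list(FOOD_GROUPS)] >= 0).all().all()


class TestGenerateBiomarkers:
    def test_detection_rates_match_calibration(self, population):
        m = population["biomarkers"]
        for a in ANALYTES:
            rate = 1.0 - m.loc[m.analyte_id == a, "censored"].mean()
            assert rate == pytest.approx(DETECTION_RATES[a], abs=0.05)

    def test_mp_detection_near_published(self, default_spec):
        p = synthetic.generate_population(default_spec, seed=7)
        i = synthetic.generate_intakes(p, default_spec, seed=7)
        m = synthetic.generate_biomarkers(p, default_spec, i, seed=7)
        rate = 1.0 - m.loc[m.analyte_id == "MP", "censored"].mean()
        assert rate == pytest.approx(0.9830, abs=0.03)

    def test_censoring_flag_consistent_with_raw_values(self, population):
        m = population["biomarkers"]
        assert (m.censored == (m.raw_concentration < m.lod)).all()

    def test_mismatched_subject_ids_rejected(self, population):
        bad = population["intakes"].iloc[:-5]
        with pytest.raises(ValueError, match="subject ids"):
            synthetic.generate_biomarkers(
                population["participants"], population["spec"], bad, seed=1
            )

    def test_high_gm_low_sd_fully_detected(self):
        spec = single_stratum_spec(n=300, analyte_gsd=1.1)
        p = synthetic.generate_population(spec, seed=3)
        i = synthetic.generate_intakes(p, spec, seed=3)
        m = synthetic.generate_biomarkers(p, spec, i, seed=3)
        assert not m.censored.any()

    def test_null_diet_effects_give_independence(self):
        spec = single_stratum_spec(n=2000)
        p = synthetic.generate_population(spec, seed=4)
        i = synthetic.generate_intakes(p, spec, seed=4)
        m = synthetic.generate_biomarkers(p, spec, i, seed=4)
        merged = m.merge(i, on="subject_id")
        rho, _ = stats.spearmanr(merged.grain, merged.raw_concentration)
        assert abs(rho) < 0.06

    def test_marginal_geometric_mean_recovery(self):
        spec = single_stratum_spec(n=10_000)
        p = synthetic.generate_population(spec, seed=9)
        i = synthetic.generate_intakes(p, spec, seed=9)
        m = synthetic.generate_biomarkers(p, spec, i, seed=9)
        adjusted = m.raw_concentration / m.creatinine
        gm = np.exp(np.log(adjusted).mean())
        assert gm == pytest.approx(spec.analytes[0].geometric_mean, rel=0.02)

    def test_injected_effect_shifts_concentration(self):
        null = single_stratum_spec(n=3000)
        shifted = single_stratum_spec(
            n=3000, diet_effects={("grain", "EP"): 0.1}
        )
        draws = {}
        for name, spec in [("null", null), ("shifted", shifted)]:
            p = synthetic.generate_population(spec, seed=6)
            i = synthetic.generate_intakes(p, spec, seed=6)
            m = synthetic.generate_biomarkers(p, spec, i, seed=6)
            draws[name] = np.log(m.raw_concentration / m.creatinine).mean()
        # grain mean intake ~484 g/day in the adult stratum -> ~0.48 log shift
        assert draws["shifted"] - draws["null"] == pytest.approx(0.48, abs=0.1)


class TestZeroInflatedFit:
    def test_positive_median_matched(self):
        p, mu, sigma = synthetic.fit_zero_inflated_lognormal(314.45, 354.46, 206.11)
        z_q = stats.norm.ppf(1 - 0.5 / p)
        assert np.exp(mu + sigma * z_q) == pytest.approx(314.45, rel=1e-9)

    def test_zero_median_uses_nonconsumers(self):
        p, mu, sigma = synthetic.fit_zero_inflated_lognormal(0.0, 28.91, 49.64)
        assert p < 0.5
        assert p * np.exp(mu + sigma**2 / 2) == pytest.approx(28.91, rel=1e-6)


class TestResidualSigmaOracle:
    def test_detection_probability_inverts(self):
        sigma = synthetic.solve_residual_sigma(
            {"g": 17.54}, {"g": 1.0}, lod=0.03, detection_rate=0.983
        )
        sigma_tot = np.hypot(sigma, np.log(1.8))
        back = stats.norm.cdf(np.log(17.54 / 0.03) / sigma_tot)
        assert back == pytest.approx(0.983, abs=1e-9)

    def test_gm_below_lod_rejected(self):
        with pytest.raises(ValueError):
            synthetic.solve_residual_sigma(
                {"g": 0.01}, {"g": 1.0}, lod=0.03, detection_rate=0.9
            )
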