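"""Spearman screening, mutually adjusted regression, g-computation."""

import numpy as np
import pandas as pd
import pytest

from biomonrisk import associations, synthetic
from biomonrisk.surveydata import FOOD_GROUPS

from conftest import single_stratum_spec


def make_tables(spec, seed, effect_log=None):
    participants = synthetic.generate_population(spec, seed=seed)
    intakes = synthetic.generate_intakes(participants, spec, seed=seed + 1)
    biomarkers = synthetic.generate_biomarkers(
        participants, spec, intakes, seed=seed + 2
    )
    adjusted = biomarkers.assign(
        adjusted=biomarkers.raw_concentration / biomarkers.creatinine
    )
    return participants, intakes, adjusted


def toy_adjusted(x, y, analyte="EP"):
    n = len(x)
    ids = [f"s{i}" for i in range(n)]
    adjusted = pd.DataFrame(
        {"subject_id": ids, "analyte_id": analyte, "adjusted": y}
    )
    intakes = pd.DataFrame({"subject_id": ids, "oil": x})
    for fg in FOOD_GROUPS:
        if fg != "oil":
            intakes[fg] = 0.0
    return adjusted, intakes


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.linspace(1, 10, 20)
        adjusted, intakes = toy_adjusted(x, x**3)
        (res,) = associations.spearman_matrix(
            adjusted, intakes, "EP", food_groups=["oil"]
        )
        assert res.estimate == pytest.approx(1.0)

    def test_perfect_antitone(self):
        x = np.linspace(1, 10, 20)
        adjusted, intakes = toy_adjusted(x, -x)
        (res,) = associations.spearman_matrix(
            adjusted, intakes, "EP", food_groups=["oil"]
        )
        assert res.estimate == pytest.approx(-1.0)

    def test_hand_ranked_value(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)); d = (-1,1,-1,1,0), sum d^2 = 4,
        # so rho = 1 - 24/120 = 0.8
        x = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5, 2, 1, 4, 3, 5], float)
        # duplicating the 5 base pairs keeps rho (ranks transform linearly)
        # while satisfying the 10-complete-pair minimum
        adjusted, intakes = toy_adjusted(x, y)
        (res,) = associations.spearman_matrix(
            adjusted, intakes, "EP", food_groups=["oil"]
        )
        assert res.estimate == pytest.approx(0.8, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(2, 1, 60)
        y = rng.lognormal(0, 1, 60)
        a1, i1 = toy_adjusted(x, y)
        a2, i2 = toy_adjusted(np.log(x), np.exp(y / y.max()))
        r1 = associations.spearman_matrix(a1, i1, "EP", food_groups=["oil"])[0]
        r2 = associations.spearman_matrix(a2, i2, "EP", food_groups=["oil"])[0]
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-12)

    def test_constant_column_rejected(self):
        adjusted, intakes = toy_adjusted(np.ones(20), np.arange(20.0) + 1)
        with pytest.raises(ValueError, match="constant"):
            associations.spearman_matrix(adjusted, intakes, "EP", food_groups=["oil"])


class TestMlrFoodGroups:
    def _participants(self, n):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "sex": np.where(np.arange(n) % 2 == 0, "male", "female"),
            }
        )

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.lognormal(2.5, 0.5, n)
        y = 0.2 * x + rng.normal(0, 0.5, n) + 5.0
        adjusted, intakes = toy_adjusted(x, y)
        res, fit = associations.mlr_food_groups(
            adjusted, intakes, self._participants(n), "EP", ["oil"]
        )
        assert res[0].ci_low <= 0.2 <= res[0].ci_high
        assert 0.15 <= res[0].estimate <= 0.25
        assert 0 <= fit["r_squared"] <= 1

    def test_null_coverage(self):
        rng = np.random.default_rng(2)
        n = 150
        covered = 0
        for _ in range(100):
            x = rng.lognormal(2.5, 0.5, n)
            y = rng.normal(10, 2, n)
            adjusted, intakes = toy_adjusted(x, y)
            res, _ = associations.mlr_food_groups(
                adjusted, intakes, self._participants(n), "EP", ["oil"]
            )
            covered += res[0].ci_low <= 0.0 <= res[0].ci_high
        assert covered >= 90

    def test_duplicate_column_rank_deficiency(self):
        rng = np.random.default_rng(3)
        n = 50
        x = rng.lognormal(2, 0.5, n)
        adjusted, intakes = toy_adjusted(x, x + 1)
        intakes["oil_copy"] = intakes["oil"]
        with pytest.raises(ValueError, match="oil_copy"):
            associations.mlr_food_groups(
                adjusted, intakes, self._participants(n), "EP", ["oil", "oil_copy"]
            )


class TestGComputation:
    def test_null_effect_ci_covers_zero(self):
        spec = single_stratum_spec(n=300)
        participants, intakes, adjusted = make_tables(spec, seed=10)
        eff = associations.gcomputation_effect(
            adjusted, intakes, participants, "EP", "oil", n_boot=400, seed=1
        )
        assert eff.ci_low <= 0.0 <= eff.ci_high
        assert abs(eff.percent_change) < 25

    def test_injected_effect_recovered(self):
        beta = 0.6  # log-scale effect per 100 g/day of oil
        spec = single_stratum_spec(n=700, diet_effects={("oil", "EP"): beta})
        participants, intakes, adjusted = make_tables(spec, seed=20)
        eff = associations.gcomputation_effect(
            adjusted, intakes, participants, "EP", "oil", n_boot=400, seed=2
        )
        truth = 100.0 * (
            np.mean(np.exp(beta * intakes.oil.to_numpy() / 100.0)) - 1.0
        )
        assert eff.ci_low <= truth <= eff.ci_high
        assert eff.percent_change > 0.0

    def test_seeded_reproducibility(self):
        spec = single_stratum_spec(n=100)
        participants, intakes, adjusted = make_tables(spec, seed=30)
        kw = dict(n_boot=200, seed=5)
        a = associations.gcomputation_effect(
            adjusted, intakes, participants, "EP", "oil", **kw
        )
        b = associations.gcomputation_effect(
            adjusted, intakes, participants, "EP", "oil", **kw
        )
        assert (a.ci_low, a.ci_high, a.percent_change) == (
            b.ci_low, b.ci_high, b.percent_change
        )

    def test_noiseless_small_instance_matches_closed_form(self):
        # with zero residual noise the g-computation estimate equals the
        # exact log-linear contrast on the generated subjects
        beta = 0.5
        spec = single_stratum_spec(
            n=60, analyte_gsd=1.0000001, diet_effects={("oil", "EP"): beta}
        )
        participants, intakes, adjusted = make_tables(spec, seed=40)
        eff = associations.gcomputation_effect(
            adjusted, intakes, participants, "EP", "oil", n_boot=200, seed=3
        )
        truth = 100.0 * (
            np.mean(np.exp(beta * intakes.oil.to_numpy() / 100.0)) - 1.0
        )
        assert eff.percent_change == pytest.approx(truth, rel=1e-3)

    def test_alternative_contrasts_run(self):
        spec = single_stratum_spec(n=120)
        participants, intakes, adjusted = make_tables(spec, seed=50)
        for contrast in ("p75_vs_p25", "plus_100g"):
            eff = associations.gcomputation_effect(
                adjusted, intakes, participants, "EP", "oil",
                contrast=contrast, n_boot=200, seed=4,
            )
            assert np.isfinite(eff.percent_change)

    def test_small_sample_rejected(self):
        spec = single_stratum_spec(n=40)
        participants, intakes, adjusted = make_tables(spec, seed=60)
        with pytest.raises(ValueError):
            associations.gcomputation_effect(
                adjusted.iloc[:20], intakes.iloc[:20], participants.iloc[:20],
                "EP", "oil", n_boot=200, seed=0,
            )


class TestEffectWeights:
    def _effects(self, values):
        return [
            associations.GCompEffect(
                analyte_id="EP", food_group=f"g{i}", age_group="all",
                percent_change=v, ci_low=v - 1, ci_high=v + 1,
                p_value=0.5, contrast="observed_vs_zero", n_boot=200,
            )
            for i, v in enumerate(values)
        ]

    def test_signed_shares(self):
        out = associations.effect_weights(self._effects([2.0, -1.0, 3.0]))
        assert [e.weight for e in out] == pytest.approx([1 / 3, -1 / 6, 1 / 2])

    def test_single_effect(self):
        (out,) = associations.effect_weights(self._effects([-4.0]))
        assert out.weight == -1.0

    def test_balanced_pair(self):
        out = associations.effect_weights(self._effects([1.0, -1.0]))
        assert [e.weight for e in out] == pytest.approx([0.5, -0.5])
        assert sum(abs(e.weight) for e in out) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            associations.effect_weights(self._effects([0.0, 0.0]))
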