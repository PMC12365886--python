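"""Normalisation, replicate summaries and the gated statistics pipeline."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoscreen.simulate import PlateSpec, generate_plate
from nanoscreen.viability import (
    PlateError,
    ViabilityGroup,
    ViabilityPlate,
    assumption_checks,
    effect_sizes,
    hedges_g,
    normalize_viability,
    omnibus_tests,
    posthoc_tests,
    replicate_summary,
    run_viability_pipeline,
)

from conftest import make_plate


class TestNormalizeViability:
    def test_control_mean_is_exactly_100(self):
        plate = make_plate(
            {"control": (None, [0.8, 0.8, 0.8]), "t1": (50, [0.4, 0.4, 0.4])}
        )
        out = normalize_viability(plate)
        np.testing.assert_allclose(out.control.values, [100, 100, 100])
        np.testing.assert_allclose(out.treatments[0].values, [50, 50, 50])

    def test_half_of_uneven_control(self):
        plate = make_plate({"control": (None, [0.6, 1.0]), "t1": (50, [0.4, 0.4])})
        out = normalize_viability(plate)
        assert out.control.values.mean() == pytest.approx(100.0, rel=1e-12)
        np.testing.assert_allclose(out.treatments[0].values, [50, 50])

    def test_zero_control_mean_rejected(self):
        plate = make_plate({"control": (None, [0.0, 0.0]), "t1": (50, [0.4, 0.4])})
        with pytest.raises(PlateError):
            normalize_viability(plate)

    def test_missing_control_label_rejected(self):
        plate = make_plate({"control": (None, [1, 1]), "t1": (50, [1, 1])})
        with pytest.raises(PlateError):
            normalize_viability(plate, control_label="nope")


class TestReplicateSummary:
    @pytest.mark.parametrize(
        "values,expected",
        [
            # triplicate zeta potentials (mV): 105-day and 24-h readings
            ([-26.3, -26.8, -28.0], (-27.0, 0.9)),
            ([-41.0, -45.4, -45.1], (-43.8, 2.5)),
            ([5, 5, 5], (5.0, 0.0)),
        ],
    )
    def test_mean_and_sample_sd(self, values, expected):
        assert replicate_summary(values) == expected

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            assert replicate_summary([3.2]) == (3.2, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_summary([])


class TestAssumptionChecks:
    def test_levene_worked_example(self):
        plate = make_plate({"a": (None, [1, 2, 3]), "b": (10, [2, 4, 6])}, control="a")
        rep = assumption_checks(plate)
        assert rep.levene_W == pytest.approx(0.8, abs=1e-12)

    def test_constant_group_flagged_not_normal(self):
        plate = make_plate({"a": (None, [5, 5, 5]), "b": (10, [1, 2, 3])}, control="a")
        rep = assumption_checks(plate)
        row = rep.shapiro.set_index("group").loc["a"]
        assert not row["normal"] and "distinct" in row["note"]
        assert not rep.all_normal

    def test_all_constant_groups_give_zero_levene(self):
        plate = make_plate({"a": (None, [7, 7, 7]), "b": (10, [9, 9, 9])}, control="a")
        rep = assumption_checks(plate)
        assert rep.levene_W == 0.0

    def test_shapiro_null_rejection_rate(self):
        # under normal sampling the per-group rejection rate should sit at alpha
        rng = np.random.default_rng(11)
        rejections = 0
        n_tests = 0
        for _ in range(2000):
            for _ in range(2):
                x = rng.normal(100.0, 5.0, size=9)
                from scipy.stats import shapiro

                _, p = shapiro(x)
                rejections += p <= 0.05
                n_tests += 1
        assert abs(rejections / n_tests - 0.05) < 0.02


class TestOmnibus:
    def test_worked_example(self, three_group_plate):
        rep = omnibus_tests(three_group_plate)
        assert rep.F == pytest.approx(3.0, abs=1e-12)
        assert (rep.df_between, rep.df_within) == (2, 6)
        assert rep.partial_eta_sq == pytest.approx(0.5, abs=1e-12)

    def test_equal_means_give_zero_F(self):
        plate = make_plate({"a": (None, [1, 3]), "b": (10, [2, 2])}, control="a")
        assert omnibus_tests(plate).F == 0.0

    def test_kruskal_worked_example(self):
        plate = make_plate({"a": (None, [1, 2]), "b": (10, [3, 4])}, control="a")
        assert omnibus_tests(plate).H == pytest.approx(2.4, abs=1e-9)

    def test_zero_within_variance_reports_infinite_F(self):
        plate = make_plate({"a": (None, [1, 1]), "b": (10, [2, 2])}, control="a")
        with pytest.warns(UserWarning):
            rep = omnibus_tests(plate)
        assert math.isinf(rep.F) and rep.p_anova == 0.0

    def test_partial_eta_identity(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            plate = generate_plate(PlateSpec(seed=seed))
            groups = [g.values for g in plate.groups]
            allv = np.concatenate(groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            sst = ((allv - allv.mean()) ** 2).sum()
            rep = omnibus_tests(plate)
            assert rep.partial_eta_sq == pytest.approx(1 - ssw / sst, abs=1e-12)


class TestEffectSizes:
    def test_identical_groups_zero(self):
        g, J = hedges_g([1, 2, 3], [1, 2, 3])
        assert g == 0.0

    def test_worked_example_and_antisymmetry(self):
        g, J = hedges_g([1, 2, 3], [3, 4, 5])
        assert (g, J) == pytest.approx((-1.6, 0.8), abs=1e-12)
        g_swapped, _ = hedges_g([3, 4, 5], [1, 2, 3])
        assert g_swapped == pytest.approx(-g, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-50, 50),
        seed=st.integers(0, 10_000),
    )
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 2, 8)
        g0, _ = hedges_g(x, y)
        g1, _ = hedges_g(x + shift, y + shift)
        assert g1 == pytest.approx(g0, abs=1e-9)

    def test_zero_pooled_variance_flagged(self):
        plate = make_plate({"a": (None, [1, 1]), "b": (10, [2, 2])}, control="a")
        rep = effect_sizes(plate)
        assert not rep.comparisons["defined"].iloc[0]

    def test_matches_independent_library(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(100, 5, rng.integers(3, 12))
            y = rng.normal(90, 8, rng.integers(3, 12))
            g, _ = hedges_g(x, y)
            assert g == pytest.approx(
                pingouin.compute_effsize(x, y, eftype="hedges"), abs=1e-9
            )


class TestPipeline:
    def test_monotone_dose_effect_all_significant(self):
        plate = generate_plate(PlateSpec(seed=5))
        rep = run_viability_pipeline(plate)
        assert (rep.posthoc.dunnett["p_adjusted"] < 0.05).all()
        assert (rep.effects.comparisons["hedges_g"].abs() > 1).all()

    def test_non_normal_group_triggers_kw_flag(self):
        plate = make_plate(
            {
                "control": (None, [100, 100, 100, 100, 100, 100, 100, 100, 1000]),
                "t1": (50, list(np.linspace(70, 75, 9))),
            }
        )
        rep = run_viability_pipeline(plate)
        assert rep.omnibus.kw_run

    def test_null_plates_rarely_yield_posthoc_hits(self):
        clean = 0
        runs = 200
        for i in range(runs):
            plate = generate_plate(
                PlateSpec(group_means_pct=(100.0,) * 6, sd_pct=5.0, seed=50_000 + i)
            )
            rep = run_viability_pipeline(plate)
            any_hit = (rep.posthoc.dunnett["p_adjusted"] < 0.05).any() or (
                rep.posthoc.tukey["p_adjusted"] < 0.05
            ).any()
            clean += not any_hit
        assert clean / runs >= 0.9

    def test_stage_identified_on_error(self):
        plate = make_plate({"a": (None, [1, 1]), "b": (10, [2, 2])}, control="a")
        with pytest.raises(PlateError, match="posthoc_tests"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_viability_pipeline(plate)


class TestPlateValidation:
    def test_single_replicate_group_rejected(self):
        with pytest.raises(PlateError):
            ViabilityGroup("a", None, [1.0])

    def test_duplicate_control_rejected(self):
        with pytest.raises(PlateError):
            ViabilityPlate(
                (
                    ViabilityGroup("c", None, [1, 2]),
                    ViabilityGroup("c", 10, [1, 2]),
                ),
                "c",
            )
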