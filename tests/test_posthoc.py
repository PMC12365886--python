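"""Multiple-comparison adjustments and the exact Kruskal–Wallis test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from nanoscreen.multcomp import dunnett_max_abs_prob, dunnett_pvalues
from nanoscreen.viability import kruskal_exact, posthoc_tests
from conftest import make_plate


class TestDunnett:
    def test_single_contrast_reduces_to_t(self):
        # with one treatment the multivariate-t maximum is a plain |t|
        for df in (5, 16, 48):
            for t0 in (0.3, 1.2, 2.8):
                p = 1.0 - dunnett_max_abs_prob(t0, [1 / math.sqrt(2)], df)
                assert p == pytest.approx(2 * stats.t.sf(t0, df), abs=1e-9)

    def test_matches_reference_implementation(self):
        # scipy's dunnett uses randomised QMC; agreement to its accuracy level
        rng = np.random.default_rng(8)
        groups = [rng.normal(100, 5, 9) for _ in range(4)]
        ctrl = rng.normal(100, 5, 9)
        ref = stats.dunnett(*groups, control=ctrl)
        dfw = 5 * 9 - 5
        sp2 = sum(((g - g.mean()) ** 2).sum() for g in groups + [ctrl]) / dfw
        tvals = [
            (g.mean() - ctrl.mean()) / math.sqrt(sp2 * (2 / 9)) for g in groups
        ]
        mine = dunnett_pvalues(tvals, [9] * 4, 9, dfw)
        np.testing.assert_allclose(mine, ref.pvalue, atol=5e-4)

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(13)
        plate = make_plate(
            {
                "control": (None, rng.normal(100, 5, 9)),
                "a": (10, rng.normal(96, 5, 9)),
                "b": (50, rng.normal(88, 5, 9)),
                "c": (100, rng.normal(70, 5, 9)),
            }
        )
        rep = posthoc_tests(plate)
        assert (rep.dunnett["p_adjusted"] >= rep.dunnett["p_unadjusted"] - 1e-15).all()
        assert (rep.tukey["p_adjusted"] >= rep.tukey["p_unadjusted"] - 1e-15).all()

    def test_null_contrast_has_p_near_one(self):
        plate = make_plate(
            {
                "control": (None, [100.0, 101.0, 99.0, 100.5, 99.5]),
                "same": (10, [100.0, 101.0, 99.0, 100.5, 99.5]),
                "diff": (100, [60.0, 61.0, 59.0, 60.5, 59.5]),
            }
        )
        rep = posthoc_tests(plate)
        row = rep.dunnett.set_index("group").loc["same"]
        assert row["mean_diff"] == 0.0
        assert row["p_adjusted"] >= 0.999


class TestTukey:
    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(100, 5, 9), rng.normal(92, 5, 9)
        plate = make_plate({"control": (None, x), "t": (50, y)})
        rep = posthoc_tests(plate)
        t_p = stats.ttest_ind(y, x).pvalue
        assert rep.tukey["p_adjusted"].iloc[0] == pytest.approx(t_p, abs=1e-6)
        assert rep.dunnett["p_adjusted"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(17)
        samples = [rng.normal(m, 4, 7) for m in (100, 95, 85)]
        plate = make_plate(
            {
                "control": (None, samples[0]),
                "a": (10, samples[1]),
                "b": (100, samples[2]),
            }
        )
        rep = posthoc_tests(plate)
        ref = stats.tukey_hsd(*samples)
        got = {
            frozenset(pair): p
            for pair, p in zip(
                rep.tukey[["group_1", "group_2"]].itertuples(index=False),
                rep.tukey["p_adjusted"],
            )
        }
        labels = ["control", "a", "b"]
        for i, j in itertools.combinations(range(3), 2):
            assert got[frozenset((labels[i], labels[j]))] == pytest.approx(
                ref.pvalue[i, j], abs=1e-9
            )


def _exact_two_group_oracle(x, y):
    """Brute-force permutation distribution of H for two groups."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    h_obs = stats.kruskal(x, y).statistic
    count = total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(combo)] = True
        h = stats.kruskal(pooled[mask], pooled[~mask]).statistic
        total += 1
        count += h >= h_obs - 1e-12
    return h_obs, count / total


class TestKruskalExact:
    @pytest.mark.parametrize(
        "n1,n2", [(2, 2), (2, 3), (2, 4), (3, 3), (2, 5), (3, 4), (2, 6), (3, 5), (4, 4)]
    )
    def test_matches_enumeration_on_small_layouts(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        # integer draws force ties, exercising the midrank handling
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
        if np.all(np.concatenate([x, y]) == x[0]):
            x[0] += 1.0
        h, p = kruskal_exact([x, y])
        h_ref, p_ref = _exact_two_group_oracle(x, y)
        assert h == pytest.approx(h_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_three_group_layout(self):
        x, y, z = [1.0, 5.0], [2.0, 2.0], [4.0, 3.0]
        h, p = kruskal_exact([x, y, z])
        assert h == pytest.approx(stats.kruskal(x, y, z).statistic, abs=1e-12)
        # independent exact route via scipy's permutation machinery
        ref = stats.permutation_test(
            (x, y, z),
            lambda *s: stats.kruskal(*s).statistic,
            permutation_type="independent",
            alternative="greater",
            n_resamples=np.inf,
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_layout_limit_guard(self):
        with pytest.raises(ValueError):
            kruskal_exact([np.arange(12.0), np.arange(12.0)], max_layouts=10)
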