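"""Incremental cost-effectiveness, dominance rules, BCa bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialcea import (bca_bootstrap, bca_interval, bootstrap_increments,
                      ce_plane_export, classify, increment)


class TestIncrementAndClassify:
    def test_published_arm_means_worked_example(self):
        dc, de = increment((5420.0, 0.02131), (5130.0, 0.02133))
        assert dc == pytest.approx(290.0, abs=1e-9)
        assert de == pytest.approx(-0.00002, abs=1e-12)
        assert classify(dc, de) == "dominated"

    def test_identical_arms(self):
        assert increment((5.0, 1.0), (5.0, 1.0)) == (0.0, 0.0)
        assert classify(0.0, 0.0) == "equivalent"

    def test_tradeoff_quadrant_icer(self):
        assert classify(311.0, 0.0002) == pytest.approx(1_555_000.0)
        assert classify(-100.0, -0.001) == pytest.approx(100_000.0)

    def test_dominance_quadrants_and_axes(self):
        assert classify(-100.0, 0.01) == "dominant"
        assert classify(100.0, -0.01) == "dominated"
        assert classify(100.0, 0.0).startswith("dominated")
        assert classify(-100.0, 0.0).startswith("dominant")
        assert classify(0.0, 0.01).startswith("dominant")
        assert classify(0.0, -0.01).startswith("dominated")


class TestBcaInterval:
    def test_constant_statistic_point_interval(self):
        assert bca_interval(np.full(500, 3.3), 3.3, np.full(10, 3.3)) == (3.3, 3.3)

    def test_reduces_to_percentile_when_corrections_vanish(self):
        rng = np.random.default_rng(0)
        rep = rng.normal(0, 1, 4001)
        rep = np.concatenate([rep, -rep])  # exactly symmetric around 0
        jack = np.zeros(8)  # zero acceleration
        lo, hi = bca_interval(rep, 0.0, jack)
        plo, phi = np.quantile(rep, [0.025, 0.975], method="linear")
        assert lo == pytest.approx(plo, abs=1e-9)
        assert hi == pytest.approx(phi, abs=1e-9)

    def test_matches_independent_formula_on_small_sample(self):
        """Oracle: the bias/acceleration construction written out inline."""
        rng = np.random.default_rng(1)
        x = np.array([3.1, 8.2, 1.4, 9.9, 4.4, 5.0, 2.2, 7.3])
        theta = x.mean()
        B = 2000
        rep = np.array([rng.choice(x, len(x)).mean() for _ in range(B)])
        jack = np.array([np.delete(x, i).mean() for i in range(len(x))])

        z0 = stats.norm.ppf(((rep < theta).sum() + 0.5 * (rep == theta).sum()) / B)
        d = jack.mean() - jack
        a = (d**3).sum() / (6 * ((d**2).sum()) ** 1.5)
        z = stats.norm.ppf([0.025, 0.975])
        q = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        expected = np.quantile(rep, q, method="linear")

        got = bca_interval(rep, theta, jack)
        assert got == pytest.approx(tuple(expected), rel=1e-12)

    def test_agrees_with_scipy_bca_on_common_resamples(self):
        """Cross-check against an independent library implementation."""
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, 10.0, size=60)
        res = stats.bootstrap((x,), np.mean, n_resamples=3000, method="BCa",
                              confidence_level=0.95, random_state=3)
        rep = res.bootstrap_distribution
        jack = np.array([np.delete(x, i).mean() for i in range(len(x))])
        lo, hi = bca_interval(rep, x.mean(), jack)
        width = res.confidence_interval.high - res.confidence_interval.low
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.05 * width)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.05 * width)


def two_arm_frame(rng, n=120, cost_shift=200.0, effect_shift=0.0):
    arm = np.repeat(["intervention", "control"], n // 2)
    z = (arm == "intervention").astype(float)
    return pd.DataFrame({
        "arm": arm,
        "total_cost": rng.gamma(4, 250, n) + cost_shift * z,
        "qaly": rng.normal(0.05, 0.01, n) + effect_shift * z,
    })


class TestBootstrapIncrements:
    def test_point_estimates_are_mean_differences(self):
        rng = np.random.default_rng(4)
        df = two_arm_frame(rng)
        res = bootstrap_increments(df, B=300, seed=0)
        g = df.groupby("arm")
        assert res.delta_cost == pytest.approx(
            g["total_cost"].mean()["intervention"] - g["total_cost"].mean()["control"])
        assert res.B == 300 and len(res.replicates) == 300

    def test_replicate_mean_near_point_estimate(self):
        rng = np.random.default_rng(5)
        df = two_arm_frame(rng, n=300)
        res = bootstrap_increments(df, B=2000, seed=1)
        boot_se = res.replicates["delta_cost"].std()
        assert abs(res.replicates["delta_cost"].mean() - res.delta_cost) < \
            3 * boot_se / np.sqrt(2000)
        assert res.ci_cost[0] < res.delta_cost < res.ci_cost[1]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        df = two_arm_frame(rng)
        a = bootstrap_increments(df, B=200, seed=9)
        b = bootstrap_increments(df, B=200, seed=9)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_ci_brackets_true_effect(self):
        rng = np.random.default_rng(7)
        df = two_arm_frame(rng, n=400, cost_shift=300.0)
        res = bootstrap_increments(df, B=1000, seed=2)
        assert res.ci_cost[0] <= 300.0 <= res.ci_cost[1]


class TestGenericBootstrap:
    def test_arm_sizes_preserved_under_stratification(self):
        rng = np.random.default_rng(8)
        df = two_arm_frame(rng, n=50)

        def stat(d):
            if len(d) == 50:  # jackknife calls see n-1 rows
                vc = d["arm"].value_counts()
                assert vc["intervention"] == 25 and vc["control"] == 25
            return d["total_cost"].mean()

        bca_bootstrap(df, stat, B=100, seed=0)

    def test_degenerate_replicates_redrawn(self, caplog):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"arm": ["a"] * 30,
                           "y": np.r_[np.nan, rng.normal(size=29)]})

        def stat(d):  # undefined when the NaN row dominates
            vals = d["y"]
            return np.nan if vals.isna().sum() > 3 else vals.mean()

        import logging
        with caplog.at_level(logging.INFO, logger="trialcea.incremental"):
            point, rep, ci = bca_bootstrap(df, stat, B=100, seed=1,
                                           stratify_by=None)
        assert not np.isnan(rep).any()

    def test_small_B_rejected(self):
        df = pd.DataFrame({"arm": ["a"] * 5, "y": range(5)})
        with pytest.raises(ValueError, match="B"):
            bca_bootstrap(df, lambda d: d["y"].mean(), B=10, seed=0)


class TestCEPlane:
    def test_cardinality_and_quadrants(self):
        rep = pd.DataFrame({"delta_cost": [100.0, 100.0, -5.0, -5.0, 0.0, 0.0],
                            "delta_effect": [0.1, -0.1, -0.1, 0.1, 0.0, 0.2]})
        out = ce_plane_export(rep)
        assert len(out) == 6
        assert list(out["quadrant"]) == ["I", "II", "III", "IV", "origin", "axis"]

    def test_all_dominated_cloud_is_quadrant_two(self):
        rng = np.random.default_rng(10)
        rep = pd.DataFrame({"delta_cost": rng.uniform(10, 20, 50),
                            "delta_effect": rng.uniform(-0.2, -0.1, 50)})
        assert (ce_plane_export(rep)["quadrant"] == "II").all()
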