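"""Disentanglement metrics: oracle equality, limit behaviour, protocols."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codae.metrics import (
    METRIC_NAMES,
    circular_correlation,
    equal_count_bins,
    identify_factor_dims,
    information_metrics,
    intervention_metrics,
    metric_report,
    predictor_metrics,
    select_best_run,
)


@pytest.fixture(scope="module")
def toy_grid():
    """Reference toy data: three independent discrete factors."""
    rng = np.random.default_rng(0)
    n = 2000
    f1 = rng.integers(0, 4, n)
    f2 = rng.integers(0, 4, n)
    f3 = rng.integers(0, 3, n)
    factors = pd.DataFrame({
        "a": f1.astype(float),
        "b": f2.astype(float),
        "shape": np.array(["circle", "triangle", "rect"])[f3],
    })
    perfect = np.stack([2.0 * f1 + 1.0, -1.5 * f2, 3.0 * f3], axis=1)
    null = rng.standard_normal((n, 3))
    return factors, perfect, null


class TestMutualInformationOracle:
    def brute_force_mi(self, x, y):
        """Plain nested-loop MI in nats over the joint table."""
        n = len(x)
        mi = 0.0
        for vx in np.unique(x):
            for vy in np.unique(y):
                pxy = np.mean((x == vx) & (y == vy))
                px = np.mean(x == vx)
                py = np.mean(y == vy)
                if pxy > 0:
                    mi += pxy * math.log(pxy / (px * py))
        return mi

    def test_mig_on_exact_binary_copy(self):
        # the full 2x2 factor grid, each cell equally represented, so
        # empirical independence is exact and the gap equals H(f)
        f1 = np.tile([0, 0, 1, 1], 100)
        f2 = np.tile([0, 1, 0, 1], 100)
        factors = pd.DataFrame({"a": f1.astype(float), "b": f2.astype(float)})
        latents = np.stack([f1, f2], axis=1).astype(float)
        scores = information_metrics(latents, factors, bins=2)
        assert scores["mig"] == pytest.approx(1.0, abs=1e-10)

    def test_xor_structure(self):
        """z1 = f1 XOR f2 carries no marginal information about f1."""
        f1 = np.tile([0, 0, 1, 1], 100)
        f2 = np.tile([0, 1, 0, 1], 100)
        z1 = (f1 ^ f2).astype(float)
        z2 = f2.astype(float)
        assert self.brute_force_mi(z1.astype(int), f1) == pytest.approx(
            0.0, abs=1e-12)
        factors = pd.DataFrame({"f1": f1.astype(float), "f2": f2.astype(float)})
        scores = information_metrics(np.stack([z1, z2], axis=1), factors,
                                     bins=2)
        # f1's gap is exactly 0, f2's gap exactly 1  ->  mig = 1/2
        assert scores["mig"] == pytest.approx(0.5, abs=1e-10)

    def test_library_mi_matches_brute_force(self):
        from sklearn.metrics import mutual_info_score
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 500)
        y = (x + rng.integers(0, 2, 500)) % 3
        assert mutual_info_score(x, y) == pytest.approx(
            self.brute_force_mi(x, y), abs=1e-10)

    def test_constant_latents_zero_information_scores(self, toy_grid):
        factors, _, _ = toy_grid
        const = np.ones((len(factors), 3))
        scores = information_metrics(const, factors)
        assert scores["mig"] == 0.0
        assert scores["dcimig"] == 0.0


class TestPerfectAndNullLimits:
    def test_perfect_code_scores_high(self, toy_grid):
        factors, perfect, _ = toy_grid
        rep = metric_report(perfect, factors, "all_factors", seed=0)
        for name in METRIC_NAMES:
            assert rep.scores[name] >= 0.95, name
        assert rep.average >= 0.95

    def test_null_code_gap_scores_low(self, toy_grid):
        factors, _, null = toy_grid
        rep = metric_report(null, factors, "all_factors", seed=0)
        for name in ("mig", "sap", "dci"):
            assert rep.scores[name] <= 0.1, name

    def test_null_classifier_scores_near_chance(self, toy_grid):
        factors, _, null = toy_grid
        scores = intervention_metrics(null, factors, seed=0)
        assert scores["z_diff"] <= 1 / 3 + 0.15  # chance for 3 factors

    def test_duplicated_latent_column_leaves_irs_unchanged(self, toy_grid):
        factors, perfect, _ = toy_grid
        a = intervention_metrics(perfect, factors, seed=0)["irs"]
        dup = np.hstack([perfect, perfect[:, :1]])
        b = intervention_metrics(dup, factors, seed=0)["irs"]
        assert b == pytest.approx(a, abs=0.05)

    def test_mixed_code_dci_below_half(self, toy_grid):
        factors, perfect, _ = toy_grid
        mixed = np.stack([perfect.sum(axis=1)] * 3, axis=1)
        mixed = mixed + np.random.default_rng(1).normal(0, 0.01, mixed.shape)
        assert predictor_metrics(mixed, factors, seed=0)["dci"] < 0.5


class TestInvariances:
    def test_monotone_rescaling_keeps_binned_scores(self, toy_grid):
        factors, perfect, _ = toy_grid
        a = information_metrics(perfect, factors)
        warped = np.stack([np.exp(perfect[:, 0] / 10.0),
                           perfect[:, 1] ** 3,
                           perfect[:, 2]], axis=1)
        b = information_metrics(warped, factors)
        for k in a:
            assert b[k] == pytest.approx(a[k], abs=0.02)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scores_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        factors = pd.DataFrame({
            "a": rng.integers(0, 3, n).astype(float),
            "b": rng.random(n),
        })
        lat = rng.standard_normal((n, 2)) * rng.uniform(0.5, 5)
        rep = metric_report(lat, factors, "all_factors", seed=0, bins=5)
        for name in METRIC_NAMES:
            assert 0.0 <= rep.scores[name] <= 1.0


class TestFactorIdentification:
    def test_affine_latent_assigned(self, rng):
        x = rng.uniform(-5, 5, 1000)
        noise = rng.standard_normal(1000)
        factors = pd.DataFrame({"x": x})
        lat = np.stack([noise, -3.0 * x + 7.0], axis=1)
        a = identify_factor_dims(lat, factors)
        assert a.mapping["x"] == 1
        assert a.correlations.loc["x", "z1"] == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_dim_unnamed(self, rng):
        factors = pd.DataFrame({"x": rng.uniform(-5, 5, 1000)})
        lat = rng.standard_normal((1000, 2))
        a = identify_factor_dims(lat, factors)
        assert a.mapping["x"] is None

    def test_doubled_angle_harmonic_assigned_to_orientation(self, rng):
        theta = rng.uniform(0, 2 * math.pi, 1000)
        factors = pd.DataFrame({"orientation": theta})
        lat = np.stack([np.sin(2 * theta), rng.standard_normal(1000)], axis=1)
        a = identify_factor_dims(lat, factors)
        assert a.mapping["orientation"] == 0

    def test_each_dimension_assigned_once(self, rng):
        x = rng.uniform(-5, 5, 500)
        factors = pd.DataFrame({"x": x, "x2": x + rng.normal(0, 0.01, 500)})
        lat = np.stack([x, np.zeros(500)], axis=1)
        a = identify_factor_dims(lat, factors)
        dims = [d for d in a.mapping.values() if d is not None]
        assert len(dims) == len(set(dims))


class TestReportProtocols:
    def test_exclusion_semantics(self, rng):
        """Pose factors and their dims are dropped; the rest decides."""
        n = 2000
        x = rng.uniform(-5, 5, n)
        y = rng.uniform(-5, 5, n)
        theta = rng.uniform(0, 2 * math.pi, n)
        s = rng.integers(0, 3, n)
        b = rng.integers(0, 4, n)
        factors = pd.DataFrame({
            "x": x, "y": y, "orientation": theta,
            "shape": np.array(["c", "t", "r"])[s],
            "brightness": b.astype(float),
        })
        lat = np.stack([x, y, np.cos(2 * theta), 2.0 * s, b + 0.5], axis=1)
        rep = metric_report(lat, factors, "excluding_position_orientation",
                            pose_dims=(0, 1, 2), seed=0)
        assert rep.average >= 0.95

    def test_unknown_protocol_rejected(self, toy_grid):
        factors, perfect, _ = toy_grid
        with pytest.raises(ValueError):
            metric_report(perfect, factors, "everything")

    def test_select_best_run(self, toy_grid):
        factors, perfect, null = toy_grid
        good = metric_report(perfect, factors, seed=0)
        bad = metric_report(null, factors, seed=0)
        assert select_best_run([bad, good]) is good


class TestCircularCorrelation:
    def test_perfect_axial_tracking(self, rng):
        theta = rng.uniform(0, 2 * math.pi, 800)
        est = np.mod(theta, math.pi)
        assert circular_correlation(est, theta) > 0.999

    def test_independent_angles_near_zero(self, rng):
        a = rng.uniform(0, math.pi, 800)
        b = rng.uniform(0, 2 * math.pi, 800)
        assert abs(circular_correlation(a, b)) < 0.1

    def test_constant_offset_invariance(self, rng):
        theta = rng.uniform(0, 2 * math.pi, 500)
        assert circular_correlation(theta + 0.7, theta) > 0.999


class TestBinning:
    def test_equal_count_bins_are_balanced(self, rng):
        codes = equal_count_bins(rng.standard_normal(1000), 10)
        counts = np.bincount(codes)
        assert len(counts) == 10
        assert counts.min() >= 80

    def test_discretize_warns_on_single_level(self):
        from codae.metrics import discretize_factors
        factors = pd.DataFrame({"ok": [0.0, 1.0, 2.0, 3.0] * 10,
                                "flat": [1.0] * 40})
        with pytest.warns(UserWarning, match="single observed level"):
            F, names = discretize_factors(factors, bins=4)
        assert names == ["ok"]
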