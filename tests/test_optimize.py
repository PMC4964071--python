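import math

import numpy as np
import pytest

from varstab import (
    FcSimConfig,
    OptimizationFailed,
    ScanSettings,
    Sample,
    bartlett_statistic,
    collect_peaks,
    minimize_interval,
    objective,
    optimize_cofactor,
    simulate_fc_dataset,
    stabilize_dataset,
)
from varstab.optimize import _log_intervals, is_scatter_channel


class TestMinimizeInterval:
    def test_quadratic_minimum(self):
        c, b = minimize_interval(lambda x: (x - 10) ** 2, 5.0, 20.0, tol=1e-4)
        assert c == pytest.approx(10.0, abs=1e-3)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_monotone_decreasing_returns_upper_end(self):
        c, _ = minimize_interval(lambda x: -x, 1.0, 2.0, tol=1e-4)
        assert c == pytest.approx(2.0, rel=1e-3)

    def test_monotone_increasing_returns_lower_end(self):
        c, _ = minimize_interval(lambda x: x, 1.0, 2.0, tol=1e-4)
        assert c == pytest.approx(1.0, rel=1e-3)

    def test_piecewise_constant_step(self):
        """A single lower step in the middle of an otherwise flat objective:
        the minimizer must land inside the step (brute force confirms the
        step is the only region at the lower level)."""
        fun = lambda x: 0.0 if 8.0 <= x <= 9.0 else 1.0
        grid = np.linspace(5, 20, 20_001)
        lower = grid[np.array([fun(g) for g in grid]) == 0.0]
        assert lower.min() >= 8.0 and lower.max() <= 9.0
        c, b = minimize_interval(fun, 5.0, 20.0, tol=1e-4)
        assert b == 0.0 and 8.0 <= c <= 9.0

    def test_tolerates_infinite_regions(self):
        fun = lambda x: math.inf if x < 10 else (x - 12) ** 2
        c, b = minimize_interval(fun, 5.0, 20.0, tol=1e-4)
        assert c == pytest.approx(12.0, abs=0.05)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            minimize_interval(lambda x: x, 2.0, 1.0)


class TestLogIntervals:
    def test_default_domain(self):
        ivs = _log_intervals(-2.0, 10.0)
        assert len(ivs) == 12
        assert ivs[0] == (-2.0, -1.0) and ivs[-1] == (9.0, 10.0)
        assert all(b - a == pytest.approx(1.0) for a, b in ivs)

    def test_partial_final_interval(self):
        ivs = _log_intervals(0.0, 2.5)
        assert ivs == [(0.0, 1.0), (1.0, 2.0), (2.0, 2.5)]

    def test_default_endpoints_as_cofactors(self):
        assert math.exp(-2.0) == pytest.approx(0.135, abs=5e-4)
        assert math.exp(10.0) == pytest.approx(22026, rel=5e-5)


class TestObjective:
    def test_deterministic(self, small_dataset):
        _, ds = small_dataset
        assert objective(ds, "FL1", 30.0) == objective(ds, "FL1", 30.0)

    def test_minimum_near_true_cofactor(self, small_dataset):
        cfg, ds = small_dataset
        c0 = cfg.true_cofactor
        b0 = objective(ds, "FL1", c0)
        assert b0 < objective(ds, "FL1", c0 / math.exp(3))
        assert b0 < objective(ds, "FL1", c0 * math.exp(3))

    def test_single_peak_single_sample_gives_sentinel(self, rng):
        z = 20 * np.sinh(rng.normal(2, 0.2, 3000))
        ds = [Sample("only", ["FL1"], z[:, None])]
        assert objective(ds, "FL1", 20.0) == math.inf


class TestOptimizeCofactor:
    def test_recovers_known_cofactor(self, small_dataset):
        cfg, ds = small_dataset
        scan = optimize_cofactor(ds, "FL1")
        assert abs(math.log(scan.c_star) - math.log(cfg.true_cofactor)) <= 0.5

    def test_scan_invariants(self, small_dataset):
        _, ds = small_dataset
        scan = optimize_cofactor(ds, "FL1")
        assert math.exp(scan.c_low) <= scan.c_star <= math.exp(scan.c_high)
        assert scan.k == 12
        finite_b = [b for _, b in scan.trace if math.isfinite(b)]
        assert scan.b_star == pytest.approx(min(finite_b))
        assert all(scan.b_star <= b + 1e-12 for b in finite_b)

    def test_bit_identical_reruns(self, small_dataset):
        _, ds = small_dataset
        s1 = optimize_cofactor(ds, "FL1")
        s2 = optimize_cofactor(ds, "FL1")
        assert s1.trace == s2.trace
        assert (s1.c_star, s1.b_star) == (s2.c_star, s2.b_star)

    def test_failure_when_no_peaks_possible(self, rng):
        # a single sample with one population never yields >= 2 peaks
        z = 10 * np.sinh(rng.normal(2, 0.2, 2000))
        ds = [Sample("s", ["FL1"], z[:, None])]
        with pytest.raises(OptimizationFailed, match="FL1"):
            optimize_cofactor(ds, "FL1")


@pytest.fixture(scope="module")
def two_channel_dataset():
    c1, c2 = float(np.exp(3.0)), float(np.exp(5.5))
    rng = np.random.default_rng(42)
    samples = []
    for j in range(3):
        t1 = np.concatenate([rng.normal(1, 0.2, 2500), rng.normal(3, 0.2, 2500)])
        t2 = np.concatenate([rng.normal(0.8, 0.25, 2500), rng.normal(2.6, 0.25, 2500)])
        rng.shuffle(t1)
        events = np.column_stack([c1 * np.sinh(t1), c2 * np.sinh(t2)])
        samples.append(Sample(f"s{j}", ["CD3", "CD8"], events))
    return (c1, c2), samples


class TestStabilizeDataset:
    def test_independent_per_channel_recovery(self, two_channel_dataset):
        (c1, c2), ds = two_channel_dataset
        res = stabilize_dataset(ds, ["CD3", "CD8"])
        assert abs(math.log(res.cofactors["CD3"].c_star) - math.log(c1)) <= 0.5
        assert abs(math.log(res.cofactors["CD8"].c_star) - math.log(c2)) <= 0.5

    def test_same_cofactor_applied_to_every_sample(self, two_channel_dataset):
        (_, _), ds = two_channel_dataset
        res = stabilize_dataset(ds, ["CD3"])
        c = res.cofactors["CD3"].c_star
        for orig, trans in zip(ds, res.transformed):
            np.testing.assert_allclose(
                trans.channel("CD3"), np.arcsinh(orig.channel("CD3") / c)
            )
            # untouched channel passes through unchanged
            np.testing.assert_array_equal(trans.channel("CD8"), orig.channel("CD8"))

    def test_rescan_at_chosen_cofactor_is_self_consistent(self, small_dataset):
        _, ds = small_dataset
        res = stabilize_dataset(ds, ["FL1"])
        scan = res.cofactors["FL1"]
        ps = collect_peaks(ds, "FL1", scan.c_star)
        assert bartlett_statistic(ps) == pytest.approx(scan.b_star, rel=1e-12)

    def test_scatter_channels_skipped(self, small_dataset):
        _, ds = small_dataset
        ds2 = [
            Sample(s.sample_id, ["FL1", "FSC-A"],
                   np.column_stack([s.events[:, 0], np.abs(s.events[:, 0])]))
            for s in ds
        ]
        with pytest.warns(UserWarning, match="scatter"):
            res = stabilize_dataset(ds2, ["FL1", "FSC-A"])
        assert "FSC-A" not in res.cofactors and "FL1" in res.cofactors

    def test_scatter_name_heuristic(self):
        assert is_scatter_channel("FSC-A") and is_scatter_channel("SSC-H")
        assert is_scatter_channel("FS Lin")
        assert not is_scatter_channel("CD8") and not is_scatter_channel("FL1")

    def test_per_channel_failure_does_not_stop_others(self, small_dataset, rng):
        _, ds = small_dataset
        ds2 = [
            Sample(s.sample_id, ["FL1", "FLAT"],
                   np.column_stack([s.events[:, 0],
                                    10 * np.sinh(rng.normal(2, 0.2, s.n_events))]))
            for s in ds[:1]
        ]
        res = stabilize_dataset(ds2, ["FL1", "FLAT"])
        # single sample, two populations: FL1 still optimizable; FLAT
        # (one population, one sample) fails but is reported, not raised
        assert "FLAT" in res.failures
        assert "FL1" in res.cofactors
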