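import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adhesim import (
    PairSummary,
    batch_summary,
    classify_bound,
    companion_time,
    fit_gompertz,
    gompertz,
    mean_overlapping_neighbors,
    radius_of_gyration,
    time_of_first_breakup,
)


class TestBoundClassification:
    def test_boundary_is_bound(self):
        assert classify_bound(2.0, 1.0)

    def test_just_detached(self):
        assert not classify_bound(2.0 + 1e-9, 1.0)

    def test_deep_overlap_bound(self):
        assert classify_bound(1.0, 1.0)


class TestFirstBreakup:
    def test_always_bound_none(self):
        assert time_of_first_breakup([1.9, 1.8, 2.0], [0, 0.01, 0.02], 1.0) is None

    def test_first_crossing(self):
        t = time_of_first_breakup(
            [1.9, 1.95, 2.01, 1.9], [0, 0.01, 0.02, 0.03], 1.0
        )
        assert t == 0.02

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            time_of_first_breakup([1.9], [0, 0.01], 1.0)


class TestCompanionTime:
    def test_never_bound(self):
        assert companion_time([2.5, 2.5, 2.5], [0, 0.1, 0.2], 1.0) == 0.0

    def test_always_bound_full_time(self):
        assert companion_time([1.9] * 11, np.linspace(0, 1, 11), 1.0) == pytest.approx(1.0)

    def test_alternating_hand_count(self):
        # bound intervals: [0,1) and [2,3) by the left-endpoint rule
        trace = [1.9, 2.5, 1.9, 2.5, 2.5]
        times = [0.0, 1.0, 2.0, 3.0, 4.0]
        assert companion_time(trace, times, 1.0) == pytest.approx(2.0)

    @given(st.integers(0, 2**32 - 1))
    def test_ct_at_least_tfb_when_broken(self, seed):
        """The interval before the first break-up is entirely bound, so CT
        can never be smaller than TFB."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        trace = rng.uniform(1.0, 3.0, n)
        times = np.cumsum(rng.uniform(0.01, 0.2, n))
        tfb = time_of_first_breakup(trace, times, 1.0)
        if tfb is not None:
            assert companion_time(trace, times, 1.0) >= tfb - times[0] - 1e-12


class TestBatchSummary:
    def test_identical_runs_zero_sem(self):
        s = PairSummary(tfb=1.0, ct=2.0, broke=True, t_total=8.0)
        out = batch_summary([s] * 4)
        assert out.sem2_tfb == 0.0 and out.sem2_ct == 0.0
        assert out.frac_broke == 1.0 and out.n_runs == 4

    def test_half_broke(self):
        runs = [
            PairSummary(tfb=1.0, ct=1.0, broke=True, t_total=8.0),
            PairSummary(tfb=None, ct=8.0, broke=False, t_total=8.0),
        ]
        assert batch_summary(runs).frac_broke == 0.5

    def test_unbroken_runs_truncate_at_total_time(self):
        runs = [
            PairSummary(tfb=2.0, ct=2.0, broke=True, t_total=8.0),
            PairSummary(tfb=None, ct=8.0, broke=False, t_total=8.0),
        ]
        assert batch_summary(runs).mean_tfb == pytest.approx(5.0)

    def test_hand_arithmetic_five_runs(self):
        tfbs = [1.0, 2.0, 3.0, 4.0, 5.0]
        runs = [
            PairSummary(tfb=t, ct=t, broke=True, t_total=8.0) for t in tfbs
        ]
        out = batch_summary(runs)
        assert out.mean_tfb == pytest.approx(3.0)
        sd = math.sqrt(sum((t - 3.0) ** 2 for t in tfbs) / 4)  # ddof=1
        assert out.sem2_tfb == pytest.approx(2 * sd / math.sqrt(5))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_summary([])

    def test_break_fraction_monotone_under_elementwise_worsening(self, rng):
        """Estimator sanity: flipping any subset of runs from bound to broken
        can only raise the break fraction."""
        runs = [
            PairSummary(
                tfb=float(rng.uniform(0, 8)) if broke else None,
                ct=8.0, broke=broke, t_total=8.0,
            )
            for broke in rng.random(20) < 0.3
        ]
        worse = [
            PairSummary(tfb=s.tfb if s.broke else 4.0, ct=s.ct, broke=True,
                        t_total=8.0)
            if s.tfb is None and k % 2 == 0 else s
            for k, s in enumerate(runs)
        ]
        assert batch_summary(worse).frac_broke >= batch_summary(runs).frac_broke


class TestGompertz:
    def test_exact_parameter_recovery(self):
        x = np.linspace(0, 10, 30)
        y = gompertz(x, b=5.0, c=2.0)
        fit = fit_gompertz(x, y)
        assert abs(fit.b - 5.0) <= 1e-6
        assert abs(fit.c - 2.0) <= 1e-6
        assert fit.rss <= 1e-12

    def test_saturates_at_one(self):
        x = np.linspace(0, 10, 20)
        y = np.ones_like(x)
        y[0] = 0.0
        fit = fit_gompertz(x, y)
        assert fit(50.0) > 0.999

    def test_shift_equivariance(self):
        x = np.linspace(-2, 6, 25)
        y = gompertz(x, b=1.5, c=0.8)
        f0 = fit_gompertz(x, y)
        f1 = fit_gompertz(x + 3.0, y)
        assert f1.b - f0.b == pytest.approx(3.0, abs=1e-6)
        assert f1.c == pytest.approx(f0.c, abs=1e-6)

    def test_rate_is_positive(self):
        x = np.linspace(0, 1, 10)
        y = np.clip(x, 0, 1)
        assert fit_gompertz(x, y).c > 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_gompertz([0, 1], [0, 1])
        with pytest.raises(ValueError):
            fit_gompertz([0, 1, 2], [0, 0.5, 1.5])


class TestClusterObservables:
    def test_single_cell_zero_gyration(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_cells_half_distance(self):
        assert radius_of_gyration([[0, 0, 0], [0, 0, 3.0]]) == pytest.approx(1.5)

    def test_matches_brute_force(self, rng):
        pos = rng.uniform(-5, 5, (50, 3))
        centroid = pos.mean(axis=0)
        brute = math.sqrt(
            sum(np.dot(p - centroid, p - centroid) for p in pos) / 50
        )
        assert radius_of_gyration(pos) == pytest.approx(brute, rel=1e-12)

    def test_all_distant_zero_neighbors(self):
        pos = np.diag([10.0, 20.0, 30.0])
        assert mean_overlapping_neighbors(pos, 1.0) == 0.0

    def test_single_overlapping_pair_among_ten(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10) * 10.0
        pos[1, 0] = 1.5  # overlaps cell 0 only
        assert mean_overlapping_neighbors(pos, 1.0) == pytest.approx(0.2)

    def test_neighbor_count_matches_brute_force(self, rng):
        pos = rng.uniform(-4, 4, (30, 3))
        count = 0
        for i in range(30):
            for j in range(30):
                if i != j and np.linalg.norm(pos[i] - pos[j]) < 2.0:
                    count += 1
        assert mean_overlapping_neighbors(pos, 1.0) == pytest.approx(count / 30)
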