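"""Usability metrics, Fitts regression and method comparison."""

import numpy as np
import pytest
from scipy import stats

from emgctl.fitts import Target, TrialLog
from emgctl.metrics import (
    compare_methods,
    completion_rate,
    fitts_regression,
    overshoot,
    path_efficiency,
    summarize,
    throughput,
)
from emgctl.motions import MotionClass

TICK = 0.03


def make_log(id_bits=1.0, movement_time=2.0, acquired=True, entries=1,
             path=None, cls=MotionClass.EXTENSION, distance=1.0, width=0.1):
    t = Target(cls=cls, distance=distance, width=width, id_bits=id_bits)
    n = int(round((movement_time if acquired else 15.0) / TICK))
    if path is None:
        # straight line along +x at constant speed
        xs = list(np.linspace(0, distance, n))
        thetas = [0.0] * n
    else:
        xs = [p[0] for p in path]
        thetas = [p[1] for p in path]
        n = len(path)
    return TrialLog(target=t, goal=(distance, 0.0), tick_s=TICK,
                    times=[TICK * (i + 1) for i in range(n)],
                    xs=xs, thetas=thetas, classes=["extension"] * n,
                    speeds=[0.6] * n, entries=entries,
                    first_entry_t=movement_time if acquired else None,
                    acquired=acquired,
                    acquisition_t=movement_time + 1.0 if acquired else None,
                    movement_time=movement_time if acquired else None,
                    timed_out=not acquired)


class TestCompletionRate:
    def test_all_acquired(self):
        assert completion_rate([make_log() for _ in range(5)]) == 100.0

    def test_36_of_48(self):
        logs = [make_log() for _ in range(36)] + \
               [make_log(acquired=False) for _ in range(12)]
        assert completion_rate(logs) == pytest.approx(75.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            completion_rate([])


class TestThroughput:
    def test_single_target(self):
        assert throughput([make_log(id_bits=1.32, movement_time=3.3)]) == \
            pytest.approx(0.4)

    def test_all_failed_rejected(self):
        with pytest.raises(ValueError):
            throughput([make_log(acquired=False)])

    def test_halves_when_times_double(self):
        logs_a = [make_log(id_bits=1.0, movement_time=t) for t in (1.0, 2.0)]
        logs_b = [make_log(id_bits=1.0, movement_time=2 * t) for t in (1.0, 2.0)]
        assert throughput(logs_a) == pytest.approx(2 * throughput(logs_b))

    def test_failed_targets_excluded(self):
        logs = [make_log(id_bits=1.0, movement_time=1.0),
                make_log(acquired=False)]
        assert throughput(logs) == pytest.approx(1.0)


class TestPathEfficiency:
    def test_straight_path_is_100(self):
        assert path_efficiency(make_log()) == pytest.approx(100.0)

    def test_out_and_back_detour_by_hand(self):
        # travel to 2D and back to D: straight = D, traveled = 3D
        n = 30
        out = list(np.linspace(0, 2.0, 2 * n))
        back = list(np.linspace(2.0, 1.0, n))[1:]
        xs = out + back
        path = [(x, 0.0) for x in xs]
        log = make_log(movement_time=len(path) * TICK, path=path)
        assert path_efficiency(log) == pytest.approx(
            100.0 * 1.0 / (2.0 + 1.0), rel=0.05)

    def test_zero_length_path_is_100(self):
        log = make_log(movement_time=TICK, path=[(0.0, 0.0)])
        assert path_efficiency(log) == 100.0

    def test_never_exceeds_100(self, rng):
        for _ in range(20):
            pts = np.cumsum(rng.standard_normal((50, 2)) * 0.01, axis=0)
            log = make_log(movement_time=50 * TICK, path=[tuple(p) for p in pts])
            assert path_efficiency(log) <= 100.0 + 1e-9


class TestOvershoot:
    def test_single_entry_dwell(self):
        assert overshoot(make_log(entries=1)) == 0

    def test_exit_and_reenter(self):
        assert overshoot(make_log(entries=2)) == 1

    def test_timeout_with_three_entries(self):
        assert overshoot(make_log(acquired=False, entries=3)) == 2


class TestFittsRegression:
    def test_hand_computed_six_point_fit(self):
        pts = [(0.59, 1.0), (0.75, 1.2), (0.92, 1.4),
               (1.32, 1.9), (1.57, 2.2), (1.80, 2.5)]
        logs = [make_log(id_bits=i, movement_time=t) for i, t in pts]
        slope, intercept, r2 = fitts_regression(logs)
        assert slope == pytest.approx(1.2350, abs=0.001)
        assert intercept == pytest.approx(0.2695, abs=0.001)
        assert r2 == pytest.approx(0.9999, abs=0.001)

    def test_exactly_linear_times_give_r2_of_1(self):
        logs = [make_log(id_bits=i, movement_time=0.5 + 2 * i)
                for i in (0.5, 1.0, 1.5, 2.0)]
        slope, intercept, r2 = fitts_regression(logs)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_constant_times_give_zero_slope(self):
        logs = [make_log(id_bits=i, movement_time=2.0) for i in (0.5, 1.0, 1.5)]
        slope, _, _ = fitts_regression(logs)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_per_id_averaging(self):
        logs = [make_log(id_bits=1.0, movement_time=1.0),
                make_log(id_bits=1.0, movement_time=3.0),
                make_log(id_bits=2.0, movement_time=4.0)]
        slope, intercept, _ = fitts_regression(logs)
        assert slope == pytest.approx(2.0)   # means (1,2) and (2,4)
        assert intercept == pytest.approx(0.0, abs=1e-12)


class TestCompareMethods:
    def test_identical_groups(self):
        f, p, sig = compare_methods([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert f == 0.0 and p == 1.0 and not sig

    def test_two_group_anova_equals_squared_t(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 0.5
        f, p, _ = compare_methods(a, b)
        t, tp = stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(tp, rel=1e-10)

    def test_well_separated_groups_significant(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 5.0
        _, p, sig = compare_methods(a, b)
        assert p < 0.001 and sig


class TestSummarize:
    def test_aggregation_matches_hand_rolled(self):
        logs = [make_log(id_bits=1.0, movement_time=1.0, entries=1),
                make_log(id_bits=1.5, movement_time=2.0, entries=2),
                make_log(id_bits=2.0, movement_time=3.0, entries=3)]
        rep = summarize(logs, method="test")
        assert rep.completion_rate == 100.0
        assert rep.throughput == pytest.approx(
            np.mean([1.0 / 1.0, 1.5 / 2.0, 2.0 / 3.0]))
        assert rep.overshoot == pytest.approx(np.mean([0, 1, 2]))
        assert rep.path_efficiency == pytest.approx(
            np.mean([path_efficiency(l) for l in logs]))
        assert rep.n_targets == 3

    def test_report_serializes(self):
        logs = [make_log(id_bits=i, movement_time=i) for i in (1.0, 2.0)]
        d = summarize(logs, method="svm").to_dict()
        assert d["method"] == "svm"
        assert set(d) >= {"completion_rate_pct", "throughput_bits_per_s",
                          "path_efficiency_pct", "overshoot_per_target", "fitts_r2"}
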