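"""Control-performance metrics for Fitts'-law sessions.

Four usability metrics summarize a session of target-acquisition
trials:

* completion rate -- % of targets acquired before the timeout;
* throughput -- mean over acquired targets of ID / movement time
  (bits/s); failed targets are excluded;
* path efficiency -- straight-line distance over traveled path length,
  as a %, from trial start to the start of the final dwell;
* overshoot -- target re-entries before acquisition (entries - 1).

Failed targets contribute to completion rate only.  A linear fit of
per-ID mean movement time against ID quantifies adherence to Fitts'
law; methods are compared per metric with a one-way ANOVA at
significance level 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitts import TrialLog

ALPHA = 0.05


def completion_rate(logs: list[TrialLog]) -> float:
    """Percentage of targets acquired."""
    if not logs:
        raise ValueError("no trial logs")
    return 100.0 * sum(l.acquired for l in logs) / len(logs)


def throughput(logs: list[TrialLog]) -> float:
    """Mean ID / movement-time over acquired targets, bits/s."""
    rates = [l.target.id_bits / l.movement_time for l in logs
             if l.acquired and l.movement_time and l.movement_time > 0]
    if not rates:
        raise ValueError("no acquired targets with positive movement time")
    return float(np.mean(rates))


def _movement_span(log: TrialLog) -> int:
    """Number of ticks from start to the start of the final dwell."""
    if log.acquired and log.movement_time is not None:
        return int(round(log.movement_time / log.tick_s))
    return len(log.times)


def path_efficiency(log: TrialLog) -> float:
    """Straight-line / traveled distance (%) over the movement span.

    A zero-length path (cursor already at its endpoint) is defined as
    100% efficient.
    """
    n = _movement_span(log)
    pts = np.concatenate([[[0.0, 0.0]], log.path()[:n]], axis=0)
    straight = float(np.linalg.norm(pts[-1] - pts[0]))
    traveled = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if traveled == 0.0:
        return 100.0
    return 100.0 * straight / traveled


def overshoot(log: TrialLog) -> int:
    """Target re-entries after the first, before acquisition."""
    return max(0, log.entries - 1)


def fitts_regression(logs: list[TrialLog]) -> tuple[float, float, float]:
    """OLS of per-ID mean movement time on ID: (slope, intercept, R^2).

    Only acquired targets enter the per-ID means.
    """
    ids: dict[float, list[float]] = {}
    for l in logs:
        if l.acquired and l.movement_time is not None:
            ids.setdefault(round(l.target.id_bits, 6), []).append(l.movement_time)
    if len(ids) < 2:
        raise ValueError("need at least two distinct ID levels with acquisitions")
    x = np.array(sorted(ids))
    y = np.array([np.mean(ids[i]) for i in x])
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def mean_times_by_id(logs: list[TrialLog]) -> dict[float, float]:
    out: dict[float, list[float]] = {}
    for l in logs:
        if l.acquired and l.movement_time is not None:
            out.setdefault(round(l.target.id_bits, 6), []).append(l.movement_time)
    return {k: float(np.mean(v)) for k, v in sorted(out.items())}


def compare_methods(metric_a, metric_b) -> tuple[float, float, bool]:
    """One-way ANOVA between two methods' per-subject (or per-run) values.

    Returns (F, p, significant-at-0.05).  Identical groups give F = 0,
    p = 1.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if np.allclose(a.var() + b.var(), 0) and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0, False
    f, p = stats.f_oneway(a, b)
    return float(f), float(p), bool(p < ALPHA)


@dataclass
class MetricsReport:
    """Session-level summary of the four metrics plus the Fitts fit."""

    method: str
    n_targets: int
    completion_rate: float
    throughput: float
    path_efficiency: float
    overshoot: float
    fitts_slope: float
    fitts_intercept: float
    fitts_r2: float
    mean_time_by_id: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_targets": self.n_targets,
            "completion_rate_pct": self.completion_rate,
            "throughput_bits_per_s": self.throughput,
            "path_efficiency_pct": self.path_efficiency,
            "overshoot_per_target": self.overshoot,
            "fitts_slope_s_per_bit": self.fitts_slope,
            "fitts_intercept_s": self.fitts_intercept,
            "fitts_r2": self.fitts_r2,
            "mean_time_by_id": {str(k): v for k, v in self.mean_time_by_id.items()},
        }


def summarize(logs: list[TrialLog], method: str = "") -> MetricsReport:
    """Aggregate one session: means of per-target path efficiency and
    overshoot over acquired targets, plus the formula-defined metrics."""
    acquired = [l for l in logs if l.acquired]
    slope, intercept, r2 = fitts_regression(logs)
    return MetricsReport(
        method=method,
        n_targets=len(logs),
        completion_rate=completion_rate(logs),
        throughput=throughput(logs),
        path_efficiency=float(np.mean([path_efficiency(l) for l in acquired])),
        overshoot=float(np.mean([overshoot(l) for l in acquired])),
        fitts_slope=slope,
        fitts_intercept=intercept,
        fitts_r2=r2,
        mean_time_by_id=mean_times_by_id(logs),
    )
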