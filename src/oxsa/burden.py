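"""Hypoxia burden scoring and intra-patient interval statistics.

The burden scores quantify how far the systemic arterial dissolved O2
falls below its wakefulness baseline.  For a window of duration T,

    score = (1/T) \\int (C_wake_mean - C(t)) dt     [µM, signed],

so scoring a wakefulness window itself yields approximately zero, and
overshoot above the baseline subtracts from the score.  The hypoxia-period
variant restricts the integral to samples below a threshold of one
standard deviation under the wake mean and normalizes by the time spent
below it.  Higher scores mean a heavier hypoxia burden.

The interval statistics assess whether windows containing pairs of
obstructive events differ from the whole-study average: per variable, the
interval-minus-overall mean differences feed a one-sample two-sided
t-test against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, DegenerateStatisticError, ParameterValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WakeBaseline:
    """Mean and SD of arterial dissolved O2 over wakefulness intervals."""

    mean: float
    sd: float
    intervals: tuple[tuple[float, float], ...]

    @property
    def threshold(self) -> float:
        """Hypoxia threshold: one SD below the wake mean."""
        return self.mean - self.sd


@dataclass(frozen=True)
class BurdenReport:
    """The three burden scores for one analysis (units follow the trace)."""

    event_sequence_score: float
    total_sequence_score: float
    hypoxia_period_score: float
    time_in_hypoxia: float
    threshold: float


def _interval_mask(times: np.ndarray, interval) -> np.ndarray:
    lo, hi = interval
    if hi <= lo:
        raise ParameterValidationError(f"empty interval ({lo}, {hi})")
    return (times >= lo - 1e-12) & (times <= hi + 1e-12)


def wake_baseline(times, values, wake_intervals) -> WakeBaseline:
    """Pooled mean/SD of the trace over the given wakefulness intervals."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    wake_intervals = tuple(tuple(map(float, iv)) for iv in wake_intervals)
    if not wake_intervals:
        raise ParameterValidationError("need at least one wake interval")
    masks = []
    for iv in wake_intervals:
        m = _interval_mask(times, iv)
        if np.count_nonzero(m) < 2:
            raise ParameterValidationError(
                f"wake interval {iv} contains fewer than two samples"
            )
        masks.append(m)
    pooled = values[np.logical_or.reduce(masks)]
    return WakeBaseline(
        mean=float(np.mean(pooled)), sd=float(np.std(pooled)),
        intervals=wake_intervals,
    )


def burden_score(
    times,
    values,
    baseline: WakeBaseline,
    interval=None,
    *,
    clip_deficit: bool = False,
) -> float:
    """Time-normalized signed area below the wake mean over ``interval``.

    With ``clip_deficit`` only excursions below the baseline accumulate
    (overshoot no longer subtracts) — a sensitivity variant.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if not np.all(np.isfinite(values)):
        raise DataError("trace contains non-finite samples")
    if interval is not None:
        m = _interval_mask(times, interval)
        times, values = times[m], values[m]
    if times.size < 2:
        raise ParameterValidationError("interval must contain >= 2 samples")
    deficit = baseline.mean - values
    if clip_deficit:
        deficit = np.maximum(deficit, 0.0)
    T = times[-1] - times[0]
    return float(np.trapezoid(deficit, times) / T)


def hypoxia_period_score(
    times, values, baseline: WakeBaseline, interval=None
) -> tuple[float, float]:
    """Burden during hypoxia only: (score, time_in_hypoxia_s).

    Hypoxia is C(t) < mean - sd; the deficit below that threshold is
    integrated and normalized by the time spent in hypoxia.  With no
    hypoxic samples the score is 0 (flagged in the log).
    """
    if baseline.sd <= 0:
        raise ParameterValidationError(
            "wake baseline has zero spread; the hypoxia threshold is undefined"
        )
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interval is not None:
        m = _interval_mask(times, interval)
        times, values = times[m], values[m]
    thr = baseline.threshold
    below = values < thr
    if not np.any(below):
        logger.info("no samples below the hypoxia threshold; score is 0")
        return 0.0, 0.0
    # per-sample quadrature weights (trapezoid rule)
    w = np.zeros_like(times)
    w[1:] += 0.5 * np.diff(times)
    w[:-1] += 0.5 * np.diff(times)
    time_in = float(np.sum(w[below]))
    area = float(np.sum(w[below] * (thr - values[below])))
    return area / time_in, time_in


def burden_report(
    times,
    values,
    baseline: WakeBaseline,
    event_interval,
    total_interval=None,
) -> BurdenReport:
    """Bundle the three scores for one analyzed sequence."""
    hp, tih = hypoxia_period_score(times, values, baseline, total_interval)
    return BurdenReport(
        event_sequence_score=burden_score(times, values, baseline, event_interval),
        total_sequence_score=burden_score(times, values, baseline, total_interval),
        hypoxia_period_score=hp,
        time_in_hypoxia=tih,
        threshold=baseline.threshold,
    )


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    sd: float
    t: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def interval_ttest(
    traces: dict,
    intervals,
    overall_span=None,
) -> dict[str, TTestResult]:
    """Interval-vs-overall one-sample t-test per variable.

    ``traces`` maps a variable name to ``(times, values)``.  For each
    variable, the interval averages minus the overall average form the
    sample d_i; the statistic is t = mean(d) / (sd(d)/sqrt(n)) with a
    two-sided p-value on n-1 degrees of freedom.  Intervals must have
    equal durations (the analysis design keeps them constant).
    """
    intervals = [tuple(map(float, iv)) for iv in intervals]
    if len(intervals) < 2:
        raise ParameterValidationError("need at least two intervals")
    durations = [hi - lo for lo, hi in intervals]
    if max(durations) - min(durations) > 1e-6 * max(durations):
        raise ParameterValidationError("interval durations must be equal")
    out: dict[str, TTestResult] = {}
    for name, (times, values) in traces.items():
        times = np.asarray(times, float)
        values = np.asarray(values, float)
        span_mask = (
            _interval_mask(times, overall_span)
            if overall_span is not None
            else np.ones_like(times, dtype=bool)
        )
        overall = float(np.mean(values[span_mask]))
        diffs = []
        for iv in intervals:
            m = _interval_mask(times, iv)
            if not np.any(m):
                raise ParameterValidationError(f"interval {iv} has no samples")
            diffs.append(float(np.mean(values[m])) - overall)
        d = np.asarray(diffs)
        n = d.size
        sd = float(np.std(d, ddof=1))
        if sd == 0.0:
            raise DegenerateStatisticError(
                f"{name}: zero variance across intervals; t is undefined"
            )
        t_stat = float(np.mean(d) / (sd / np.sqrt(n)))
        p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
        out[name] = TTestResult(
            mean_difference=float(np.mean(d)), sd=sd, t=t_stat, p_value=p, n=n
        )
    return out
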