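"""Feedback gains, reaction-time detection and the anticipatory-EMG check.

A feedback gain is the absolute difference between the trapezoid-rule
integrals of the two contrasted conditions' mean EMG traces, taken over a
window that starts at the participant's own divergence latency (25 ms wide
for the short-latency stretch response to avoid overlap with the
long-latency one, 50 ms otherwise).  Anchoring the window at each
participant's latency matters: with a fixed window, a latency shift under
reward would masquerade as a gain change.  Reward modulation is summarized
as the log-ratio G = ln(gain_rewarded / gain_non_rewarded), zero meaning
no modulation.

Reaction times in the proprioception-cued task are the first time the
processed triceps EMG rises strictly above the trial-baseline mean plus
3 SD for 5 consecutive milliseconds; trials never meeting the criterion
are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import BaselineStats
from .synthetic_emg import TrialRecording

__all__ = [
    "GainEstimate",
    "ReactionTimeResult",
    "mean_trace",
    "feedback_gain",
    "gain_log_ratio",
    "detect_reaction_time",
    "anticipatory_means",
]


@dataclass(frozen=True)
class GainEstimate:
    muscle: str
    start_ms: float
    width_ms: float
    gain_rewarded: float
    gain_nonrewarded: float
    log_ratio_G: float | None

    @classmethod
    def from_gains(cls, muscle, start_ms, width_ms, gain_r, gain_nr) -> "GainEstimate":
        return cls(muscle, start_ms, width_ms, gain_r, gain_nr, gain_log_ratio(gain_r, gain_nr))


@dataclass(frozen=True)
class ReactionTimeResult:
    trial_id: int
    rt_ms: float  # NaN when discarded
    discarded: bool
    k_sd: float = 3.0
    run_ms: float = 5.0


def _window_slice(times: np.ndarray, start_ms: float, width_ms: float) -> slice:
    i0 = int(np.argmin(np.abs(times - start_ms)))
    i1 = i0 + int(round(width_ms))
    if i1 >= len(times) or abs(times[i0] - start_ms) > 0.5:
        raise ValueError(f"window [{start_ms}, {start_ms + width_ms}] exceeds the series")
    return slice(i0, i1 + 1)


def mean_trace(trials: Sequence[TrialRecording], muscle: str) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean EMG across trials on their shared aligned time base.

    Trials are aligned on the sample nearest t = 0 and cropped to the
    overlap, so recordings of unequal length can be averaged.
    """
    if not trials:
        raise ValueError("mean_trace requires at least one trial")
    idx0 = [int(np.argmin(np.abs(tr.time_ms))) for tr in trials]
    before = min(idx0)
    after = min(len(tr.time_ms) - i for tr, i in zip(trials, idx0))
    stack = np.stack(
        [np.asarray(tr.emg[muscle])[i - before : i + after] for tr, i in zip(trials, idx0)]
    )
    times = trials[0].time_ms[idx0[0] - before : idx0[0] + after]
    return np.asarray(times, dtype=float), stack.mean(axis=0)


def feedback_gain(
    times: np.ndarray,
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    start_ms: float,
    width_ms: float,
) -> float:
    """|trapezoid(mean_a) - trapezoid(mean_b)| over [start, start+width].

    Units: normalized EMG x ms.  Both traces must cover the window on the
    common ``times`` base.
    """
    sl = _window_slice(np.asarray(times, dtype=float), start_ms, width_ms)
    tw = np.asarray(times, dtype=float)[sl]
    ia = np.trapezoid(np.asarray(mean_a)[sl], tw)
    ib = np.trapezoid(np.asarray(mean_b)[sl], tw)
    return float(abs(ia - ib))


def integrated_activity(times, trace, start_ms: float, width_ms: float) -> float:
    """Trapezoid-rule integral of a single mean trace over the window
    (used by the reaction-time task, which has no condition contrast)."""
    sl = _window_slice(np.asarray(times, dtype=float), start_ms, width_ms)
    return float(np.trapezoid(np.asarray(trace)[sl], np.asarray(times, dtype=float)[sl]))


def gain_log_ratio(gain_rewarded: float, gain_nonrewarded: float) -> float | None:
    """G = ln(gain_rewarded / gain_nonrewarded); None when undefined.

    Gains are absolute differences and can be zero in degenerate (null)
    data; such pairs carry no ratio information and are excluded from the
    paired statistics by the caller.
    """
    if gain_rewarded <= 0 or gain_nonrewarded <= 0:
        return None
    return float(np.log(gain_rewarded / gain_nonrewarded))


def detect_reaction_time(
    trial: TrialRecording,
    baseline: BaselineStats,
    muscle: str = "triceps_lat",
    k_sd: float = 3.0,
    run_ms: float = 5.0,
) -> ReactionTimeResult:
    """First time the processed EMG exceeds baseline mean + k SD for
    ``run_ms`` consecutive samples, searching from the aligned event
    (t = 0) onward.

    The inequality is strict ("rose above"): a trace exactly at threshold
    does not trigger.  Trials with no sustained crossing are discarded.
    """
    t = np.asarray(trial.time_ms, dtype=float)
    y = np.asarray(trial.emg[muscle], dtype=float)
    threshold = baseline.mean(muscle) + k_sd * baseline.sd(muscle)
    run = int(round(run_ms))
    start = int(np.argmin(np.abs(t)))
    above = y[start:] > threshold
    if len(above) >= run:
        # rolling all-true over a run-length window
        windows = np.lib.stride_tricks.sliding_window_view(above, run)
        hits = np.nonzero(windows.all(axis=1))[0]
        if hits.size:
            return ReactionTimeResult(trial.trial_id, float(t[start + hits[0]]), False, k_sd, run_ms)
    return ReactionTimeResult(trial.trial_id, math.nan, True, k_sd, run_ms)


def anticipatory_means(
    trials: Sequence[TrialRecording],
    muscle: str = "triceps_lat",
    window_ms: tuple[float, float] = (-20.0, 0.0),
) -> float:
    """Mean EMG in the pre-perturbation window [-20, 0) ms, averaged over
    trials — the quantity behind the anticipatory-activity control test in
    fixed-delay designs (per participant and condition; the paired
    signed-rank across participants lives in :mod:`.stats_report`)."""
    if not trials:
        raise ValueError("need at least one trial")
    vals = []
    for tr in trials:
        t = np.asarray(tr.time_ms, dtype=float)
        idx0 = int(np.argmin(np.abs(t)))
        i0 = idx0 + int(round(window_ms[0]))
        i1 = idx0 + int(round(window_ms[1]))
        if i0 < 0:
            raise ValueError("trial lacks pre-event samples for the anticipatory window")
        vals.append(float(np.asarray(tr.emg[muscle])[i0:i1].mean()))
    return float(np.mean(vals))
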