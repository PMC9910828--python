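"""EMG conditioning: band-pass, rectification, normalization, alignment.

The chain is fixed — band-pass 20–250 Hz, full-wave rectification,
division by a per-muscle normalization scalar obtained from four static
2 s calibration holds — and is applied identically to calibration and task
recordings.  Filtering is a 4th-order Butterworth run forward-backward
(zero phase): any group delay would bias every latency estimate, which is
the pipeline's core quantity.  Trial-baseline statistics (mean and SD in a
50 ms window 350–300 ms before the task's anchoring event) feed the
reaction-time threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import signal

from .synthetic_emg import CalibrationSet, TrialRecording
from .task_designs import TaskDesign

__all__ = [
    "NormalizationScalars",
    "BaselineStats",
    "bandpass",
    "rectify",
    "normalization_scalar",
    "normalize",
    "align",
    "trial_baseline",
    "preprocess_trial",
    "preprocess_calibration",
    "ProcessingError",
]

#: margin (ms) at each series edge contaminated by filter transients;
#: analysis windows must not rely on it
TRANSIENT_MS = 50.0


class ProcessingError(ValueError):
    pass


NormalizationScalars = Mapping[str, float]


@dataclass(frozen=True)
class BaselineStats:
    """Per-muscle (mean, sd) of normalized EMG in the trial-baseline window."""

    stats: Mapping[str, tuple[float, float]]
    window_ms: tuple[float, float]

    def mean(self, muscle: str) -> float:
        return self.stats[muscle][0]

    def sd(self, muscle: str) -> float:
        return self.stats[muscle][1]


@lru_cache(maxsize=8)
def _bp_sos(lo_hz: float, hi_hz: float, fs: float):
    return signal.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(series: np.ndarray, lo_hz: float = 20.0, hi_hz: float = 250.0, fs: float = 1000.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis.

    Forward-backward application cancels group delay; edges are padded by
    reflection (scipy's default odd extension) before filtering.
    """
    if not fs > 2 * hi_hz:
        raise ProcessingError("sampling rate must exceed twice the upper band edge")
    series = np.asarray(series, dtype=float)
    sos = _bp_sos(lo_hz, hi_hz, fs)
    padlen = 3 * (2 * sos.shape[0] + 1) * 3
    if series.shape[-1] <= padlen:
        raise ProcessingError(
            f"series of length {series.shape[-1]} too short for the filter transient ({padlen})"
        )
    return signal.sosfiltfilt(sos, series, axis=-1)


def rectify(series: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    return np.abs(np.asarray(series, dtype=float))


def normalization_scalar(cal: CalibrationSet) -> dict[str, float]:
    """Per-muscle normalization scalar from four static holds.

    For each hold, the band-passed and rectified signal from 250 ms after
    start-position entry to 250 ms before the end of the 2 s window is
    concatenated across the four holds and averaged (4 x 1500 ms = 6000
    samples at 1000 Hz).  ``cal`` must already be processed
    (``processing == "rectified"``); see :func:`preprocess_calibration`.
    """
    if cal.processing != "rectified":
        raise ProcessingError("calibration must be band-passed and rectified first")
    fs = cal.fs
    margin = int(round(0.25 * fs))
    scalars: dict[str, float] = {}
    muscles = list(cal.holds[0])
    for m in muscles:
        chunks = []
        for hold, entry in zip(cal.holds, cal.entry_ms):
            i0 = int(round(entry * fs / 1000.0)) + margin
            i1 = i0 + 2 * fs - 2 * margin
            chunks.append(np.asarray(hold[m][i0:i1]))
        scalar = float(np.concatenate(chunks).mean())
        if scalar <= 0:
            raise ProcessingError(f"degenerate calibration for muscle {m!r}")
        scalars[m] = scalar
    return scalars


def preprocess_calibration(cal: CalibrationSet) -> CalibrationSet:
    """Band-pass and rectify every calibration hold."""
    holds = [{m: rectify(bandpass(s, fs=cal.fs)) for m, s in hold.items()} for hold in cal.holds]
    return CalibrationSet(holds=holds, entry_ms=list(cal.entry_ms), fs=cal.fs, processing="rectified")


def normalize(series: np.ndarray, scalars: NormalizationScalars, muscle: str) -> np.ndarray:
    """Express a rectified series in units of the muscle's calibration level."""
    if muscle not in scalars:
        raise KeyError(f"no normalization scalar for muscle {muscle!r}")
    return np.asarray(series, dtype=float) / scalars[muscle]


def align(trial: TrialRecording, event_name: str, onset_correction_ms: float = 4.0) -> TrialRecording:
    """Re-index a trial so the (corrected) event time becomes t = 0.

    The onset correction compensates the lag between the commanded torque
    and limb acceleration; it applies only to mechanical-perturbation
    events.  Visual events (target onset, cursor/target jump) are stored
    photodiode-corrected and must be aligned with ``onset_correction_ms=0``.
    """
    if event_name not in trial.events:
        raise KeyError(f"trial has no event {event_name!r}")
    correction = onset_correction_ms if event_name == "perturbation" else 0.0
    t0 = trial.events[event_name] + correction
    return trial.copy_with(
        time_ms=trial.time_ms - t0,
        events={k: v - t0 for k, v in trial.events.items()},
    )


def preprocess_trial(trial: TrialRecording, scalars: NormalizationScalars, fs: float = 1000.0) -> TrialRecording:
    """Apply the full chain (band-pass, rectify, normalize) to every muscle."""
    if trial.processing != "raw":
        raise ProcessingError(f"expected raw EMG, got {trial.processing!r}")
    emg = {m: normalize(rectify(bandpass(s, fs=fs)), scalars, m) for m, s in trial.emg.items()}
    return trial.copy_with(emg=emg, processing="normalized")


def trial_baseline(trial: TrialRecording, design: TaskDesign) -> BaselineStats:
    """Mean and SD per muscle over the 50 ms trial-baseline window.

    The window is [-350, -300) ms relative to the design's anchoring event
    (displacement onset for mechanical tasks, target appearance for the
    jump tasks), half-open so it holds exactly 50 samples at 1000 Hz.  The
    SD is the across-sample standard deviation within this single trial's
    window.
    """
    rule = design.baseline_rule
    if rule.event not in trial.events:
        raise KeyError(f"trial has no event {rule.event!r}")
    correction = design.design_constants.get("onset_correction_ms", 0.0)
    if rule.event != "perturbation":
        correction = 0.0
    t_event = trial.events[rule.event] + correction
    rel = trial.time_ms - t_event
    mask = (rel >= rule.start_ms) & (rel < rule.end_ms)
    n_expected = int(round(rule.end_ms - rule.start_ms))
    if mask.sum() < n_expected:
        raise ProcessingError("insufficient pre-event samples for the trial baseline")
    stats = {}
    for m, series in trial.emg.items():
        win = np.asarray(series)[mask]
        stats[m] = (float(win.mean()), float(win.std(ddof=1)))
    return BaselineStats(stats=stats, window_ms=(rule.start_ms, rule.end_ms))
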