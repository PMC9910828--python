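"""Response latency as the ROC divergence time between two trial sets.

At every sample of the analysis window, discrimination between the two
contrasted sets of (processed, aligned) EMG trials is quantified as the
area under the ROC curve — equivalently the Mann–Whitney probability that
a random trial from side A exceeds one from side B, ties counted half.
Latency is then the elbow of the AUC trace: once the trace leaves the
25–75 % band for two consecutive samples, a two-segment linear regression
is fitted to the AUC up to that crossing, exhaustively searching the
breakpoint that minimizes the summed squared residuals; the breakpoint
time is the divergence latency.  Because the AUC is rank-based, the
estimate is invariant to any strictly monotone rescaling of the EMG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .synthetic_emg import TrialRecording
from .task_designs import Contrast, TaskDesign
from .preprocess import align

__all__ = [
    "AUCTrace",
    "LatencyEstimate",
    "auc_trace",
    "detect_crossing",
    "segmented_fit",
    "estimate_latency",
    "DEFAULT_WINDOW_MS",
]

#: analysis window around the alignment event (ms); pre-event samples
#: anchor the flat segment of the breakpoint regression
DEFAULT_WINDOW_MS = (-100.0, 300.0)


@dataclass(frozen=True)
class AUCTrace:
    """Time-resolved ROC discrimination between two trial sets."""

    times: np.ndarray  # ms relative to the alignment event
    auc: np.ndarray  # in [0, 1]
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.auc):
            raise ValueError("times and auc must have equal length")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need at least two trials per side")


@dataclass(frozen=True)
class LatencyEstimate:
    latency_ms: float
    crossing_index: int | None
    direction: str | None  # "above" | "below"
    breakpoint_index: int | None
    sse: float
    slope_pre: float
    slope_post: float
    valid: bool
    reason: str = ""

    @classmethod
    def invalid(cls, reason: str) -> "LatencyEstimate":
        return cls(math.nan, None, None, None, math.nan, math.nan, math.nan, False, reason)


def _sample_window(trial: TrialRecording, muscle: str, window_ms) -> np.ndarray:
    """Extract the analysis window around the aligned event (1 kHz grid).

    The sample nearest t = 0 anchors the window, so alignment events that
    fall between samples are rounded to the closest one (< 0.5 ms off).
    """
    t = trial.time_ms
    idx0 = int(np.argmin(np.abs(t)))
    lo, hi = int(round(window_ms[0])), int(round(window_ms[1]))
    i0, i1 = idx0 + lo, idx0 + hi
    if i0 < 0 or i1 >= len(t):
        raise ValueError(
            f"trial {trial.trial_id} does not cover the analysis window {window_ms}"
        )
    return np.asarray(trial.emg[muscle])[i0 : i1 + 1]


def auc_trace(
    trials_a: Sequence[TrialRecording],
    trials_b: Sequence[TrialRecording],
    muscle: str,
    window_ms=DEFAULT_WINDOW_MS,
) -> AUCTrace:
    """Per-sample ROC AUC between two aligned, processed trial sets.

    All trials enter individually (no averaging).  At each sample the AUC
    is computed by the Mann–Whitney construction from midranks, so tied
    amplitudes count one half.
    """
    if len(trials_a) < 2 or len(trials_b) < 2:
        raise ValueError("need at least two trials on each side of the contrast")
    a = np.stack([_sample_window(tr, muscle, window_ms) for tr in trials_a])
    b = np.stack([_sample_window(tr, muscle, window_ms) for tr in trials_b])
    n_a, n_b = a.shape[0], b.shape[0]
    both = np.concatenate([a, b], axis=0)
    ranks = rankdata(both, axis=0)
    u = ranks[:n_a].sum(axis=0) - n_a * (n_a + 1) / 2.0
    auc = u / (n_a * n_b)
    times = np.arange(int(round(window_ms[0])), int(round(window_ms[1])) + 1, dtype=float)
    return AUCTrace(times=times, auc=auc, n_a=n_a, n_b=n_b)


def detect_crossing(trace: AUCTrace, lo: float = 0.25, hi: float = 0.75, run: int = 2):
    """First index where the AUC leaves the [lo, hi] band for ``run``
    consecutive samples, in either direction.

    Returns ``(index, direction)`` or ``None`` if the threshold is never
    sustained.
    """
    auc = np.asarray(trace.auc)
    for i in range(len(auc) - run + 1):
        seg = auc[i : i + run]
        if np.all(seg > hi):
            return i, "above"
        if np.all(seg < lo):
            return i, "below"
    return None


def segmented_fit(
    trace: AUCTrace,
    fit_start_index: int,
    crossing_index: int,
    direction: str = "above",
    min_segment: int = 3,
) -> LatencyEstimate:
    """Two-segment least-squares fit of the AUC up to the band crossing.

    Every candidate breakpoint between ``fit_start_index`` and
    ``crossing_index`` is tried; at each, two independent straight lines
    are fitted to the samples up to and from the breakpoint (the
    breakpoint sample belongs to both segments, each at least
    ``min_segment`` samples).  The breakpoint minimizing the total SSE —
    ties broken toward the earliest, the conservative latency — is the
    divergence point.
    """
    if crossing_index - fit_start_index < 2 * (min_segment - 1):
        return LatencyEstimate.invalid("fit window too short for two segments")
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.auc, dtype=float)
    best = None
    for bp in range(fit_start_index + min_segment - 1, crossing_index - min_segment + 2):
        i1 = slice(fit_start_index, bp + 1)
        i2 = slice(bp, crossing_index + 1)
        sse = 0.0
        slopes = []
        for seg in (i1, i2):
            coef, res, *_ = np.polyfit(t[seg], y[seg], 1, full=True)
            slopes.append(coef[0])
            sse += float(res[0]) if len(res) else 0.0
        if best is None or sse < best[1] - 1e-15:
            best = (bp, sse, slopes[0], slopes[1])
    bp, sse, s_pre, s_post = best
    return LatencyEstimate(
        latency_ms=float(t[bp]),
        crossing_index=crossing_index,
        direction=direction,
        breakpoint_index=bp,
        sse=sse,
        slope_pre=s_pre,
        slope_post=s_post,
        valid=True,
    )


def estimate_latency(
    trials_a: Sequence[TrialRecording],
    trials_b: Sequence[TrialRecording],
    muscle: str,
    design: TaskDesign,
    contrast: Contrast | None = None,
    window_ms=DEFAULT_WINDOW_MS,
    fit_start_ms: float | None = None,
) -> LatencyEstimate:
    """Full divergence-latency estimate for one participant and reward
    condition: AUC trace → sustained band crossing → segmented fit.

    Trials must already be preprocessed and aligned to the contrast's
    event (see :func:`align_contrast_trials`).  For mechanical
    perturbations the pre-crossing fit starts at the event (t = 0); for
    visual contrasts it starts at the window's first sample.  Invalid
    (no-crossing) estimates are returned as values, not raised — a flat
    channel genuinely has no measurable divergence.
    """
    trace = auc_trace(trials_a, trials_b, muscle, window_ms)
    hit = detect_crossing(trace)
    if hit is None:
        return LatencyEstimate.invalid("AUC never leaves the 25-75% band")
    crossing_index, direction = hit
    if fit_start_ms is None:
        mechanical = contrast is None or contrast.align_event == "perturbation"
        fit_start_ms = 0.0 if mechanical else float(trace.times[0])
    fit_start_index = int(np.searchsorted(trace.times, fit_start_ms))
    if crossing_index <= fit_start_index:
        return LatencyEstimate.invalid("band crossing precedes the fit window")
    return segmented_fit(trace, fit_start_index, crossing_index, direction)


def align_contrast_trials(
    trials: Sequence[TrialRecording],
    design: TaskDesign,
    contrast: Contrast,
) -> tuple[list[TrialRecording], list[TrialRecording]]:
    """Split preprocessed trials into the contrast's two sides, aligned to
    the contrast event (mechanical events get the design's onset
    correction)."""
    from .synthetic_emg import _matches  # shared selector semantics

    correction = design.design_constants.get("onset_correction_ms", 0.0)
    out: tuple[list, list] = ([], [])
    for tr in trials:
        for side, sel in enumerate((contrast.selector_a, contrast.selector_b)):
            if _matches(tr.condition, sel):
                out[side].append(align(tr, contrast.align_event, correction))
    return out
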