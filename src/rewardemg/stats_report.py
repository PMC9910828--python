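"""Paired signed-rank statistics and the end-to-end analysis pipeline.

Wilcoxon signed-rank convention
-------------------------------
For paired samples, differences of zero are dropped, the absolute
differences are midranked (ties give half-integer ranks), and the
statistic W is the sum of ranks of positive differences.  The effect size
is the common-language proportion of favorable ranks::

    r = W / (n (n + 1) / 2)

so r = 1 when every difference is positive and r = 0.5 under exchange
symmetry.  Two-sided p-values are exact for n <= 25 (full null
distribution of W by convolution over the signed ranks, identical to
enumerating all 2^n sign assignments) and use the normal approximation
with tie and continuity corrections for larger n.

The pipeline (:func:`run_pipeline`) mirrors the per-experiment sequence:
movement-time contrast, per-participant divergence latencies per reward
condition with a paired latency test, per-muscle feedback gains anchored
at each participant's own latency with paired rewarded-vs-non-rewarded
tests and the log-ratio G, plus the anticipatory-EMG control in the
fixed-delay task and per-trial reaction times in the RT task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import preprocess as pp
from .divergence_latency import align_contrast_trials, estimate_latency
from .responses import (
    anticipatory_means,
    detect_reaction_time,
    feedback_gain,
    gain_log_ratio,
    integrated_activity,
    mean_trace,
)
from .synthetic_emg import Dataset, TrialRecording, _matches
from .task_designs import TaskDesign, movement_time

__all__ = [
    "SignedRankResult",
    "signed_rank",
    "effect_size_r",
    "median_mt_contrast",
    "run_pipeline",
    "StatisticalError",
]

EXACT_P_MAX_N = 25


class StatisticalError(ValueError):
    pass


@dataclass(frozen=True)
class SignedRankResult:
    """Wilcoxon signed-rank outcome: W, pairs used, effect size r, p."""

    W: float
    n: int
    r: float
    p: float

    def as_dict(self) -> dict:
        return {"W": self.W, "n": self.n, "r": self.r, "p": self.p}


def effect_size_r(W: float, n: int) -> float:
    """Effect size r = W / (n(n+1)/2), the proportion of favorable ranks."""
    total = n * (n + 1) / 2.0
    if not 0 <= W <= total:
        raise ValueError(f"W={W} outside [0, {total}] for n={n}")
    return W / total


def _exact_two_sided_p(doubled_ranks: np.ndarray, w_doubled: int) -> float:
    """Exact two-sided p for W from the null distribution of the sum of a
    random subset of the (doubled, integer) ranks — each rank enters with
    probability 1/2, which is exactly the 2^n sign-assignment enumeration.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for dr in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[dr:] = dist[: total + 1 - dr]
        dist = 0.5 * (dist + shifted)
    p_le = float(dist[: w_doubled + 1].sum())
    p_ge = float(dist[w_doubled:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank(x, y) -> SignedRankResult:
    """Wilcoxon signed-rank test on paired samples ``x`` (e.g. rewarded)
    vs ``y`` (non-rewarded).

    Zero differences are dropped; ties midranked.  Requires at least 5
    informative pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatisticalError("paired samples must have equal length")
    d = x - y
    d = d[np.isfinite(d) & (d != 0)]
    n = len(d)
    if n < 5:
        raise StatisticalError(f"only {n} non-zero pairs; need at least 5")
    ranks = rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    if n <= EXACT_P_MAX_N:
        doubled = np.round(2 * ranks).astype(int)
        p = _exact_two_sided_p(doubled, int(round(2 * W)))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / 48.0
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (W - mean - 0.5 * np.sign(W - mean)) / sd
        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return SignedRankResult(W=W, n=n, r=effect_size_r(W, n), p=p)


def median_mt_contrast(
    mts: Mapping[str, Mapping[str, Sequence[float]]],
) -> tuple[pd.DataFrame, SignedRankResult]:
    """Per-participant median movement-time difference (rewarded minus
    non-rewarded) and the paired signed-rank test across participants.

    ``mts[participant][reward]`` holds that participant's valid MTs in the
    conditions of interest.
    """
    table = _median_table(mts)
    ok = table.dropna()
    res = signed_rank(ok["median_rewarded"].to_numpy(), ok["median_nonrewarded"].to_numpy())
    return table, res


def _median_table(mts) -> pd.DataFrame:
    rows = []
    for pid, by_reward in mts.items():
        med_r = float(np.median(by_reward["rewarded"])) if len(by_reward["rewarded"]) else math.nan
        med_nr = (
            float(np.median(by_reward["non_rewarded"])) if len(by_reward["non_rewarded"]) else math.nan
        )
        rows.append(
            {"participant": pid, "median_rewarded": med_r, "median_nonrewarded": med_nr,
             "contrast": med_r - med_nr}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


REWARD_LEVELS = ("rewarded", "non_rewarded")


def _safe_test(x, y) -> dict:
    """A paired test that cannot be run (too few informative pairs) is a
    reportable outcome of the pipeline, not a crash."""
    try:
        return signed_rank(x, y).as_dict()
    except StatisticalError as err:
        return {"error": str(err)}


def _conditions_of_interest(design: TaskDesign, contrast) -> list[Mapping[str, str]]:
    if contrast is None:
        return [{}]
    return [contrast.selector_a, contrast.selector_b]


def _trials_in(trials, selectors, reward=None):
    out = []
    for tr in trials:
        if reward is not None and tr.condition.get("reward") != reward:
            continue
        if any(_matches(tr.condition, sel) for sel in selectors):
            out.append(tr)
    return out


def run_pipeline(dataset: Dataset, contrast_name: str | None = None) -> dict:
    """Run the full analysis on a dataset and return a structured report.

    Stages: preprocessing (calibration scalars, filtering chain), the
    movement-time contrast, per-participant/per-reward divergence
    latencies with a paired test, per-muscle feedback gains and log-ratio
    G with paired tests, and task-specific extras (anticipatory check in
    the fixed-delay task; reaction times in the RT task).  Deterministic
    given its inputs.
    """
    design = dataset.design
    task = design.task_id
    contrast = design.contrast(contrast_name) if contrast_name else None
    if contrast is None and task != "proprio_rt":
        raise ValueError(f"task {task!r} requires a contrast name")
    muscles = list(dataset.participants[0].calibration.holds[0])
    report: dict = {"task": task, "contrast": contrast_name, "tables": {}}

    # --- preprocessing
    processed: dict[str, list[TrialRecording]] = {}
    baselines: dict[str, dict[int, pp.BaselineStats]] = {}
    for part in dataset.participants:
        scalars = pp.normalization_scalar(pp.preprocess_calibration(part.calibration))
        trials = [pp.preprocess_trial(tr, scalars) for tr in part.trials]
        processed[part.participant_id] = trials
        baselines[part.participant_id] = {tr.trial_id: pp.trial_baseline(tr, design) for tr in trials}

    # --- movement times (conditions of interest = the contrast's cells)
    selectors = _conditions_of_interest(design, contrast)
    mts: dict[str, dict[str, list[float]]] = {}
    mt_rows = []
    for pid, trials in processed.items():
        mts[pid] = {r: [] for r in REWARD_LEVELS}
        for tr in _trials_in(trials, selectors):
            mt = movement_time(tr, design)
            mt_rows.append(
                {"participant": pid, "trial": tr.trial_id, "reward": tr.condition["reward"],
                 "mt_ms": mt, "valid": bool(np.isfinite(mt))}
            )
            if np.isfinite(mt):
                mts[pid][tr.condition["reward"]].append(mt)
    mt_table = _median_table(mts)
    ok = mt_table.dropna()
    report["tables"]["movement_times"] = pd.DataFrame(mt_rows)
    report["tables"]["mt_contrast"] = mt_table
    report["mt_test"] = _safe_test(
        ok["median_rewarded"].to_numpy(), ok["median_nonrewarded"].to_numpy()
    )

    if task == "proprio_rt":
        _rt_stage(dataset, processed, baselines, report)
        return report

    # --- divergence latency per participant x reward
    lat_rows = []
    latencies: dict[tuple[str, str], float] = {}
    aligned_by_pid: dict[str, dict[str, tuple[list, list]]] = {}
    for pid, trials in processed.items():
        aligned_by_pid[pid] = {}
        for reward in REWARD_LEVELS:
            sub = [tr for tr in trials if tr.condition["reward"] == reward]
            side_a, side_b = align_contrast_trials(sub, design, contrast)
            aligned_by_pid[pid][reward] = (side_a, side_b)
            est = estimate_latency(side_a, side_b, contrast.muscle, design, contrast)
            lat_rows.append(
                {"participant": pid, "task": task, "contrast": contrast.name,
                 "muscle": contrast.muscle, "reward": reward,
                 "latency_ms": est.latency_ms, "valid": est.valid, "sse": est.sse}
            )
            if est.valid:
                latencies[(pid, reward)] = est.latency_ms
    lat_table = pd.DataFrame(lat_rows)
    report["tables"]["latencies"] = lat_table
    pivot = lat_table[lat_table.valid].pivot_table(
        index="participant", columns="reward", values="latency_ms"
    ).dropna()
    if {"rewarded", "non_rewarded"} <= set(pivot.columns):
        report["latency_test"] = _safe_test(pivot["rewarded"], pivot["non_rewarded"])
    else:
        report["latency_test"] = {"error": "no valid latencies in both reward conditions"}

    # --- feedback gains per muscle, window anchored at each participant's
    #     own latency for that reward condition
    gain_rows = []
    for pid in processed:
        for reward in REWARD_LEVELS:
            if (pid, reward) not in latencies:
                continue
            start = latencies[(pid, reward)]
            side_a, side_b = aligned_by_pid[pid][reward]
            for m in muscles:
                ta, ma = mean_trace(side_a, m)
                tb, mb = mean_trace(side_b, m)
                n = min(len(ta), len(tb))
                gain = feedback_gain(ta[:n], ma[:n], mb[:n], start, contrast.window_ms)
                gain_rows.append(
                    {"participant": pid, "task": task, "muscle": m, "reward": reward,
                     "window_start_ms": start, "window_ms": contrast.window_ms, "gain": gain}
                )
    gain_cols = ["participant", "task", "muscle", "reward", "window_start_ms", "window_ms", "gain"]
    gain_table = pd.DataFrame(gain_rows, columns=gain_cols)
    report["tables"]["gains"] = gain_table
    report["gain_tests"] = {}
    report["log_ratio_G"] = {}
    for m in muscles:
        sub = gain_table[gain_table.muscle == m].pivot_table(
            index="participant", columns="reward", values="gain"
        ).dropna()
        if not {"rewarded", "non_rewarded"} <= set(sub.columns):
            report["log_ratio_G"][m] = {"median_G": math.nan, "n": 0, "n_excluded_nonpositive": 0}
            report["gain_tests"][m] = {"error": "no gains in both reward conditions"}
            continue
        gs = [
            g for g in (
                gain_log_ratio(row["rewarded"], row["non_rewarded"]) for _, row in sub.iterrows()
            )
            if g is not None
        ]
        report["log_ratio_G"][m] = {
            "median_G": float(np.median(gs)) if gs else math.nan,
            "n": len(gs),
            "n_excluded_nonpositive": int(len(sub) - len(gs)),
        }
        if {"rewarded", "non_rewarded"} <= set(sub.columns):
            report["gain_tests"][m] = _safe_test(sub["rewarded"], sub["non_rewarded"])
        else:
            report["gain_tests"][m] = {"error": "no gains in both reward conditions"}

    # --- anticipatory-EMG control (fixed target-to-perturbation delay only)
    if task == "in_out":
        report["anticipatory"] = _anticipatory_stage(processed, design, contrast)
    return report


def _anticipatory_stage(processed, design, contrast) -> dict:
    out = {}
    for reward in REWARD_LEVELS:
        per_side = {0: [], 1: []}
        correction = design.design_constants.get("onset_correction_ms", 0.0)
        for pid, trials in processed.items():
            for side, sel in enumerate((contrast.selector_a, contrast.selector_b)):
                sub = [
                    pp.align(tr, "perturbation", correction)
                    for tr in trials
                    if tr.condition["reward"] == reward and _matches(tr.condition, sel)
                ]
                per_side[side].append(anticipatory_means(sub, contrast.muscle))
        try:
            out[reward] = signed_rank(per_side[0], per_side[1]).as_dict()
        except StatisticalError as err:
            out[reward] = {"error": str(err)}
    return out


def _rt_stage(dataset: Dataset, processed, baselines, report: dict) -> None:
    """Reaction-time task: per-trial RTs, the median-RT reward contrast,
    and gains integrated from each trial's own reaction time."""
    design = dataset.design
    correction = design.design_constants.get("onset_correction_ms", 0.0)
    muscles = list(dataset.participants[0].calibration.holds[0])
    rt_rows, gain_rows = [], []
    rts: dict[str, dict[str, list[float]]] = {}
    per_trial_gain: dict[str, dict[str, list[dict[str, float]]]] = {}
    for pid, trials in processed.items():
        rts[pid] = {r: [] for r in REWARD_LEVELS}
        per_trial_gain[pid] = {r: [] for r in REWARD_LEVELS}
        for tr in trials:
            aligned = pp.align(tr, "perturbation", correction)
            res = detect_reaction_time(aligned, baselines[pid][tr.trial_id])
            rt_rows.append(
                {"participant": pid, "trial": tr.trial_id, "reward": tr.condition["reward"],
                 "rt_ms": res.rt_ms, "discarded": res.discarded}
            )
            if res.discarded:
                continue
            rts[pid][tr.condition["reward"]].append(res.rt_ms)
            gains = {}
            for m in muscles:
                try:
                    gains[m] = integrated_activity(
                        aligned.time_ms, aligned.emg[m], res.rt_ms, 50.0
                    )
                except ValueError:
                    continue
            per_trial_gain[pid][tr.condition["reward"]].append(gains)
    report["tables"]["reaction_times"] = pd.DataFrame(rt_rows)
    rt_rows2 = []
    for pid, by_reward in rts.items():
        if all(len(v) for v in by_reward.values()):
            rt_rows2.append(
                {"participant": pid,
                 "median_rewarded": float(np.median(by_reward["rewarded"])),
                 "median_nonrewarded": float(np.median(by_reward["non_rewarded"]))}
            )
    rt_table = pd.DataFrame(rt_rows2)
    report["tables"]["rt_contrast"] = rt_table
    report["rt_test"] = (
        _safe_test(rt_table["median_rewarded"], rt_table["median_nonrewarded"])
        if len(rt_table)
        else {"error": "no participants with reaction times in both conditions"}
    )
    # per-participant mean of per-trial integrals, per reward
    report["gain_tests"], report["log_ratio_G"] = {}, {}
    for m in muscles:
        rows = []
        for pid in per_trial_gain:
            means = {}
            for reward in REWARD_LEVELS:
                vals = [g[m] for g in per_trial_gain[pid][reward] if m in g]
                if vals:
                    means[reward] = float(np.mean(vals))
            if len(means) == 2:
                rows.append({"participant": pid, **means})
        tab = pd.DataFrame(rows)
        gain_rows.append(tab.assign(muscle=m))
        gs = [
            g for g in (
                gain_log_ratio(r["rewarded"], r["non_rewarded"]) for _, r in tab.iterrows()
            )
            if g is not None
        ]
        report["log_ratio_G"][m] = {
            "median_G": float(np.median(gs)) if gs else math.nan,
            "n": len(gs),
            "n_excluded_nonpositive": int(len(tab) - len(gs)),
        }
        report["gain_tests"][m] = (
            _safe_test(tab["rewarded"], tab["non_rewarded"])
            if len(tab)
            else {"error": "no participants with gains in both conditions"}
        )
    report["tables"]["gains"] = pd.concat(gain_rows, ignore_index=True)
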