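"""ROC AUC traces, sustained band crossings and breakpoint regression."""

import numpy as np
import pytest

from rewardemg import preprocess as pp
from rewardemg.divergence_latency import (
    AUCTrace,
    auc_trace,
    align_contrast_trials,
    detect_crossing,
    estimate_latency,
    segmented_fit,
)
from rewardemg.synthetic_emg import SyntheticConfig, simulate_calibration, simulate_trial

from conftest import make_trial


def _trials(matrix, t0_index=0):
    """One TrialRecording per row; time base shifted so t=0 sits at
    ``t0_index``."""
    matrix = np.asarray(matrix, dtype=float)
    times = np.arange(matrix.shape[1], dtype=float) - t0_index
    return [make_trial({"triceps_lat": row}, time_ms=times, trial_id=i) for i, row in enumerate(matrix)]


def _brute_auc(a_col, b_col):
    wins = sum((x > y) + 0.5 * (x == y) for x in a_col for y in b_col)
    return wins / (len(a_col) * len(b_col))


def test_auc_matches_exhaustive_pairwise_count():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 5, size=(5, 8)).astype(float)  # integers force ties
    b = rng.integers(0, 5, size=(4, 8)).astype(float)
    trace = auc_trace(_trials(a), _trials(b), "triceps_lat", window_ms=(0, 7))
    for j in range(8):
        assert trace.auc[j] == pytest.approx(_brute_auc(a[:, j], b[:, j]))


def test_auc_degenerate_cases():
    a = np.ones((3, 4))
    trace = auc_trace(_trials(a), _trials(a.copy()), "triceps_lat", window_ms=(0, 3))
    np.testing.assert_allclose(trace.auc, 0.5)
    trace = auc_trace(_trials(a + 1), _trials(a), "triceps_lat", window_ms=(0, 3))
    np.testing.assert_allclose(trace.auc, 1.0)


def test_auc_requires_two_trials_per_side():
    a = np.ones((3, 4))
    with pytest.raises(ValueError):
        auc_trace(_trials(a), _trials(a[:1]), "triceps_lat", window_ms=(0, 3))


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(1)
    a, b = rng.normal(2, 1, (6, 10)), rng.normal(1, 1, (5, 10))
    t1 = auc_trace(_trials(a), _trials(b), "triceps_lat", (0, 9))
    t2 = auc_trace(_trials(np.exp(a)), _trials(np.exp(b)), "triceps_lat", (0, 9))
    np.testing.assert_allclose(t1.auc, t2.auc)


def test_auc_antisymmetric_under_side_swap():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=(4, 6)), rng.normal(size=(7, 6))
    t_ab = auc_trace(_trials(a), _trials(b), "triceps_lat", (0, 5))
    t_ba = auc_trace(_trials(b), _trials(a), "triceps_lat", (0, 5))
    np.testing.assert_allclose(t_ab.auc, 1.0 - t_ba.auc)


def _trace(auc):
    auc = np.asarray(auc, dtype=float)
    return AUCTrace(times=np.arange(len(auc), dtype=float), auc=auc, n_a=5, n_b=5)


def test_crossing_requires_two_consecutive_samples():
    auc = np.full(20, 0.5)
    auc[10] = 0.9  # an isolated sample does not count
    assert detect_crossing(_trace(auc)) is None


def test_crossing_detects_first_sustained_sample_both_directions():
    up = np.full(20, 0.5)
    up[12:] = 0.8
    assert detect_crossing(_trace(up)) == (12, "above")
    down = np.full(20, 0.5)
    down[7:] = 0.1
    assert detect_crossing(_trace(down)) == (7, "below")


def test_segmented_fit_recovers_noiseless_elbow():
    times = np.arange(60, dtype=float)
    elbow = 30
    auc = np.where(times < elbow, 0.5, 0.5 + 0.02 * (times - elbow))
    trace = AUCTrace(times=times, auc=auc, n_a=10, n_b=10)
    hit = detect_crossing(trace)
    assert hit is not None
    est = segmented_fit(trace, 0, hit[0], hit[1])
    assert est.valid and est.breakpoint_index == elbow
    assert est.latency_ms == 30.0
    assert est.sse == pytest.approx(0.0, abs=1e-20)


def test_segmented_fit_matches_exhaustive_breakpoint_search():
    rng = np.random.default_rng(3)
    for _ in range(5):
        n = 40
        times = np.arange(n, dtype=float)
        auc = np.clip(0.5 + np.cumsum(rng.normal(0, 0.02, n)), 0, 1)
        trace = AUCTrace(times=times, auc=auc, n_a=5, n_b=5)
        crossing = n - 1
        est = segmented_fit(trace, 0, crossing)
        # independent re-computation with plain lstsq over every breakpoint
        best = np.inf
        for bp in range(2, crossing - 1):
            sse = 0.0
            for sl in (slice(0, bp + 1), slice(bp, crossing + 1)):
                A = np.vstack([times[sl], np.ones(sl.stop - sl.start)]).T
                _, res, *_ = np.linalg.lstsq(A, auc[sl], rcond=None)
                sse += float(res[0]) if len(res) else 0.0
            best = min(best, sse)
        assert est.sse == pytest.approx(best, abs=1e-12)


def test_segmented_fit_rejects_too_short_window():
    trace = _trace(np.linspace(0.5, 0.9, 5))
    est = segmented_fit(trace, 0, 3)
    assert not est.valid


def test_estimate_invalid_when_no_divergence(designs):
    """A contrast with no evoked difference (flat channels) yields an
    invalid estimate rather than a spurious latency."""
    design = designs["in_out"]
    cfg = SyntheticConfig(seed=8, muscles=("triceps_lat",), bumps=())
    cal = simulate_calibration(cfg, np.random.default_rng(8))
    scal = pp.normalization_scalar(pp.preprocess_calibration(cal))
    trials = []
    for i in range(40):
        cond = {"perturbation": "inward" if i % 2 else "outward", "target": "outward",
                "reward": "non_rewarded"}
        tr = simulate_trial(cond, design, cfg, np.random.default_rng([8, i]), trial_id=i)
        trials.append(pp.preprocess_trial(tr, scal))
    c = design.contrast("slr")
    a, b = align_contrast_trials(trials, design, c)
    est = estimate_latency(a, b, "triceps_lat", design, c)
    assert not est.valid


def test_estimate_invariant_to_common_scaling(designs):
    design = designs["in_out"]
    cfg = SyntheticConfig(seed=12, muscles=("triceps_lat",))
    cal = simulate_calibration(cfg, np.random.default_rng(12))
    scal = pp.normalization_scalar(pp.preprocess_calibration(cal))
    trials = []
    for i in range(60):
        cond = {"perturbation": "inward" if i % 2 else "outward", "target": "outward",
                "reward": "non_rewarded"}
        tr = simulate_trial(cond, design, cfg, np.random.default_rng([12, i]), trial_id=i)
        trials.append(pp.preprocess_trial(tr, scal))
    c = design.contrast("slr")
    a, b = align_contrast_trials(trials, design, c)
    est1 = estimate_latency(a, b, "triceps_lat", design, c)
    for tr in a + b:
        tr.emg["triceps_lat"] = tr.emg["triceps_lat"] * 37.5
    est2 = estimate_latency(a, b, "triceps_lat", design, c)
    assert est1.latency_ms == est2.latency_ms


def _recovery_error(n_per_side, seed, designs):
    design = designs["in_out"]
    cfg = SyntheticConfig(seed=seed, muscles=("triceps_lat",))
    cal = simulate_calibration(cfg, np.random.default_rng([seed, 99]))
    scal = pp.normalization_scalar(pp.preprocess_calibration(cal))
    trials = []
    for i in range(2 * n_per_side):
        cond = {"perturbation": "inward" if i % 2 else "outward", "target": "outward",
                "reward": "non_rewarded"}
        tr = simulate_trial(cond, design, cfg, np.random.default_rng([seed, i]), trial_id=i)
        trials.append(pp.preprocess_trial(tr, scal))
    c = design.contrast("slr")
    a, b = align_contrast_trials(trials, design, c)
    est = estimate_latency(a, b, "triceps_lat", design, c)
    return abs(est.latency_ms - 25.0) if est.valid else np.inf


def test_recovery_error_shrinks_with_trial_count(designs):
    errs = {
        n: np.median([_recovery_error(n, seed, designs) for seed in range(8)])
        for n in (10, 30, 100)
    }
    assert errs[100] <= errs[10]
    assert errs[100] <= 4.0
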