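"""Synthetic surface-EMG and kinematics with known ground truth.

Every downstream stage of the pipeline (preprocessing, ROC divergence
latency, feedback gains, reaction times, paired statistics) is validated
against data from this generator, which emulates what the experiments
record: per-trial five-muscle surface EMG at 1000 Hz with tonic
pre-activation under a background load, a perturbation- or jump-evoked
response whose onset and amplitude depend on condition and reward, and
radial hand kinematics yielding movement times that shorten under reward.

Signal model
------------
Raw EMG for each muscle is a zero-mean, band-limited Gaussian carrier
(unit variance, band ``carrier_band``) amplitude-modulated by a
non-negative envelope ``E(t)``, plus additive white sensor noise::

    raw(t) = carrier(t) * E(t) + noise_sd * white(t)

so that the analysis chain (band-pass, full-wave rectification,
normalization) has expectation proportional to ``E(t)``.  The envelope is
a tonic baseline plus condition-dependent evoked bumps, each rising as a
half-Gaussian (sigma ``rise_sigma_ms``) to a plateau that starts exactly
at the event time plus the ground-truth latency; rewarded trials multiply
every evoked amplitude by ``reward_gain_factor`` (ground-truth ``e^G``).
Trial-to-trial variability is a shared log-normal amplitude factor.

Kinematics are minimum-jerk radial profiles solved so the task's own
movement-time definition recovers the drawn ground-truth MT exactly (up to
the 1 ms sampling grid).

Randomness: a single dataset seed expands into independent per-trial
streams keyed ``(seed, participant, trial)`` through numpy's SeedSequence,
so any subset of trials is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, signal

from .task_designs import TaskDesign, make_schedule

__all__ = [
    "MUSCLES",
    "EvokedBump",
    "SyntheticConfig",
    "GroundTruth",
    "TrialRecording",
    "CalibrationSet",
    "ParticipantData",
    "Dataset",
    "simulate_trial",
    "simulate_calibration",
    "simulate_dataset",
]

MUSCLES = ("brachioradialis", "triceps_lat", "pectoralis", "post_deltoid", "biceps")

#: relative evoked-response scale of each muscle (triceps carries the
#: analysed responses; the others co-activate more weakly)
DEFAULT_MUSCLE_SCALE = {
    "brachioradialis": 0.35,
    "triceps_lat": 1.0,
    "pectoralis": 0.4,
    "post_deltoid": 0.45,
    "biceps": 0.3,
}


@dataclass(frozen=True)
class EvokedBump:
    """One condition-dependent evoked component of the EMG envelope.

    ``latency_key`` selects the onset latency from
    ``SyntheticConfig.true_latency_ms``; ``select`` restricts the bump to
    trials whose condition matches every listed factor level.
    """

    latency_key: str
    select: Mapping[str, str]
    amplitude: float


# Evoked structure per task: which envelope components exist and how their
# amplitude depends on condition.  Contrasted conditions get different
# amplitudes so ROC discrimination has something to find; the onset of the
# *differing* component is the contrast's ground-truth latency.
DEFAULT_BUMPS: dict[str, tuple[EvokedBump, ...]] = {
    # Amplitudes (in baseline units) follow the single-sample ROC algebra:
    # for rectified Gaussian carriers the AUC between envelope levels
    # e_a > e_b is 1 - (2/pi) arctan(e_b/e_a), so sustained 75% AUC needs
    # an envelope ratio above ~2.4.  Stretch responses of a pre-loaded
    # extensor are several times its tonic level, and goal-dependent
    # long-latency components can be inhibitory (negative amplitude); the
    # values below give plateau ratios of ~3-4 in each contrast.
    "in_out": (
        EvokedBump("slr", {"perturbation": "inward"}, 6.0),
        EvokedBump("slr", {"perturbation": "outward"}, 0.15),
        EvokedBump("llr", {"perturbation": "inward", "target": "outward"}, 14.0),
        EvokedBump("llr", {"perturbation": "inward", "target": "inward"}, -6.5),
        EvokedBump("llr", {"perturbation": "outward"}, 0.3),
    ),
    "target_selection": (
        EvokedBump("slr", {"perturbation": "inward"}, 2.5),
        EvokedBump("slr", {"perturbation": "outward"}, 0.15),
        EvokedBump("selection", {"targets": "two", "perturbation": "inward"}, 10.0),
        EvokedBump("selection", {"targets": "one", "perturbation": "inward"}, -2.0),
    ),
    "cursor_jump": (
        EvokedBump("jump", {"jump": "inward"}, 8.0),
        EvokedBump("jump", {"jump": "outward"}, 0.15),
    ),
    "target_jump": (
        EvokedBump("jump", {"jump": "inward"}, 8.0),
        EvokedBump("jump", {"jump": "outward"}, 0.15),
    ),
    # the voluntary response burst; its onset is the per-trial reaction time
    "proprio_rt": (EvokedBump("rt", {}, 40.0),),
}

# mean ground-truth MT per task (ms); the In-Out task must enter the large
# target well before the trial ends 800 ms after the perturbation
_MT_MEAN = {
    "in_out": 450.0,
    "target_selection": 650.0,
    "cursor_jump": 700.0,
    "target_jump": 700.0,
    "proprio_rt": 450.0,  # unused: proprio_rt MT = RT + movement term
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults define the simulated conditions."""

    seed: int = 0
    n_participants: int = 16
    fs: int = 1000
    muscles: tuple[str, ...] = MUSCLES
    baseline_level: float = 1.0
    carrier_band: tuple[float, float] = (30.0, 220.0)
    noise_sd: float = 0.05
    true_latency_ms: Mapping[str, float] = field(
        default_factory=lambda: {"slr": 25.0, "llr": 50.0, "selection": 100.0, "jump": 120.0}
    )
    bumps: tuple[EvokedBump, ...] | None = None  # None -> task default
    muscle_scale: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MUSCLE_SCALE))
    amplitude_jitter_sd: float = 0.2  # log-normal sigma, shared per trial
    participant_amp_sd: float = 0.15  # log-normal sigma across participants
    rise_sigma_ms: float = 10.0
    rt_rise_sigma_ms: float = 1.5  # ballistic voluntary bursts rise faster
    plateau_ms: float = 150.0
    decay_tau_ms: float = 150.0
    reward_gain_factor: float = 1.25  # ground-truth e^G
    reward_mt_shift_ms: float = 25.0
    mt_mean_ms: float | None = None  # None -> per-task default
    mt_noise_sd: float = 60.0
    participant_mt_sd: float = 40.0
    rt_mean_ms: float = 147.0
    rt_rewarded_mean_ms: float = 134.6
    rt_sd_ms: float = 25.0

    def __post_init__(self) -> None:
        if not self.fs > 2 * self.carrier_band[1]:
            raise ValueError("fs must exceed twice the upper carrier band edge")
        if any(v <= 0 for v in self.true_latency_ms.values()):
            raise ValueError("true latencies must be positive")


@dataclass(frozen=True)
class GroundTruth:
    mt_ms: float
    rt_ms: float | None
    latency_ms: Mapping[str, float]
    evoked_amplitude: Mapping[str, float]
    reward_gain_factor: float


@dataclass
class TrialRecording:
    """One trial: condition labels, events, EMG, kinematics, movement time.

    ``processing`` flags the EMG state (``raw`` | ``filtered`` |
    ``rectified`` | ``normalized``); all series share the ``time_ms`` base.
    """

    trial_id: int
    participant_id: str
    condition: dict[str, str]
    events: dict[str, float]
    time_ms: np.ndarray
    emg: dict[str, np.ndarray]
    radial_pos: np.ndarray
    radial_vel: np.ndarray
    processing: str = "raw"
    mt_ms: float = math.nan
    ground_truth: GroundTruth | None = None

    def copy_with(self, **kw) -> "TrialRecording":
        d = self.__dict__ | kw
        return TrialRecording(**d)


@dataclass
class CalibrationSet:
    """Four 2 s static holds per muscle, entry at time 0 of each hold."""

    holds: list[dict[str, np.ndarray]]
    entry_ms: list[float]
    fs: int = 1000
    processing: str = "raw"

    def __post_init__(self) -> None:
        if len(self.holds) != 4:
            raise ValueError("calibration requires exactly four holds")
        for h in self.holds:
            for series in h.values():
                if len(series) < 2 * self.fs:
                    raise ValueError("each hold must span at least 2 s")


@dataclass
class ParticipantData:
    participant_id: str
    calibration: CalibrationSet
    trials: list[TrialRecording]


@dataclass
class Dataset:
    design: TaskDesign
    config: SyntheticConfig | None
    participants: list[ParticipantData]


# ---------------------------------------------------------------------------
# minimum-jerk helpers


def _mj_pos(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _mj_vel(u: np.ndarray) -> np.ndarray:
    return 30 * u**2 - 60 * u**3 + 30 * u**4


def _mj_fraction_at(frac: float) -> float:
    """u such that the minimum-jerk shape reaches ``frac`` of the distance."""
    return float(optimize.brentq(lambda u: _mj_pos(np.array(u)) - frac, 0.0, 1.0))


def _visual_duration(mt_target: float, dist: float, r_target: float, r_start: float) -> float:
    """Minimum-jerk duration T whose measured visual MT equals ``mt_target``.

    Measured MT runs from start-position exit to the first time the cursor
    is inside the target with radial speed below 10 cm/s (0.01 cm/ms).
    """
    u_exit = _mj_fraction_at(r_start / dist)
    u_enter = _mj_fraction_at((dist - r_target) / dist)

    def measured(T: float) -> float:
        # decelerating-limb root of v(u) = 0.01 cm/ms; movements so slow
        # that peak velocity never reaches 10 cm/s satisfy the velocity
        # criterion throughout, leaving target entry as the binding event
        c = 0.01 * T / dist
        if _mj_vel(np.array(0.5)) <= c:
            u_stop = 0.0
        else:
            u_stop = optimize.brentq(lambda u: _mj_vel(np.array(u)) - c, 0.5, 1.0)
        return (max(u_stop, u_enter) - u_exit) * T

    return float(optimize.brentq(lambda T: measured(T) - mt_target, 50.0, 20 * mt_target))


# ---------------------------------------------------------------------------
# carrier / envelope


def _carrier_sos(config: SyntheticConfig):
    lo, hi = config.carrier_band
    return signal.butter(4, [lo, hi], btype="bandpass", fs=config.fs, output="sos")


def _carrier(n: int, n_ch: int, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((n_ch, n))
    band = signal.sosfiltfilt(_carrier_sos(config), white, axis=-1)
    return band / band.std(axis=-1, keepdims=True)


def _bump_shape(
    t: np.ndarray, onset: float, config: SyntheticConfig, sigma: float | None = None
) -> np.ndarray:
    """Half-Gaussian rise to a plateau, then slow exponential decay."""
    s = config.rise_sigma_ms if sigma is None else sigma
    t_plateau = onset + 3 * s
    t_decay = t_plateau + config.plateau_ms
    out = np.zeros_like(t, dtype=float)
    rising = (t >= onset) & (t < t_plateau)
    out[rising] = np.exp(-((t[rising] - t_plateau) ** 2) / (2 * s**2))
    out[(t >= t_plateau) & (t < t_decay)] = 1.0
    decaying = t >= t_decay
    out[decaying] = np.exp(-(t[decaying] - t_decay) / config.decay_tau_ms)
    return out


def _matches(condition: Mapping[str, str], selector: Mapping[str, str]) -> bool:
    return all(condition.get(f) == lv for f, lv in selector.items())


# ---------------------------------------------------------------------------
# trial simulation


@dataclass(frozen=True)
class _ParticipantEffects:
    amp_factor: float = 1.0
    mt_offset: float = 0.0


def simulate_trial(
    condition: Mapping[str, str],
    design: TaskDesign,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    trial_id: int = 0,
    participant_id: str = "p00",
    effects: _ParticipantEffects = _ParticipantEffects(),
) -> TrialRecording:
    """Simulate one trial of ``design`` under ``condition``.

    The evoked envelope bump starts exactly ``true_latency_ms`` after the
    task's alignment event (or at the drawn reaction time for the RT
    task); rewarded trials scale every evoked amplitude by
    ``reward_gain_factor``.  Ground truth is stored on the recording.
    """
    for factor, level in condition.items():
        if factor not in design.factors or level not in design.factors[factor]:
            raise ValueError(f"invalid condition {factor}={level!r} for task {design.task_id}")
    rewarded = condition.get("reward") == "rewarded"
    geom = design.geometry
    task = design.task_id
    mt_mean = config.mt_mean_ms if config.mt_mean_ms is not None else _MT_MEAN[task]

    # --- event layout and ground-truth timing
    rt_ms: float | None = None
    if task in ("in_out", "target_selection", "proprio_rt"):
        target_onset = 400.0
        if task == "in_out":
            pert = target_onset + 600.0
        else:
            pert = target_onset + float(np.round(rng.uniform(600.0, 1000.0)))
        if task == "proprio_rt":
            mean_rt = config.rt_rewarded_mean_ms if rewarded else config.rt_mean_ms
            rt_ms = max(float(rng.normal(mean_rt, config.rt_sd_ms)), 60.0)
            mt_target = rt_ms + max(float(rng.normal(300.0, config.mt_noise_sd / 2)), 120.0)
        else:
            mt_target = float(rng.normal(mt_mean + effects.mt_offset, config.mt_noise_sd))
            if rewarded:
                mt_target -= config.reward_mt_shift_ms
            mt_target = max(mt_target, 120.0)
        u_enter = _mj_fraction_at((geom.target_distance_cm - geom.target_radius_cm) / geom.target_distance_cm)
        T = mt_target / u_enter
        t_move0 = pert
        end = pert + design.design_constants.get("trial_end_after_perturbation_ms", 1000.0)
        end = max(end, t_move0 + min(T, mt_target + 400.0))
        events = {"target_onset": target_onset, "perturbation": pert}
        # the commanded torque precedes limb acceleration; evoked responses
        # are time-locked to the acceleration, hence the actuation lag here
        # (the analysis applies the matching onset correction when aligning)
        actuation_lag = design.design_constants.get("onset_correction_ms", 0.0)
        align_event, align_time = "perturbation", pert + actuation_lag
    elif task in ("cursor_jump", "target_jump"):
        target_onset = float(np.round(rng.uniform(600.0, 700.0)))
        mt_target = float(rng.normal(mt_mean + effects.mt_offset, config.mt_noise_sd))
        if rewarded:
            mt_target -= config.reward_mt_shift_ms
        mt_target = max(mt_target, 200.0)
        T = _visual_duration(mt_target, geom.target_distance_cm, geom.target_radius_cm, geom.start_radius_cm)
        t_move0 = target_onset + max(float(rng.normal(250.0, 30.0)), 120.0)
        jump = t_move0 + 0.5 * T  # cursor/target jump at the midline crossing
        end = t_move0 + T + 200.0
        events = {"target_onset": target_onset, "jump": jump}
        align_event, align_time = "jump", jump
    else:  # pragma: no cover
        raise ValueError(f"unknown task {task!r}")

    n = int(round(end)) + 1
    t = np.arange(n, dtype=float)  # ms at fs = 1000

    # --- kinematics: minimum-jerk radial profile
    u = np.clip((t - t_move0) / T, 0.0, 1.0)
    pos = geom.target_distance_cm * _mj_pos(u)
    vel = geom.target_distance_cm / T * _mj_vel(u) * 1000.0  # cm/s
    exited = pos > geom.start_radius_cm
    events["start_exit"] = float(t[np.argmax(exited)]) if exited.any() else math.nan
    entered = np.abs(pos - geom.target_distance_cm) <= geom.target_radius_cm
    events["target_entry"] = float(t[np.argmax(entered)]) if entered.any() else math.nan

    # --- envelope and raw EMG
    bumps = config.bumps if config.bumps is not None else DEFAULT_BUMPS[task]
    jitter = float(rng.lognormal(0.0, config.amplitude_jitter_sd))
    reward_factor = config.reward_gain_factor if rewarded else 1.0
    amplitudes: dict[str, float] = {}
    latencies: dict[str, float] = {}
    bump_shapes: list[tuple[float, np.ndarray]] = []
    for bump in bumps:
        if not _matches(condition, bump.select):
            continue
        if bump.latency_key == "rt":
            lat = rt_ms if rt_ms is not None else 0.0
        else:
            lat = float(config.true_latency_ms[bump.latency_key])
        onset = align_time + lat
        amp = bump.amplitude * reward_factor
        latencies[bump.latency_key] = lat
        amplitudes[bump.latency_key] = amplitudes.get(bump.latency_key, 0.0) + amp
        sigma = config.rt_rise_sigma_ms if bump.latency_key == "rt" else None
        bump_shapes.append((amp, _bump_shape(t, onset, config, sigma)))

    carrier = _carrier(n, len(config.muscles), config, rng)
    sensor = rng.standard_normal((len(config.muscles), n)) * config.noise_sd
    emg: dict[str, np.ndarray] = {}
    for i, m in enumerate(config.muscles):
        env = np.full(n, config.baseline_level)
        scale = config.muscle_scale.get(m, 1.0) * effects.amp_factor * jitter
        for amp, shape in bump_shapes:
            env = env + amp * scale * shape
        # inhibitory components cannot drive activity below silence
        env = np.maximum(env, 0.0)
        emg[m] = carrier[i] * env + sensor[i]

    gt = GroundTruth(
        mt_ms=mt_target,
        rt_ms=rt_ms,
        latency_ms=latencies,
        evoked_amplitude=amplitudes,
        reward_gain_factor=reward_factor,
    )
    return TrialRecording(
        trial_id=trial_id,
        participant_id=participant_id,
        condition=dict(condition),
        events=events,
        time_ms=t,
        emg=emg,
        radial_pos=pos,
        radial_vel=vel,
        processing="raw",
        mt_ms=mt_target,
        ground_truth=gt,
    )


def simulate_calibration(config: SyntheticConfig, rng: np.random.Generator) -> CalibrationSet:
    """Four 2 s static holds with a stationary envelope at baseline level."""
    holds = []
    n = 2 * config.fs
    for _ in range(4):
        carrier = _carrier(n, len(config.muscles), config, rng)
        sensor = rng.standard_normal((len(config.muscles), n)) * config.noise_sd
        holds.append(
            {
                m: carrier[i] * config.baseline_level + sensor[i]
                for i, m in enumerate(config.muscles)
            }
        )
    return CalibrationSet(holds=holds, entry_ms=[0.0] * 4, fs=config.fs)


def simulate_dataset(
    design: TaskDesign,
    config: SyntheticConfig,
    n_epochs: int | None = None,
) -> Dataset:
    """Simulate a full dataset: per participant, a calibration set plus one
    trial per schedule row.

    ``n_epochs`` optionally shortens the schedule (single block) for
    smaller simulations; the default runs the design's full trial count.
    Deterministic under a fixed ``config.seed``.
    """
    if n_epochs is not None:
        design = replace(design, n_epochs=n_epochs, epochs_per_block=n_epochs)
    participants = []
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        p_rng = np.random.default_rng([config.seed, 900_000 + p])
        effects = _ParticipantEffects(
            amp_factor=float(p_rng.lognormal(0.0, config.participant_amp_sd)),
            mt_offset=float(p_rng.normal(0.0, config.participant_mt_sd)),
        )
        schedule_seed = int(np.random.SeedSequence([config.seed, p]).generate_state(1)[0])
        schedule = make_schedule(design, seed=schedule_seed)
        cal = simulate_calibration(config, np.random.default_rng([config.seed, p, 10_000_000]))
        trials = []
        factor_names = list(design.factors)
        for row in schedule.itertuples(index=False):
            cond = {f: getattr(row, f) for f in factor_names}
            rng = np.random.default_rng([config.seed, p, int(row.trial_index)])
            trials.append(
                simulate_trial(
                    cond,
                    design,
                    config,
                    rng,
                    trial_id=int(row.trial_index),
                    participant_id=pid,
                    effects=effects,
                )
            )
        participants.append(ParticipantData(pid, cal, trials))
    return Dataset(design=design, config=config, participants=participants)
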