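"""Task designs, trial schedules, monetary returns and movement times.

Five reaching tasks probe distinct sensorimotor feedback loops: an In-Out
Target task (short- and long-latency stretch responses), a Target Selection
task (goal switching), Cursor Jump and Target Jump tasks (visuomotor
responses) and a Proprioception-cued Reaction Time task.  Each task is a
small factorial design run in fixed-size epochs whose trial order is
randomized within the epoch; rewarded trials pay out a monetary return that
decreases with poorer performance (less time on target, or longer movement
time).

The module ships a design library as one YAML file per task
(``rewardemg/designs/``) and exposes:

* :func:`load_design` / :data:`TASK_IDS` — the built-in designs,
* :func:`make_schedule` — a seeded within-epoch randomized schedule,
* :func:`in_out_return` / :func:`mt_return` — the two return functions,
* :func:`movement_time` — task-specific movement-time measurement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TASK_IDS",
    "ReturnParams",
    "Contrast",
    "BaselineRule",
    "TaskGeometry",
    "TaskDesign",
    "load_design",
    "make_schedule",
    "in_out_return",
    "mt_return",
    "movement_time",
    "time_in_target",
    "ConfigurationError",
]

TASK_IDS = ("in_out", "target_selection", "cursor_jump", "target_jump", "proprio_rt")


class ConfigurationError(ValueError):
    """A task design whose epoch/block arithmetic is inconsistent."""


@dataclass(frozen=True)
class ReturnParams:
    """Parameters of a monetary-return function.

    Two functional forms exist.  ``time_in_target`` (In-Out Target task):

        return = g * exp(-tau * p),   p = 1 - min((x - x0) / (xf - x0), 1)

    with ``x`` the accumulated time (ms) spent inside the target between
    perturbation onset and trial end.  ``movement_time`` (all other tasks):

        return = max(g * (scaler * exp(-tau * p) + shifter), 0),
        p = MT / mt_max

    ``g_max`` is in cents; ``scaler``/``shifter``/``tau`` are dimensionless
    calibration constants; ``mt_max``, ``x0``, ``xf`` are in ms.
    """

    form: str
    g_max: float
    tau: float
    scaler: float = 1.0
    shifter: float = 0.0
    mt_max: float | None = None
    x0: float | None = None
    xf: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("time_in_target", "movement_time"):
            raise ValueError(f"unknown return form {self.form!r}")
        if self.g_max <= 0 or self.tau <= 0:
            raise ValueError("g_max and tau must be positive")
        if self.form == "time_in_target":
            if self.x0 is None or self.xf is None or not self.xf > self.x0:
                raise ValueError("time_in_target form requires xf > x0")
        else:
            if self.mt_max is None or not self.mt_max > 0:
                raise ValueError("movement_time form requires mt_max > 0")


@dataclass(frozen=True)
class Contrast:
    """A named pair of disjoint condition selectors for EMG analysis.

    ``selector_a``/``selector_b`` map factor name → level; a trial belongs
    to a side when every listed factor matches.  ``window_ms`` is the
    feedback-gain integration width (25 ms for the SLR, else 50 ms).
    ``align_event`` names the trial event the analysis is aligned to.
    """

    name: str
    selector_a: Mapping[str, str]
    selector_b: Mapping[str, str]
    window_ms: int
    align_event: str
    muscle: str = "triceps_lat"

    def __post_init__(self) -> None:
        if not self.selector_a or not self.selector_b:
            raise ValueError("contrast selectors must be non-empty")
        shared = set(self.selector_a) & set(self.selector_b)
        if not any(self.selector_a[f] != self.selector_b[f] for f in shared):
            raise ValueError(f"contrast {self.name!r}: selectors are not disjoint")


@dataclass(frozen=True)
class BaselineRule:
    """Trial-baseline window: alignment event plus offsets in ms."""

    event: str
    start_ms: float = -350.0
    end_ms: float = -300.0


@dataclass(frozen=True)
class TaskGeometry:
    """Radial workspace geometry (cm) used for movement-time measurement."""

    target_distance_cm: float
    target_radius_cm: float
    start_radius_cm: float


@dataclass(frozen=True)
class TaskDesign:
    task_id: str
    factors: Mapping[str, tuple[str, ...]]
    epoch_size: int
    copies_per_combo: int
    n_epochs: int
    epochs_per_block: int
    contrasts: tuple[Contrast, ...]
    baseline_rule: BaselineRule
    mt_definition: str
    return_params: tuple[tuple[Mapping[str, str], ReturnParams], ...]
    geometry: TaskGeometry
    design_constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_combos = int(np.prod([len(v) for v in self.factors.values()]))
        if self.epoch_size != self.copies_per_combo * n_combos:
            raise ConfigurationError(
                f"{self.task_id}: epoch_size {self.epoch_size} != "
                f"copies_per_combo {self.copies_per_combo} x {n_combos} combos"
            )
        if self.n_epochs % self.epochs_per_block:
            raise ConfigurationError(
                f"{self.task_id}: {self.n_epochs} epochs do not divide into "
                f"blocks of {self.epochs_per_block}"
            )
        if self.mt_definition not in (
            "perturbation_to_target_entry",
            "exit_to_target_below_velocity",
        ):
            raise ConfigurationError(f"unknown mt_definition {self.mt_definition!r}")

    @property
    def n_trials(self) -> int:
        return self.n_epochs * self.epoch_size

    @property
    def n_blocks(self) -> int:
        return self.n_epochs // self.epochs_per_block

    def combos(self) -> list[dict[str, str]]:
        """All factor combinations in a fixed (sorted-insertion) order."""
        names = list(self.factors)
        return [
            dict(zip(names, levels))
            for levels in itertools.product(*(self.factors[n] for n in names))
        ]

    def contrast(self, name: str) -> Contrast:
        for c in self.contrasts:
            if c.name == name:
                return c
        raise KeyError(f"task {self.task_id!r} has no contrast {name!r}")

    def return_params_for(self, condition: Mapping[str, str]) -> ReturnParams:
        """Return-function parameters for a trial's factor combination."""
        for selector, params in self.return_params:
            if all(condition.get(f) == lv for f, lv in selector.items()):
                return params
        raise KeyError(f"no return parameters match condition {dict(condition)}")


def _parse_design(doc: Mapping) -> TaskDesign:
    factors = {k: tuple(v) for k, v in doc["factors"].items()}
    contrasts = tuple(
        Contrast(
            name=c["name"],
            selector_a=dict(c["a"]),
            selector_b=dict(c["b"]),
            window_ms=int(c["window_ms"]),
            align_event=c["align_event"],
            muscle=c.get("muscle", "triceps_lat"),
        )
        for c in doc.get("contrasts", [])
    )
    rp = []
    for entry in doc["return_params"]:
        entry = dict(entry)
        selector = dict(entry.pop("select", {}))
        rp.append((selector, ReturnParams(**entry)))
    br = doc["baseline_rule"]
    return TaskDesign(
        task_id=doc["task_id"],
        factors=factors,
        epoch_size=int(doc["epoch_size"]),
        copies_per_combo=int(doc["copies_per_combo"]),
        n_epochs=int(doc["n_epochs"]),
        epochs_per_block=int(doc["epochs_per_block"]),
        contrasts=contrasts,
        baseline_rule=BaselineRule(
            event=br["event"],
            start_ms=float(br.get("start_ms", -350)),
            end_ms=float(br.get("end_ms", -300)),
        ),
        mt_definition=doc["mt_definition"],
        return_params=tuple(rp),
        geometry=TaskGeometry(**doc["geometry"]),
        design_constants=dict(doc.get("design_constants", {})),
    )


def load_design(task_id: str) -> TaskDesign:
    """Load one of the built-in task designs by id (see :data:`TASK_IDS`)."""
    if task_id not in TASK_IDS:
        raise KeyError(f"unknown task id {task_id!r}; known: {TASK_IDS}")
    text = resources.files("rewardemg").joinpath("designs", f"{task_id}.yaml").read_text()
    return _parse_design(yaml.safe_load(text))


def load_design_file(path) -> TaskDesign:
    """Load a user-supplied design from a YAML file (same schema)."""
    with open(path) as fh:
        return _parse_design(yaml.safe_load(fh))


def make_schedule(design: TaskDesign, seed: int) -> pd.DataFrame:
    """Build a randomized trial schedule for ``design``.

    Each epoch contains every factor combination exactly
    ``copies_per_combo`` times, shuffled independently per epoch with a
    generator seeded by ``seed`` — the same (design, seed) pair always
    yields the same schedule.

    Returns a DataFrame with columns ``trial_index`` (0-based), ``epoch``,
    ``block`` and one column per factor.
    """
    rng = np.random.default_rng(seed)
    combos = design.combos()
    rows: list[dict] = []
    for epoch in range(design.n_epochs):
        epoch_trials = combos * design.copies_per_combo
        order = rng.permutation(len(epoch_trials))
        for cond_idx in order:
            rows.append(
                {
                    "trial_index": len(rows),
                    "epoch": epoch,
                    "block": epoch // design.epochs_per_block,
                    **epoch_trials[cond_idx],
                }
            )
    return pd.DataFrame(rows)


def in_out_return(x, params: ReturnParams):
    """Monetary return (cents) for the In-Out Target task.

    ``x`` is the accumulated time in ms spent inside the target between
    perturbation onset and trial end (samples need not be contiguous).
    Non-decreasing in ``x`` and bounded by (0, g_max].
    """
    if params.form != "time_in_target":
        raise ValueError("in_out_return requires time_in_target parameters")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("time in target must be >= 0")
    p = 1.0 - np.minimum((x - params.x0) / (params.xf - params.x0), 1.0)
    out = params.g_max * np.exp(-params.tau * p)
    return float(out) if out.ndim == 0 else out


def mt_return(mt, params: ReturnParams):
    """Monetary return (cents) as a decreasing function of movement time.

    ``return = max(g * (scaler * exp(-tau * MT/mt_max) + shifter), 0)``;
    the shifter sits inside the factor of g, and the result is clipped at
    zero.  Non-increasing in ``mt``.
    """
    if params.form != "movement_time":
        raise ValueError("mt_return requires movement_time parameters")
    mt = np.asarray(mt, dtype=float)
    if np.any(mt < 0):
        raise ValueError("movement time must be >= 0")
    p = mt / params.mt_max
    out = np.maximum(params.g_max * (params.scaler * np.exp(-params.tau * p) + params.shifter), 0.0)
    return float(out) if out.ndim == 0 else out


def time_in_target(trial, design: TaskDesign) -> float:
    """Accumulated time (ms) inside the target from perturbation onset to
    trial end — the performance variable of the In-Out Target task.

    Samples inside the target are counted at the sampling rate and need
    not be contiguous.
    """
    end_after = design.design_constants.get("trial_end_after_perturbation_ms", 800.0)
    t = np.asarray(trial.time_ms, dtype=float)
    pos = np.asarray(trial.radial_pos, dtype=float)
    t0 = trial.events["perturbation"]
    geom = design.geometry
    inside = np.abs(pos - geom.target_distance_cm) <= geom.target_radius_cm
    mask = inside & (t > t0) & (t <= t0 + end_after)
    return float(mask.sum() * 1000.0 / design.design_constants.get("fs_hz", 1000.0))


def movement_time(trial, design: TaskDesign) -> float:
    """Movement time (ms) of one trial under the task's MT definition.

    ``perturbation_to_target_entry`` — time from the (corrected)
    mechanical perturbation to the first sample whose radial position is
    inside the end target, regardless of velocity.

    ``exit_to_target_below_velocity`` — time from leaving the start
    position to the first sample inside the end target with radial speed
    below 10 cm/s; radial velocity is taken from centered finite
    differences of radial position.

    Returns NaN when the criterion is never met (invalid trial, excluded
    downstream).
    """
    geom = design.geometry
    t = np.asarray(trial.time_ms, dtype=float)
    pos = np.asarray(trial.radial_pos, dtype=float)
    inside = np.abs(pos - geom.target_distance_cm) <= geom.target_radius_cm

    if design.mt_definition == "perturbation_to_target_entry":
        t0 = trial.events["perturbation"]
        mask = inside & (t > t0)
        if not mask.any():
            return float("nan")
        return float(t[np.argmax(mask)] - t0)

    # exit_to_target_below_velocity
    out_of_start = pos > geom.start_radius_cm
    if not out_of_start.any():
        return float("nan")
    t_exit = t[np.argmax(out_of_start)]
    dt_s = np.gradient(t) / 1000.0  # ms -> s
    vel = np.gradient(pos) / dt_s  # cm/s, centered differences
    mask = inside & (np.abs(vel) < 10.0) & (t > t_exit)
    if not mask.any():
        return float("nan")
    return float(t[np.argmax(mask)] - t_exit)
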