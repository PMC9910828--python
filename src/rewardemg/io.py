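"""On-disk dataset layout: manifest CSV plus one time-series CSV per trial.

Layout under a dataset directory::

    manifest.csv                  one row per trial: ids, factor levels,
                                  event times (ms), movement time, relative
                                  path of the time-series file
    trials/<pid>_t<trial>.csv     columns time_ms, radial_pos, radial_vel,
                                  then one column per muscle; '#'-prefixed
                                  header lines carry fs and the processing
                                  provenance flag (raw | filtered |
                                  rectified | normalized)
    calibration/<pid>_hold<k>.csv one file per 2 s hold, same header style

This is the documented entry point for real recordings: anything written
in this layout can be read back into the in-memory containers and pushed
through the pipeline.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_emg import CalibrationSet, Dataset, ParticipantData, TrialRecording
from .task_designs import TaskDesign, load_design

__all__ = ["write_dataset", "read_dataset"]

_EVENT_COLS = ("target_onset", "perturbation", "jump", "start_exit", "target_entry")


def _write_series(path: Path, df: pd.DataFrame, fs: int, processing: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz: {fs}\n# processing: {processing}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def _read_series(path: Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        df = pd.read_csv(fh)
    return df, meta


def write_dataset(dataset: Dataset, outdir) -> Path:
    """Write a dataset in the manifest + time-series layout; returns the
    directory path."""
    outdir = Path(outdir)
    (outdir / "trials").mkdir(parents=True, exist_ok=True)
    (outdir / "calibration").mkdir(exist_ok=True)
    fs = dataset.config.fs if dataset.config else 1000
    rows = []
    for part in dataset.participants:
        for k, hold in enumerate(part.calibration.holds):
            df = pd.DataFrame({m: s for m, s in hold.items()})
            df.insert(0, "time_ms", np.arange(len(df)))
            _write_series(
                outdir / "calibration" / f"{part.participant_id}_hold{k}.csv",
                df, fs, part.calibration.processing,
            )
        for tr in part.trials:
            rel = f"trials/{part.participant_id}_t{tr.trial_id:04d}.csv"
            df = pd.DataFrame({"time_ms": tr.time_ms, "radial_pos": tr.radial_pos,
                               "radial_vel": tr.radial_vel})
            for m, s in tr.emg.items():
                df[m] = s
            _write_series(outdir / rel, df, fs, tr.processing)
            # events are prefixed: factor names (e.g. "perturbation") can
            # collide with event names otherwise
            row = {"participant": part.participant_id, "trial": tr.trial_id,
                   **{f: lv for f, lv in tr.condition.items()},
                   **{f"event_{e}": tr.events.get(e, math.nan) for e in _EVENT_COLS},
                   "mt_ms": tr.mt_ms, "path": rel}
            rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.insert(0, "task_id", dataset.design.task_id)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir


def read_dataset(indir, design: TaskDesign | None = None) -> Dataset:
    """Read a dataset previously written with :func:`write_dataset` (or
    real data arranged in the same layout)."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    task_id = manifest["task_id"].iloc[0]
    if design is None:
        design = load_design(task_id)
    factor_names = list(design.factors)
    participants = []
    for pid, sub in manifest.groupby("participant", sort=True):
        holds = []
        fs = 1000
        processing = "raw"
        for k in range(4):
            df, meta = _read_series(indir / "calibration" / f"{pid}_hold{k}.csv")
            fs = int(meta.get("fs_hz", 1000))
            processing = meta.get("processing", "raw")
            holds.append({m: df[m].to_numpy() for m in df.columns if m != "time_ms"})
        cal = CalibrationSet(holds=holds, entry_ms=[0.0] * 4, fs=fs, processing=processing)
        trials = []
        for row in sub.itertuples(index=False):
            df, meta = _read_series(indir / row.path)
            muscles = [c for c in df.columns if c not in ("time_ms", "radial_pos", "radial_vel")]
            events = {
                e: float(getattr(row, f"event_{e}"))
                for e in _EVENT_COLS
                if hasattr(row, f"event_{e}") and np.isfinite(getattr(row, f"event_{e}"))
            }
            trials.append(
                TrialRecording(
                    trial_id=int(row.trial),
                    participant_id=str(pid),
                    condition={f: getattr(row, f) for f in factor_names},
                    events=events,
                    time_ms=df["time_ms"].to_numpy(dtype=float),
                    emg={m: df[m].to_numpy(dtype=float) for m in muscles},
                    radial_pos=df["radial_pos"].to_numpy(dtype=float),
                    radial_vel=df["radial_vel"].to_numpy(dtype=float),
                    processing=meta.get("processing", "raw"),
                    mt_ms=float(row.mt_ms),
                )
            )
        participants.append(ParticipantData(str(pid), cal, trials))
    return Dataset(design=design, config=None, participants=participants)
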