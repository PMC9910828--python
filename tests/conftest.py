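import numpy as np
import pytest

from rewardemg.synthetic_emg import TrialRecording
from rewardemg.task_designs import TASK_IDS, load_design


@pytest.fixture(scope="session")
def designs():
    return {tid: load_design(tid) for tid in TASK_IDS}


def make_trial(
    emg=None,
    *,
    time_ms=None,
    events=None,
    condition=None,
    radial_pos=None,
    radial_vel=None,
    trial_id=0,
    processing="normalized",
):
    """Build a bare TrialRecording around a dict of EMG series (for tests
    that need hand-crafted signals rather than simulated ones)."""
    emg = emg or {}
    n = len(next(iter(emg.values()))) if emg else len(time_ms)
    if time_ms is None:
        time_ms = np.arange(n, dtype=float)
    if radial_pos is None:
        radial_pos = np.zeros(n)
    if radial_vel is None:
        radial_vel = np.zeros(n)
    return TrialRecording(
        trial_id=trial_id,
        participant_id="p00",
        condition=condition or {},
        events=events or {},
        time_ms=np.asarray(time_ms, dtype=float),
        emg={m: np.asarray(s, dtype=float) for m, s in emg.items()},
        radial_pos=np.asarray(radial_pos, dtype=float),
        radial_vel=np.asarray(radial_vel, dtype=float),
        processing=processing,
    )
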