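import numpy as np
import pytest

from gaitdx import features as ft
from gaitdx import preprocess as pp
from gaitdx import synth


def make_trial(seed=0, form=2, duration=8.0, noise_sd=1.0, frame_rate=100.0):
    rng = np.random.default_rng(seed)
    patient = synth.make_patient(f"P{seed:03d}", form, rng)
    return synth.generate_trial(
        patient, duration=duration, frame_rate=frame_rate,
        noise_sd=noise_sd, seed=seed + 1, trial_id=f"P{seed:03d}-T0",
    )


@pytest.fixture(scope="session")
def trial_and_events():
    return make_trial(seed=0)


@pytest.fixture(scope="session")
def trimmed_series(trial_and_events):
    trial, gt = trial_and_events
    sub = pp.subsample(trial, 2)
    trimmed, steps = pp.trim_to_complete_steps(sub, gt.scaled(2))
    return ft.angle_series(trimmed, steps)
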