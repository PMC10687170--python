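import numpy as np
import pandas as pd
import pytest

from motorstates.simulate import GeneratorSpec, simulate_session
from motorstates.task import TRIAL_COLUMNS


def make_trials(se, perturbation=None, speed=None, direction=None, rt=None, subject="t"):
    """Hand-build a completed-trial table from per-trial values."""
    n = len(se)
    perturbation = ["unperturbed"] * n if perturbation is None else perturbation
    speed = ["fast", "slow"] * (n // 2 + 1) if speed is None else speed
    direction = ["down", "right", "up", "left"] * (n // 4 + 1) if direction is None else direction
    rt = np.linspace(0.5, 1.2, n) if rt is None else rt
    df = pd.DataFrame(
        {
            "subject_id": subject,
            "trial_index": np.arange(1, n + 1),
            "speed": list(speed)[:n],
            "direction": list(direction)[:n],
            "perturbation": perturbation,
            "perturb_force": [5.0 if p != "unperturbed" else np.nan for p in perturbation],
            "perturb_angle": [0.0 if p != "unperturbed" else np.nan for p in perturbation],
            "rt_seconds": rt,
            "speed_error": np.asarray(se, float),
            "completed": True,
        }
    )
    df["correct"] = df["speed_error"].abs() <= 0.13
    return df[list(TRIAL_COLUMNS)]


@pytest.fixture(scope="session")
def default_session():
    """One generated session at the default study conditions."""
    return simulate_session(GeneratorSpec(seed=11))


@pytest.fixture(scope="session")
def noiseless_session():
    """Zero-noise session: the model should fit it perfectly."""
    spec = GeneratorSpec(noise_sd_rt=0.0, noise_sd_se=0.0, seed=7)
    return simulate_session(spec)
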