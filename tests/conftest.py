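import numpy as np
import pytest

import skategrf as sg


@pytest.fixture(scope="session")
def noiseless_trial() -> sg.SyntheticTrial:
    """Straight-motion stride with exact markers and unperturbed truth."""
    return sg.simulate_stride(
        sg.SimulationConfig(marker_noise_sd=0.0, direction_perturbation_deg=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def noisy_trial() -> sg.SyntheticTrial:
    """Straight-motion stride with 3 mm marker noise."""
    return sg.simulate_stride(sg.SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def small_cohorts() -> dict[str, list[sg.SyntheticTrial]]:
    """4 participants x 2 trials per motion, default noise, fixed seed."""
    out = {}
    for motion in ("straight", "curve-right", "curve-left"):
        side = "left" if motion == "curve-left" else "right"
        cfg = sg.SimulationConfig(motion=motion, side=side)
        out[motion] = sg.make_cohort(4, 2, cfg, seed=11)
    return out


def random_frame(rng: np.random.Generator) -> sg.LocalFrame:
    """A valid travel-aligned local frame from a random horizontal velocity."""
    v = rng.normal(size=3)
    v[2] *= 0.1
    v[:2] += np.sign(v[:2]) * 1.0  # keep horizontal speed well above eps
    return sg.local_frame(v[None, :])
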