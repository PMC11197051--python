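import dataclasses

import numpy as np
import pytest

from myolabel import (build_schedule, make_params, noise_free_params,
                      simulate_participant)


@pytest.fixture(scope="session")
def small_schedule():
    return build_schedule("biomech", 1)


@pytest.fixture(scope="session")
def noise_free_session(small_schedule):
    return simulate_participant(small_schedule, noise_free_params(seed=3))


@pytest.fixture(scope="session")
def healthy_session():
    """One paper-calibrated participant, 3 reps (fast but representative)."""
    sch = build_schedule("biomech", 3)
    return simulate_participant(sch, make_params("paper_healthy", seed=7))


def single_knob_params(seed, **overrides):
    """Noise-free parameters with selected generator knobs switched on."""
    p = noise_free_params(seed)
    return dataclasses.replace(p, **overrides)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
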