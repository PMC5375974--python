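"""Shared fixtures: small deterministic synthetic shifts."""

import numpy as np
import pytest

from shiftsense import synthgen

SHIFT_START = 1_700_000_000.0


@pytest.fixture(scope="session")
def short_config() -> synthgen.SynthConfig:
    """One-hour shift with two calls (one low-, one high-stress)."""
    return synthgen.SynthConfig(
        seed=11,
        shift_start=SHIFT_START,
        shift_hours=1.0,
        calls=synthgen.default_calls(11, SHIFT_START, 1.0, n_calls=2),
    )


@pytest.fixture(scope="session")
def short_shift(short_config) -> synthgen.SyntheticShift:
    return synthgen.simulate_shift(short_config)


@pytest.fixture(scope="session")
def quiet_config() -> synthgen.SynthConfig:
    """Ten quiet minutes: no calls, for pure-signal checks."""
    return synthgen.SynthConfig(seed=3, shift_start=SHIFT_START,
                                shift_hours=1.0 / 6.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
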