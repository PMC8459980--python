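import numpy as np
import pytest

from ivim_bopt import (
    IVIMParams,
    NoiseProfile,
    PALETTE,
    build_phantom,
    ivim_signal,
    simulate_stack,
)


@pytest.fixture(scope="session")
def palette_b() -> np.ndarray:
    return np.array(PALETTE, dtype=float)


@pytest.fixture(scope="session")
def gm_truth() -> IVIMParams:
    return IVIMParams(S0=1.0, f=0.1, D=1e-3, Dstar=10e-3)


@pytest.fixture(scope="session")
def noiseless_curve(palette_b, gm_truth):
    return palette_b, np.asarray(ivim_signal(gm_truth, palette_b))


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom((10, 10, 1), seed=1)


@pytest.fixture(scope="session")
def noisy_stack(small_phantom):
    """Default-noise 20-repetition full-palette stack, shared across tests."""
    return simulate_stack(
        small_phantom, PALETTE, NoiseProfile.default_brain(), n_reps=20, seed=5
    )


def random_truth(rng: np.random.Generator) -> IVIMParams:
    """Physiological brain-range IVIM parameters for randomized-truth tests."""
    return IVIMParams(
        S0=float(rng.uniform(0.5, 2.0)),
        f=float(rng.uniform(0.02, 0.15)),
        D=float(rng.uniform(0.4e-3, 1.2e-3)),
        Dstar=float(rng.uniform(5e-3, 50e-3)),
    )
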