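import numpy as np
import pytest

from swimpair.hydro import HydroParams, SimState


@pytest.fixture(scope="session")
def params():
    return HydroParams()


@pytest.fixture(scope="session")
def fast_params():
    """Coarser integrator for tests where sub-nanometre accuracy is not
    the point (per-step displacement error ~1e-9 vs the default)."""
    return HydroParams(substeps=16)


def random_resting_state(rng: np.random.Generator, d_range=(8.0, 50.0)) -> SimState:
    bits = rng.integers(0, 2, size=4).astype(bool)
    d = float(rng.uniform(*d_range))
    return SimState.from_bits(bits, d=d, back_centroid=float(rng.uniform(-50, 50)))


def random_mid_stroke_state(rng: np.random.Generator) -> SimState:
    """A state with arbitrary (non-resting) arm lengths in [6, 10]."""
    L = rng.uniform(6.0, 10.0, size=4)
    d = float(rng.uniform(6.0, 50.0))
    x1 = float(rng.uniform(-50, 50))
    x = np.cumsum([x1, L[0], L[1], d, L[2], L[3]])
    bits = L > 8.0
    return SimState(x=x, arm_bits=bits)


def random_rates(rng: np.random.Generator) -> np.ndarray:
    mag = float(rng.uniform(0.5, 4.0))
    ldot = np.zeros(4)
    back = int(rng.integers(-1, 2))
    front = int(rng.integers(-1, 2))
    if back == 0 and front == 0:
        back = 1
    if back != 0:
        ldot[rng.integers(0, 2)] = back * mag
    if front != 0:
        ldot[2 + rng.integers(0, 2)] = front * mag
    return ldot
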