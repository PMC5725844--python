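import numpy as np
import pytest

from scratchsim import run, validate_params


@pytest.fixture()
def default_params():
    return validate_params({"seed": 1})


@pytest.fixture(scope="session")
def default_run():
    """One full default 24 h run (uninhibited T98G scenario), shared by the
    slower integration and acceptance tests."""
    return run(validate_params({"seed": 1}))


@pytest.fixture(scope="session")
def c_inhibited_run():
    """Seed-matched default run with the FAK convergence fully inhibited."""
    return run(validate_params({"seed": 1, "inhibition_C": 1.0}))


def reported_series(result) -> np.ndarray:
    """Per-tick reported average motility, tick 0 excluded."""
    return np.array([f.reported_avg_motility for f in result.frames])[1:]


def add_cells(world, coords, *, released=False, color=0, tracked=False,
              mu=None, cycle=0):
    """Append cells at the given (x, y) coordinates with uniform attributes."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    mu_val = world.mu0 if mu is None else mu
    world.append_cells(
        x=coords[:, 0].copy(),
        y=coords[:, 1].copy(),
        jit_a=np.zeros(n),
        jit_b=np.zeros(n),
        mu=np.full(n, float(mu_val)),
        cycle=np.full(n, cycle, dtype=np.int64),
        color=np.full(n, color, dtype=np.int8),
        released=np.full(n, released, dtype=bool),
        tracked=np.full(n, tracked, dtype=bool),
        trailer_color=np.zeros(n, dtype=np.int32),
    )
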