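import numpy as np
import pytest

from sbrd.geometry import Billiard, Spherocylinder
from sbrd.simulate import SimulationConfig, simulate_smdm_displacements

# the reference cell geometry used throughout: average E. coli dimensions,
# total length 2.25 um, width 0.9 um
STD_LENGTH = 2.25
STD_RADIUS = 0.45


@pytest.fixture(scope="session")
def std_billiard() -> Billiard:
    return Billiard.from_center((0.0, 0.0), STD_LENGTH, STD_RADIUS, 0.0)


@pytest.fixture(scope="session")
def std_shape(std_billiard) -> Spherocylinder:
    return Spherocylinder(std_billiard)


def _run_sim(shape, D, n_particles, total_time, seed):
    cfg = SimulationConfig(
        D_input=D, n_particles=n_particles, shape=shape, total_time=total_time, seed=seed
    )
    return simulate_smdm_displacements(cfg)


@pytest.fixture(scope="session")
def disp_D10(std_shape):
    """~4e5 displacements at D = 10 um^2/s in the reference cell (frame coords)."""
    return _run_sim(std_shape, 10.0, 300, 2.0, seed=101)


@pytest.fixture(scope="session")
def disp_D1(std_shape):
    """~4e5 displacements at D = 1 um^2/s in the reference cell (frame coords)."""
    return _run_sim(std_shape, 1.0, 300, 2.0, seed=102)
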