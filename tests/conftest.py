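import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from radiosem.world import (  # noqa: E402
    Grid,
    RadarConfig,
    StateParams,
    make_grid,
    sample_cardiac_state,
)


@pytest.fixture(scope="session")
def grid_844() -> Grid:
    return make_grid((8, 8, 4))


@pytest.fixture()
def radar_nonoise() -> RadarConfig:
    return RadarConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def normal_state():
    return sample_cardiac_state("NORMAL", 30, seed=11)


@pytest.fixture(scope="session")
def metronome_params() -> StateParams:
    """Zero-variance heart rate: forces exactly 1-s inter-beat intervals."""
    return StateParams(hr_mean=60, hr_sd=0, ibi_cv=0)


def single_scatterer_cube(
    grid: Grid,
    config: RadarConfig,
    node: int,
    displacement=None,
    n_t: int = 64,
):
    """Radar cube for one point reflector sitting on a grid node."""
    from radiosem.world import DisplacementField, simulate_radar

    mask = np.zeros(grid.n_voxels, dtype=bool)
    mask[node] = True
    values = np.zeros((grid.n_voxels, n_t))
    if displacement is not None:
        values[node] = displacement
    field = DisplacementField(
        values=values, grid=grid, fs_hz=config.chirp_rate_hz, torso_mask=mask
    )
    return simulate_radar(field, config, clutter=None, seed=0)
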