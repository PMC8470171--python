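import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# fixed example generation: the suite must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ojiptox.simulate import (
    ContaminantProfile,
    ControlTemplate,
    CurveDataset,
    DatasetConfig,
    TimeGrid,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_grid() -> TimeGrid:
    return TimeGrid(n_points=64, dt=0.05)


def make_profile(
    ec_label="ecA",
    direction=None,
    batch_direction=None,
    ec50=10.0,
    hill=1.5,
    concentrations=(0.0, 1.0, 10.0, 100.0),
) -> ContaminantProfile:
    direction = np.array([0.1, -0.15, 0.1, -0.05, 0.2, -0.1, 0.05]) if direction is None else direction
    batch = np.zeros(7) if batch_direction is None else batch_direction
    return ContaminantProfile(
        ec_label=ec_label,
        direction=np.asarray(direction, dtype=float),
        batch_direction=np.asarray(batch, dtype=float),
        ec50=ec50,
        hill=hill,
        concentrations=concentrations,
    )


@pytest.fixture(scope="session")
def two_class_dataset(small_grid) -> CurveDataset:
    """Two well-separated contaminants, short grid: a fast classification fixture."""
    d = np.zeros(7)
    d[1] = 0.3  # ecA raises the J amplitude with dose
    e = np.zeros(7)
    e[2] = -0.3  # ecB lowers the I amplitude
    b1 = np.zeros(7); b1[0] = 0.05
    b2 = np.zeros(7); b2[0] = -0.05
    cfg = DatasetConfig(
        profiles=(
            make_profile("ecA", d, b1, concentrations=(0.0, 5.0, 20.0)),
            make_profile("ecB", e, b2, concentrations=(0.0, 5.0, 20.0)),
        ),
        replicates_per_cell=20,
        noise_cv=0.01,
        rep_cv=0.005,
        master_seed=11,
        grid=small_grid,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def tiny_dataset(small_grid) -> CurveDataset:
    rng = np.random.default_rng(0)
    values = np.abs(rng.lognormal(7.0, 0.1, size=(10, small_grid.n_points))) + 100
    values = np.sort(values, axis=1)  # nondecreasing, positive
    meta = pd.DataFrame(
        {
            "ec_label": ["ecA"] * 5 + ["ecB"] * 5,
            "concentration": [0.0, 0.0, 1.0, 1.0, 2.0] * 2,
            "replicate_id": list(range(5)) * 2,
        }
    )
    return CurveDataset(time=small_grid, values=values, meta=meta)
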