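
import pandas as pd
import pytest

import canopydissect as cd
from canopydissect.experiments import ZERO_VARIABILITY


@pytest.fixture(scope="session")
def uniform_spec():
    """A single deterministic genotype (all variability zero)."""
    panel = cd.generate_panel(1, variability=ZERO_VARIABILITY, seed=7)
    return panel.specs[0]


@pytest.fixture(scope="session")
def small_panel():
    return cd.generate_panel(5, seed=3)


def make_canopy(spec, n, spacing, thermal_time=45.0, noise=0.0, seed=0):
    """A regular n x n grid of one genotype; returns (plants, bounds, density)."""
    plants = [
        cd.build_plant_mesh(
            spec,
            thermal_time,
            ((i + 0.5) * spacing, (j + 0.5) * spacing),
            replicate_noise=noise,
            seed=seed,
            plant_id=f"p{i:02d}_{j:02d}",
        )
        for i in range(n)
        for j in range(n)
    ]
    bounds = ((0.0, n * spacing), (0.0, n * spacing))
    return plants, bounds, 1.0 / spacing**2


@pytest.fixture(scope="session")
def small_canopy(uniform_spec):
    plants, bounds, density = make_canopy(uniform_spec, 4, 0.4)
    return plants, bounds, density


def interception_frame(plants, result, r_i):
    return pd.DataFrame(
        {
            "plant_id": [p.plant_id for p in plants],
            "x": [p.position[0] for p in plants],
            "y": [p.position[1] for p in plants],
            "leaf_area": [p.leaf_area for p in plants],
            "r_i": r_i,
            "r_plant": [result.r_plant[p.plant_id] for p in plants],
        }
    )
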