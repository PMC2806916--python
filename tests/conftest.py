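import numpy as np
import pandas as pd
import pytest

from seepscape import DepthGrid, ProfileTable, TransportSystem


@pytest.fixture
def grid30() -> DepthGrid:
    """30 cm domain at 0.1 cm spacing."""
    return DepthGrid.uniform(30.0, 0.1)


@pytest.fixture
def diffusion_system(grid30) -> TransportSystem:
    """Diffusion-only system: no burial, no bioirrigation, zero-gradient bottom."""
    return TransportSystem(grid30, porosity=0.8, molecular_diffusivity=5e-6,
                           overlying_concentration=28.0)


@pytest.fixture
def sulfate_table() -> ProfileTable:
    """A well-formed 3 cm-interval sulfate table for one core."""
    return ProfileTable(pd.DataFrame({
        "core_id": "MatB",
        "variable": "sulfate",
        "depth_top_cm": [0.0, 3.0, 6.0, 9.0],
        "depth_bottom_cm": [3.0, 6.0, 9.0, 12.0],
        "value": [26.93333333, 12.1, 3.4, 0.8123456789],
        "replicate": [1, 1, 1, 1],
    }))


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with zero diagonal and entries in (0, 1)."""
    d = rng.uniform(0.001, 0.999, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d
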