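import numpy as np
import pytest

from ramancaf import (
    SimConfig,
    SpectralDataset,
    WavenumberGrid,
    default_profiles,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_grid() -> WavenumberGrid:
    return WavenumberGrid(np.arange(400.0, 1801.0, 2.0))  # 701 points


@pytest.fixture(scope="session")
def tiny_dataset() -> SpectralDataset:
    """4 spectra x 5 channels, two classes, two cells; hand-countable."""
    grid = WavenumberGrid(np.array([400.0, 500.0, 600.0, 700.0, 800.0]))
    rng = np.random.default_rng(42)
    matrix = rng.normal(10.0, 1.0, size=(4, 5))
    return SpectralDataset(
        grid=grid,
        matrix=matrix,
        labels=np.array(["A", "A", "B", "B"], dtype=object),
        cell_ids=np.array(["c1", "c1", "c2", "c2"], dtype=object),
        class_order=("A", "B"),
        pixels=np.array([[0, 0], [1, 0], [0, 0], [1, 0]]),
    )


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Reduced study design for fast end-to-end tests: 3/3/3 cells x 20 px."""
    return SimConfig(
        profiles=default_profiles(),
        cells_per_class={"HPaSC": 3, "HPaSC_iCAF": 3, "HPaSC_myCAF": 3},
        pixels_per_cell=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim_dataset(small_sim_config) -> SpectralDataset:
    return simulate_dataset(small_sim_config)
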