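import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIXTURE_SEED = 7
MODEL_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def truth():
    """The canonical synthetic dataset: 200 kb over three chromosomes,
    20 bound sites, two cell types with different accessible subsets."""
    from attnbind.simulate import SimulationConfig, simulate

    return simulate(SimulationConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def uniqueness(truth):
    from attnbind.features import uniqueness_track

    return uniqueness_track(truth.genome)


@pytest.fixture(scope="session")
def cells(truth, uniqueness):
    from attnbind.pipeline import prepare_cell

    return {
        cell: prepare_cell(truth, cell, uniqueness)
        for cell in truth.cell_names()
    }


@pytest.fixture(scope="session")
def benchmark(truth, uniqueness):
    """Three seeded training runs of the desk-scale cross-cell-type
    benchmark (train cellA on chrA+chrB, validate on chrC, evaluate the
    held-out cellB on chrB+chrC)."""
    from attnbind.pipeline import run_synthetic_benchmark

    return run_synthetic_benchmark(
        truth, MODEL_SEEDS, uniqueness=uniqueness
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
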