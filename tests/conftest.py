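import numpy as np
import pytest

from polygs import simulate as sim


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-lineage program: fast but structurally complete."""
    return sim.SimulationConfig(
        n_markers=120,
        n_qtl=25,
        effective_size=80,
        burn_in=40,
        polycross_size=60,
        n_families=3,
        n_mothers=20,
        progeny_per_family=8,
        n_plots=4,
        trait_h2={"wsc": 0.4, "dmd": 0.3},
        selection_trait="wsc",
        generations={"Intermediate": ["F13", "F14"], "Late": ["F5"]},
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return sim.simulate_program(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
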