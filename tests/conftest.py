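import warnings

import pytest

from pcmat import SimulationConfig, run_simulation

# analysis warnings (tiny gates etc.) are expected in small fixtures
warnings.filterwarnings("ignore", message="gating only")


@pytest.fixture(scope="session")
def default_run():
    """One default 14-day simulation, shared across tests."""
    return run_simulation(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def quiet_config():
    """A stripped config for mechanistic unit checks.

    No selection, no mutation, no death, no influx; deterministic budgets.
    Useful for exact division-arithmetic oracles.
    """
    return SimulationConfig(
        n_founders=1,
        founder_influx_rate=0.0,
        founder_affinity_sigma=0.0,
        mutation_rate=0.0,
        selection_fraction=0.0,
        pc_export_prob=0.0,
        pc_death_rate=0.0,
        gc_death_rate=0.0,
        pc_egress_rate=0.0,
        budget_mode="deterministic",
        label_noise_sigma=0.0,
        horizon_steps=1,
        seed=0,
    )
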