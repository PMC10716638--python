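import pytest

from gazedpa.simulate import SimulationConfig, build_design, simulate_gaze


@pytest.fixture(scope="session")
def tiny_config():
    """4 participants, 4 gendered + 4 neutral items: fast structural checks."""
    return SimulationConfig(n_participants=4, n_gendered=4, n_neutral=4, seed=11)


@pytest.fixture(scope="session")
def tiny_experiment(tiny_config):
    design = build_design(tiny_config, seed=11)
    table, truth = simulate_gaze(design, tiny_config, seed=12)
    return design, table, truth


@pytest.fixture(scope="session")
def small_config():
    """8 participants, 8 + 8 items: enough structure for analysis tests."""
    return SimulationConfig(n_participants=8, n_gendered=8, n_neutral=8, seed=21)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    design = build_design(small_config, seed=21)
    table, truth = simulate_gaze(design, small_config, seed=22)
    return design, table, truth


@pytest.fixture(scope="session")
def default_experiment():
    """One full-size experiment under the study-design defaults."""
    cfg = SimulationConfig(seed=101)
    design = build_design(cfg, seed=101)
    table, truth = simulate_gaze(design, cfg, seed=102)
    return design, table, truth
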