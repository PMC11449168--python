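import numpy as np
import pytest

from crocsoc.synthetic_data import (
    SyntheticTruth,
    TelemetryScenario,
    fixture_scenario,
    simulate_behaviour_panel,
    simulate_detections,
)


@pytest.fixture(scope="session")
def soc_half():
    return fixture_scenario("soc_half")


@pytest.fixture(scope="session")
def coa_weighted():
    return fixture_scenario("coa_weighted")


@pytest.fixture(scope="session")
def vi_disjoint():
    return fixture_scenario("vi_disjoint")


@pytest.fixture(scope="session")
def small_study():
    """A small simulated telemetry study shared across I/O and metric tests."""
    scenario = TelemetryScenario(
        n_individuals=5, duration_days=30, receiver_spacing_km=2.5, seed=7
    )
    return simulate_detections(scenario)


@pytest.fixture(scope="session")
def small_panel():
    """A model-scale behaviour panel at desk size with its truth."""
    truth = SyntheticTruth().with_(n_individuals=25, n_months=18)
    panel, truth, effects = simulate_behaviour_panel(truth, seed=42)
    return panel, truth, effects


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """One short DHGLM fit reused by summary/derived-statistic tests."""
    import warnings

    from crocsoc.dhglm import SamplerConfig, fit_dhglm, prepare_model_data

    panel, truth, _ = small_panel
    data = prepare_model_data(panel, transform=False)
    cfg = SamplerConfig(chains=1, iterations=500, warmup=250, thin=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        draws = fit_dhglm(data, sampler=cfg, seed=5)
    return draws, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
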