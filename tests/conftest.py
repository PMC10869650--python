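import numpy as np
import pytest

from trialcua import (
    AdditiveMapping,
    AnalysisOptions,
    TrialConfig,
    UnitCostTable,
    UtilityTariff,
    generate_trial,
)


@pytest.fixture(scope="session")
def tariff():
    return UtilityTariff.default_uk()


@pytest.fixture(scope="session")
def iciq_mapping():
    return AdditiveMapping.default_iciq()


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable.toy_default()


@pytest.fixture(scope="session")
def small_config():
    return TrialConfig(n_per_arm=60, n_centres=6, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def complete_config():
    return TrialConfig(n_per_arm=60, n_centres=6, target_missing_fraction=0.0, seed=42)


@pytest.fixture(scope="session")
def complete_dataset(complete_config):
    return generate_trial(complete_config)


@pytest.fixture()
def fast_options():
    return AnalysisOptions(m=3, knn=5, n_bootstrap=40, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
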