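import pandas as pd
import pytest

from pyrethrisk import GeneratorConfig, generate_primo_table, load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def default_generation(registry):
    """One seeded synthetic dietary table shared across tests."""
    config = GeneratorConfig(seed=0)
    records, truth = generate_primo_table(config, registry)
    return config, records, truth


@pytest.fixture()
def three_row_dcca_records():
    """Minimal hand-checkable fixture: the three DCCA producers in one diet-year."""
    return pd.DataFrame(
        {
            "diet_id": ["D1"] * 3,
            "diet_label": ["XX general"] * 3,
            "year": [2018] * 3,
            "substance": ["cyfluthrin", "cypermethrin", "permethrin"],
            "scenario": ["middle"] * 3,
            "percent_adi": [10.0, 20.0, 5.0],
        }
    )
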