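import pandas as pd
import pytest

from faersignal import (
    MedDRAHierarchy,
    PlantedSignal,
    SyntheticConfig,
    generate_bundle,
    prepare_dataset,
    synthetic_meddra_map,
)


@pytest.fixture(scope="session")
def planted_config():
    """Small bundle with one strong planted signal on the target drug."""
    return SyntheticConfig(
        n_cases=3000,
        seed=42,
        planted_signals=[PlantedSignal("TARGETDRUG", "PT_030", 50.0)],
    )


@pytest.fixture(scope="session")
def planted_bundle(planted_config):
    return generate_bundle(planted_config)


@pytest.fixture(scope="session")
def planted_dataset(planted_config, planted_bundle):
    tables, _ = planted_bundle
    meddra = MedDRAHierarchy.from_frame(synthetic_meddra_map(planted_config))
    return prepare_dataset(tables, ["TARGETDRUG"], meddra=meddra)


@pytest.fixture()
def meddra_frame():
    return pd.DataFrame(
        {
            "PT": ["Bradycardia", "Cardiac arrest", "Diabetes insipidus"],
            "HLT": ["Rate disorders", "Cardiac arrests", "ADH disorders"],
            "HLGT": ["Arrhythmias", "Arrhythmias", "Endocrine"],
            "SOC": ["Cardiac disorders", "Cardiac disorders", "Endocrine disorders"],
        }
    )
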