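import pandas as pd
import pytest
from hypothesis import settings

from mlchia import load_compound_table, paper_micellar_system

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compound_table() -> pd.DataFrame:
    """The bundled 18-compound table (log P_mw, PSA, experimental %HIA)."""
    return load_compound_table()


@pytest.fixture(scope="session")
def training_table(compound_table) -> pd.DataFrame:
    return compound_table[compound_table["role"] == "train"]


@pytest.fixture(scope="session")
def validation_table(compound_table) -> pd.DataFrame:
    return compound_table[compound_table["role"] == "validation"]


@pytest.fixture(scope="session")
def paper_mixture():
    return paper_micellar_system()
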