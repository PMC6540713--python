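import pandas as pd
import pytest

from snowcept.interception_model import InterceptionParams
from snowcept.io import load_table2, table2_path


@pytest.fixture(scope="session")
def troughs():
    """The packaged 56-point trough table as domain records."""
    return load_table2()


@pytest.fixture(scope="session")
def trough_df():
    """The packaged trough table as a DataFrame (printed percent scale)."""
    return pd.read_csv(table2_path())


@pytest.fixture(scope="session")
def revised_params():
    return InterceptionParams.revised()


@pytest.fixture(scope="session")
def original_params():
    return InterceptionParams.pomeroy_hedstrom()
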