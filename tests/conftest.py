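import numpy as np
import pytest

from coastnis import packaged_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 30-site two-island survey."""
    return packaged_table1()


@pytest.fixture(scope="session")
def table1_no_outliers(table1):
    """The survey with the two detached distance-to-port sites removed."""
    from coastnis import flag_outliers, remove_outliers

    return remove_outliers(table1, flag_outliers(table1, "dist_port_km"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160909)
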