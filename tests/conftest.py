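import pytest

from kpqspr import external_validation, fit_ols, load_table1, split_by_flag


@pytest.fixture(scope="session")
def table1():
    """The packaged canonical 50-compound dataset."""
    return load_table1()


@pytest.fixture(scope="session")
def table1_split(table1):
    return split_by_flag(table1)


@pytest.fixture(scope="session")
def full_fit(table1):
    """Two-descriptor OLS fit on all 50 compounds."""
    return fit_ols(table1, descriptors=("alpha", "vsmin"))


@pytest.fixture(scope="session")
def ext_result(table1):
    """Fixed-split external validation on the canonical dataset."""
    return external_validation(table1)
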