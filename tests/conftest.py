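import pytest

from npnorm import load_norm_tables, load_tscore_formulas


@pytest.fixture(scope="session")
def tables():
    return load_norm_tables()


@pytest.fixture(scope="session")
def formulas():
    return load_tscore_formulas()
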