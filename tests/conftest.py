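import pytest

from msistrat import builtin_strategies, table1_defaults


@pytest.fixture(scope="session")
def config():
    return table1_defaults()


@pytest.fixture(scope="session")
def strategies(config):
    return {s.name: s for s in builtin_strategies(config)}
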