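import pytest

from micapop.alleles import default_groups, parse_allele


def a(name: str):
    """Shorthand allele constructor for tests."""
    return parse_allele(name)


@pytest.fixture(scope="session")
def table1_groups():
    """The packaged ambiguity-group fixture (five groups)."""
    return default_groups()
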