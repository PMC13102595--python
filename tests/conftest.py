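import numpy as np
import pytest

from selenopep import (
    load_default_table, parse_peptide, selera_fixture,
)


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def fixture_bundle():
    return selera_fixture()


@pytest.fixture(scope="session")
def selera(table, fixture_bundle):
    """Parsed designed selenopeptides keyed by name."""
    return {
        name: parse_peptide(seq, table, id=name)
        for name, seq in fixture_bundle.designs.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_peptide_tokens(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWYU"):
    return tuple(rng.choice(list(alphabet), size=length))
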