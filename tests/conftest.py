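import numpy as np
import pytest

from mircane.catalog import reference_mature_queries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def catalog_queries():
    return reference_mature_queries()


@pytest.fixture(scope="session")
def distinct_queries(catalog_queries=None):
    from mircane.catalog import reference_mature_queries

    seen, out = set(), []
    for q in reference_mature_queries():
        if q.residues not in seen:
            seen.add(q.residues)
            out.append(q)
    return out


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
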