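import pytest

from genestitch import DesignParameters, random_gene, screen_tm_settings


@pytest.fixture(scope="session")
def default_params():
    return DesignParameters()


@pytest.fixture(scope="session")
def kilobase_design():
    """One screened design of a ~1 kb random gene, shared across tests."""
    gene = random_gene(1000, gc_fraction=0.5, seed=42)
    return screen_tm_settings(gene)
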