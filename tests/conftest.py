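import pytest

import spkmix as sx


@pytest.fixture(scope="session")
def bursting():
    return sx.build_fixture("bursting_gene")


@pytest.fixture(scope="session")
def self_gene_coop():
    return sx.build_fixture("self_regulating_gene")


@pytest.fixture(scope="session")
def self_gene_noncoop():
    return sx.build_fixture("self_regulating_gene", cooperative=False)


@pytest.fixture(scope="session")
def toggle():
    return sx.build_fixture("toggle_switch", n=2)


@pytest.fixture(scope="session")
def small_toggle():
    """Non-cooperative toggle with small copy numbers, cheap to solve
    exactly on a truncated lattice."""
    return sx.build_fixture(
        "toggle_switch", n=1, k0=10.0, k_minus=2.0, alpha=1.0, alpha_=2.0,
        epsilon=0.1,
    )


@pytest.fixture(scope="session")
def coupled():
    return sx.build_fixture("coupled_toggles")
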