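import pytest

from exonweave import fixtures


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small planted-gene scenario shared across read-only tests."""
    cfg = fixtures.FixtureConfig(
        seed=11,
        n_genes=6,
        sequence_length=40_000,
        n_donor_proteomes=2,
        protein_divergence=0.02,
    )
    return fixtures.make_fixture(cfg)


@pytest.fixture(scope="session")
def clean_fixture():
    """Divergence 0, no corruption: every junction perfectly conserved."""
    cfg = fixtures.FixtureConfig(
        seed=5, n_genes=8, sequence_length=60_000, n_donor_proteomes=1
    )
    return fixtures.make_fixture(cfg)
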