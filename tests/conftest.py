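import pytest

from negset.fixtures import FixtureSpec, make_biounit, make_pipeline_fixture


@pytest.fixture(scope="session")
def pipeline_fixture(tmp_path_factory):
    """One full synthetic input bundle shared across the suite."""
    return make_pipeline_fixture(tmp_path_factory.mktemp("bundle"), seed=202)


@pytest.fixture()
def two_chain_fixture(tmp_path):
    """A 2-chain biological unit with a 12 Å gap (clearly non-interacting)."""
    spec = FixtureSpec(
        n_chains=2, pairwise_gaps={("A", "B"): 12.0}, seed=1
    )
    return make_biounit(spec, tmp_path)
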