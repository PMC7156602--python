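import numpy as np
import pytest

from rnasmc import FixtureSpec, generate_fixtures, nussinov_backend


@pytest.fixture(scope="session")
def backend():
    """The built-in pair-maximization folding backend (shared, stateless)."""
    return nussinov_backend()


@pytest.fixture(scope="session")
def small_fixture_set():
    """A reproducible synthetic dataset: 20 transcripts, one planted SNP each."""
    return generate_fixtures(
        FixtureSpec(n_transcripts=20, length_range=(90, 140), seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


# A 37-nt structure whose decomposition contains every element kind:
# two outer stems around a multibranch loop; one branch is a plain
# stem-hairpin, the other stacks a bulge and an interior loop.
ALL_KINDS_DB = "((..((...))..((.((..((...))..))))..))"
ALL_KINDS_SEQ = "A" * len(ALL_KINDS_DB)


@pytest.fixture(scope="session")
def all_kinds_structure():
    from rnasmc import parse_dotbracket

    return parse_dotbracket(ALL_KINDS_DB, ALL_KINDS_SEQ, seq_id="allkinds")
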