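import numpy as np
import pytest

from bestop.seqio import NucSequence
from bestop.simulate import AmpliconSimSpec, make_amplicon_with_sites, simulate_amplicon_reads


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def one_site_amplicon():
    """A synthetic amplicon with one plus-strand protospacer whose only C
    sits at protospacer position 5."""
    return make_amplicon_with_sites(n_sites=1, spacer_c_positions={0: (5,)}, seed=7)


@pytest.fixture(scope="session")
def simulated_run():
    """A 2,000-read simulation with editing, indels and sequencing error,
    shared by tests that only inspect it."""
    ref, sites = make_amplicon_with_sites(n_sites=1, spacer_c_positions={0: (5,)}, seed=7)
    spec = AmpliconSimSpec(
        reference=ref,
        sites=sites,
        per_position_edit_prob={("gRNA1", 5): 0.2},
        indel_prob=0.05,
        subst_error_rate=0.001,
        depth=2000,
        seed=41,
    )
    reads, truth = simulate_amplicon_reads(spec)
    return spec, reads, truth
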