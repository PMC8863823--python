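import pytest

from ifnscan.synthetic_data import generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A compact synthetic genome with 2 positives and one decoy per class."""
    return generate_genome(n_pos=2, n_decoy=6, genome_len=250_000, seed=7)
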