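import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from polyaslide.orf_io import OrfRecord
from polyaslide.synthetic_data import NON_LYSINE_SENSE_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cds(rng, n_codons, p_lysine=0.1):
    """A strict-valid random CDS as a codon tuple."""
    body = []
    for _ in range(n_codons):
        if rng.random() < p_lysine:
            body.append("AAA" if rng.random() < 0.6 else "AAG")
        else:
            body.append(NON_LYSINE_SENSE_CODONS[rng.integers(59)])
    return ("ATG", *body, "TAA")


@pytest.fixture
def random_orfs(rng):
    return [
        OrfRecord(id=f"orf{i}", codons=random_cds(rng, int(rng.integers(5, 60))))
        for i in range(50)
    ]
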