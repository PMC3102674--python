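import numpy as np
import pytest

from plastdiv.align import LocusAlignment, Sample


def make_alignment(rows, locus="loc1", feature="IGS", region="LSC", species=None):
    """Alignment with samples s1..sn; species defaults to one per sample."""
    samples = [
        Sample(f"s{i + 1}", "G", species[i] if species else f"sp{i + 1}")
        for i in range(len(rows))
    ]
    return LocusAlignment(locus, feature, region, samples, list(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def aln_factory():
    return make_alignment
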