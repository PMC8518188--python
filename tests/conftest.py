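import numpy as np
import pytest

from hcbha.io_core import ContigSeq, ReadSet, SequenceRead
from hcbha.simdata import CommunitySpec, generate_community

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_community():
    """Three unrelated 20-kb circular genomes with ground truth."""
    spec = CommunitySpec(n_genomes=3, length_range=(20_000, 20_000), seed=7)
    return generate_community(spec)


def make_reads(seqs, platform="long", quals=None, prefix="r"):
    reads = []
    for i, s in enumerate(seqs):
        q = quals[i] if quals else None
        reads.append(SequenceRead(id=f"{prefix}{i}", bases=s, quals=q,
                                  platform=platform))
    return ReadSet(reads)


def tile_reads(genome: str, read_len: int, step: int, circular=False,
               prefix="t"):
    """Error-free reads tiling a genome at fixed stride."""
    reads = []
    n = len(genome)
    src = genome + genome[:read_len] if circular else genome
    limit = n if circular else n - read_len + 1
    for i, start in enumerate(range(0, limit, step)):
        reads.append(SequenceRead(id=f"{prefix}{i}",
                                  bases=src[start:start + read_len],
                                  platform="long"))
    return ReadSet(reads)
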