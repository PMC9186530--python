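import numpy as np
import pytest

from hapasm.seqmodel import Read, Sequence, TruthInterval


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_bases(rng, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                      size=n).tobytes().decode()


@pytest.fixture
def tiling_reads():
    """Error-free reads tiling a random 20 kbp genome every 1 kbp."""
    from hapasm import simulate as sim
    genome, _ = sim.simulate_genome(sim.GenomeSpec(seed=5, backbone_len=20_000))
    reads = []
    for i, s in enumerate(range(0, len(genome.bases) - 4000 + 1, 1000)):
        reads.append(Read(Sequence(f"r{i}", genome.bases[s:s + 4000]), "hifi",
                          TruthInterval(genome.id, s, s + 4000, "+")))
    return genome, reads
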