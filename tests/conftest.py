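import pytest

from aquasrna.io_formats import ReferenceSet, SmallRNARead
from aquasrna.simulate import generate_reads, generate_references, tank_preset


def make_refset(role: str, seqs: dict[str, str], name: str = "test") -> ReferenceSet:
    return ReferenceSet(name, role, tuple(seqs.items()))


def make_read(seq: str, read_id: str = "r1", quality: int | None = 40) -> SmallRNARead:
    qual = (quality,) * len(seq) if quality is not None else None
    return SmallRNARead(read_id, seq, qual)


@pytest.fixture(scope="session")
def tank_sample():
    """A seeded rearing-tank-like synthetic sample (references, raw
    reads with adapters, truth), shared across tests."""
    config = tank_preset(seed=11, n_reads=3000)
    refs = generate_references(config)
    reads, truth = generate_reads(config, refs)
    return config, refs, reads, truth
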