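import pytest

from tripletrep import simulate
from tripletrep.pools import PoolRecord, RibozymeReference, SequencePool


@pytest.fixture(scope="session")
def toy_ref() -> RibozymeReference:
    """Two GC-rich toy subunits standing in for the ribozyme (+) strands."""
    return simulate.gen_reference(seed=7, lengths=(180, 90), gc=0.6)


@pytest.fixture()
def tiny_pool() -> SequencePool:
    return SequencePool(
        [
            PoolRecord(id="a", sequence="GCGCGCGCGCGC", cycle=5),
            PoolRecord(id="b", sequence="AUAUAUAUAUAU", cycle=5, weight=2.0),
            PoolRecord(id="c", sequence="GGGCCCAAAUUU", cycle=9),
        ]
    )
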