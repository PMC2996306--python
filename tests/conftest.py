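import numpy as np
import pytest

from contigforge.io_formats import QualRead
from contigforge.synthetic_data import SimConfig, gen_transcriptome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_transcripts(rng):
    """Five random CDS transcripts with their translations."""
    cfg = SimConfig(seed=42, n_transcripts=5)
    return gen_transcriptome(cfg, rng)


def make_read(seq: str, q: int = 40, rid: str = "r1", mate: int = 0) -> QualRead:
    return QualRead(rid, seq, [q] * len(seq), mate)


@pytest.fixture
def make_qual_read():
    return make_read
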