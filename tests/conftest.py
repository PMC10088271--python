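import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from g4telo.pqs_scan import PQSHit
from g4telo.seqio import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20230410)


def make_hit(seqid: str, start: int, end: int, strand: str = "+", score: int = 60) -> PQSHit:
    """Minimal PQSHit for interval-level tests (runs/loops immaterial)."""
    return PQSHit(
        interval=GenomicInterval(seqid, start, end, strand),
        score=score,
        n_tetrads=3,
        run_spans=(),
        loop_lengths=(1, 1, 1),
        n_defects=0,
        motif="G" * (end - start),
    )


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.array(list("GCAT"))
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))
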