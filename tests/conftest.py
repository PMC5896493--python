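import random

import numpy as np
import pytest

from haplopipe.seqio import QualityRead, UniqueSeq

BASES = "ACGT"


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def random_uniques(
    rng: random.Random,
    n_max: int = 30,
    seq_len: int = 10,
    samples: tuple[str, ...] = ("s1",),
) -> list[UniqueSeq]:
    """Distinct random sequences with random counts; mimics a pooled,
    dereplicated input."""
    n = rng.randint(1, n_max)
    seqs = set()
    while len(seqs) < n:
        # mix of near-identical and distant sequences to exercise skew logic
        if seqs and rng.random() < 0.6:
            base = rng.choice(sorted(seqs))
            pos = rng.randrange(len(base))
            seqs.add(base[:pos] + rng.choice(BASES) + base[pos + 1:])
        else:
            seqs.add(random_seq(rng, seq_len))
    out = []
    for s in sorted(seqs):
        counts = {
            sample: rng.randint(1, 10_000)
            for sample in samples
            if rng.random() < 0.8
        }
        if not counts:
            counts = {samples[0]: rng.randint(1, 10_000)}
        out.append(UniqueSeq(seq=s, counts=counts))
    return out


def make_read(seq: str, q: int = 40, rid: str = "r") -> QualityRead:
    return QualityRead(id=rid, seq=seq, qual=np.full(len(seq), q, dtype=np.int16))


@pytest.fixture
def rng():
    return random.Random(20240917)
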