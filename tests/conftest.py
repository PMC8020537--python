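import random

import pytest

from coidenoise.sequence_io import UniqueSequence

BASES = "ACGT"


def us(seq: str, count: int, id: str | None = None) -> UniqueSequence:
    return UniqueSequence(id=id or f"s_{seq[:8]}_{count}", sequence=seq, count=count)


def random_dataset(
    rng: random.Random, n: int, length: int = 30, max_count: int = 2000
) -> list[UniqueSequence]:
    """A dereplicated dataset with clustered structure: a few seeds plus
    near-copies at small Hamming distances, abundances spanning the range
    where merges are possible."""
    seeds = ["".join(rng.choice(BASES) for _ in range(length)) for _ in range(max(1, n // 5))]
    seqs: dict[str, int] = {}
    while len(seqs) < n:
        base = rng.choice(seeds)
        k = rng.randint(0, 4)
        s = list(base)
        for _ in range(k):
            pos = rng.randrange(length)
            s[pos] = rng.choice([b for b in BASES if b != s[pos]])
        seq = "".join(s)
        if seq not in seqs:
            seqs[seq] = rng.choice([1, 1, 2, 3, 5, 10, 80, 200, max_count])
    return [us(seq, c, id=f"r{i}") for i, (seq, c) in enumerate(seqs.items())]


@pytest.fixture
def toy_dataset() -> list[UniqueSequence]:
    return [
        us("AAATTTCCCGGG", 100, "a"),
        us("AAATTTCCCGGA", 1, "b"),
        us("TTTTTTCCCGGG", 40, "c"),
    ]
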