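"""Naive reference implementations used as independent oracles.

Deliberately literal and unoptimised: full pairwise distances, direct rule
application, pure Python.  The package implementation must match these on
random instances.
"""

from __future__ import annotations

from coidenoise.sequence_io import UniqueSequence


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def naive_classic_denoise(
    seqs: list[UniqueSequence], alpha: float
) -> tuple[dict[str, int], dict[str, str]]:
    """Literal skew-precedence denoising.

    Returns (centroid id -> accumulated reads, daughter id -> centroid id).
    """
    ordered = sorted(seqs, key=lambda s: (-s.count, s.sequence))
    centroids: list[UniqueSequence] = []
    totals: dict[str, int] = {}
    merged_into: dict[str, str] = {}
    for s in ordered:
        home = None
        for c in centroids:
            d = hamming(s.sequence, c.sequence)
            if c.count > 0 and s.count / c.count <= 1.0 / 2.0 ** (alpha * d + 1.0):
                home = c
                break
        if home is None:
            centroids.append(s)
            totals[s.id] = s.count
        else:
            totals[home.id] += s.count
            merged_into[s.id] = home.id
    return totals, merged_into


def naive_single_linkage(seqs: list[UniqueSequence], d: int) -> list[frozenset[str]]:
    """Union-find over the full distance matrix."""
    ids = [s.id for s in seqs]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if hamming(seqs[i].sequence, seqs[j].sequence) <= d:
                parent[find(ids[i])] = find(ids[j])
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]
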