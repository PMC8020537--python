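"""Single-linkage MOTU construction and clustering-distance diagnostics.

MOTUs (molecular operational taxonomic units, species-level proxies) are the
connected components of the graph linking every pair of sequences at
distance <= d.  All member sequences are retained inside each MOTU — not
just the representative — so downstream analyses can work at either the
MOTU or the sequence level.

This is the linkage phase only: the subsequent topological refinement that
SWARM applies using abundance structure is published elsewhere and not
reimplemented here, so intra-MOTU distances on real-like data will run
higher than a refined clustering would give.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .sequence_io import UniqueSequence, canonical_sort, check_dereplicated

__all__ = ["Motu", "cluster", "motu_distance_stats", "MotuDistanceStats", "d_selection_curve"]

DEFAULT_D = 13  # recommended clustering distance for the 313-nt COI fragment


@dataclass(frozen=True, slots=True)
class Motu:
    """A cluster of sequences; the representative is the most abundant
    member (ties broken lexicographically)."""

    representative: UniqueSequence
    members: tuple[UniqueSequence, ...]
    total_reads: int

    def __post_init__(self) -> None:
        assert self.total_reads == sum(m.count for m in self.members)


def _pairwise_distances(
    seqs: Sequence[UniqueSequence], metric: Literal["positional", "levenshtein"]
) -> np.ndarray:
    n = len(seqs)
    if metric == "positional":
        lengths = {len(s.sequence) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("positional metric requires equal-length sequences")
        mat = np.frombuffer("".join(s.sequence for s in seqs).encode(), dtype=np.uint8)
        mat = mat.reshape(n, -1)
        out = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            out[i, i + 1:] = (mat[i + 1:] != mat[i]).sum(axis=1)
        return out + out.T
    if metric == "levenshtein":
        out = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = edlib.align(seqs[i].sequence, seqs[j].sequence)["editDistance"]
        return out + out.T
    raise ValueError(f"unknown metric {metric!r}")


def cluster(
    seqs: Iterable[UniqueSequence],
    d: int = DEFAULT_D,
    metric: Literal["positional", "levenshtein"] = "positional",
) -> list[Motu]:
    """Single-linkage clustering at distance ``d``.

    Sequences whose pairwise distance is <= d are linked; MOTUs are the
    connected components (so chains can join pairs further than d apart).
    Output is ordered by decreasing representative count, ties by
    representative sequence.
    """
    if d < 1:
        raise ValueError("clustering distance d must be >= 1")
    ordered = canonical_sort(seqs)
    check_dereplicated(ordered)
    if not ordered:
        return []
    dist = _pairwise_distances(ordered, metric)
    ii, jj = np.nonzero(dist <= d)
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=dist.shape)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[UniqueSequence]] = {}
    for s, lab in zip(ordered, labels):
        groups.setdefault(int(lab), []).append(s)
    motus = []
    for mem in groups.values():
        mem = canonical_sort(mem)
        motus.append(
            Motu(representative=mem[0], members=tuple(mem), total_reads=sum(m.count for m in mem))
        )
    motus.sort(key=lambda m: (-m.representative.count, m.representative.sequence))
    return motus


@dataclass(frozen=True, slots=True)
class MotuDistanceStats:
    """Pooled within-MOTU distances and between-representative distances.

    ``mean_intra`` is None when no MOTU has two or more members;
    ``mean_inter`` is None with fewer than two MOTUs.  Percent identity of a
    mean distance m on fragment length L is 100 * (L - m) / L.
    """

    mean_intra: float | None
    mean_inter: float | None
    intra_distribution: tuple[float, ...]
    inter_distribution: tuple[float, ...]

    @staticmethod
    def percent_identity(distance: float, length: int) -> float:
        return 100.0 * (length - distance) / length


def motu_distance_stats(
    motus: Sequence[Motu], metric: Literal["positional", "levenshtein"] = "positional"
) -> MotuDistanceStats:
    """Mean intra-MOTU distance (all within-MOTU pairs, pooled over MOTUs
    with >= 2 members) and mean inter-MOTU distance (representatives only)."""
    if not motus:
        raise ValueError("no MOTUs")
    intra: list[float] = []
    for m in motus:
        if len(m.members) < 2:
            continue
        dist = _pairwise_distances(m.members, metric)
        iu = np.triu_indices(len(m.members), k=1)
        intra.extend(dist[iu].tolist())
    reps = [m.representative for m in motus]
    inter: list[float] = []
    if len(reps) >= 2:
        dist = _pairwise_distances(reps, metric)
        iu = np.triu_indices(len(reps), k=1)
        inter = dist[iu].tolist()
    return MotuDistanceStats(
        mean_intra=float(np.mean(intra)) if intra else None,
        mean_inter=float(np.mean(inter)) if inter else None,
        intra_distribution=tuple(sorted(intra)),
        inter_distribution=tuple(sorted(inter)),
    )


def d_selection_curve(
    seqs: Sequence[UniqueSequence],
    d_values: Iterable[int],
    metric: Literal["positional", "levenshtein"] = "positional",
) -> pd.DataFrame:
    """MOTU counts and distance means over a range of clustering distances.

    One row per d: total MOTUs, MOTUs with >= 2 sequences, and the mean
    intra-/inter-MOTU distances.  Total MOTUs is non-increasing in d and the
    mean intra-MOTU distance non-decreasing; the curve is the basis for
    choosing d (a clear gap between intra and inter distributions).
    """
    d_values = sorted(set(int(d) for d in d_values))
    if not d_values:
        raise ValueError("d_values must be non-empty")
    rows = []
    for d in d_values:
        motus = cluster(seqs, d=d, metric=metric)
        stats = motu_distance_stats(motus, metric=metric) if motus else None
        rows.append(
            {
                "d": d,
                "n_motus_total": len(motus),
                "n_motus_ge2seqs": sum(1 for m in motus if len(m.members) >= 2),
                "mean_intra": stats.mean_intra if stats else None,
                "mean_inter": stats.mean_inter if stats else None,
            }
        )
    return pd.DataFrame(rows, columns=["d", "n_motus_total", "n_motus_ge2seqs", "mean_intra", "mean_inter"])
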