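"""Codon-position entropy profiles and the entropy-ratio diagnostic.

In a protein-coding marker the three codon positions differ sharply in how
much variation they tolerate: third positions are largely synonymous and
highly variable, second positions are the most constrained.  Sequencing and
PCR errors, by contrast, fall uniformly across positions.  The Shannon
entropy of the base composition at each codon position therefore separates
biological variation from noise, and the entropy ratio

    Er = entropy(position 2) / entropy(position 3)

drops as denoising removes erroneous sequences — which is the basis of the
parameter-selection curve produced by :func:`er_curve`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import UniqueSequence

__all__ = ["EntropyProfile", "positional_entropy", "entropy_ratio", "er_curve", "codon_position"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def codon_position(column: int, frame_offset: int) -> int:
    """Codon position (1, 2 or 3) of a 1-based alignment column.

    ``frame_offset`` is the codon position of the first column; positions
    cycle from there, including through any trailing partial codon.
    """
    if frame_offset not in (1, 2, 3):
        raise ValueError("frame_offset must be 1, 2 or 3")
    return (frame_offset - 1 + column - 1) % 3 + 1


@dataclass(frozen=True, slots=True)
class EntropyProfile:
    """Mean per-column Shannon entropy at each codon position.

    ``e1``/``e2``/``e3`` are entropies in the chosen log base (natural by
    default, so the maximum is ln 4 ≈ 1.386).  ``frame_offset`` records the
    codon position of the first alignment column; ``weighting`` records
    whether each unique sequence contributed once (``"unique"``) or in
    proportion to its reads (``"read_weighted"``).
    """

    e1: float
    e2: float
    e3: float
    frame_offset: int = 3
    log_base: str = "natural"
    weighting: str = "unique"

    @property
    def total(self) -> float:
        return self.e1 + self.e2 + self.e3

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.e1, self.e2, self.e3)


def _column_entropies(counts: np.ndarray, log_base: str) -> np.ndarray:
    """Shannon entropy of each column given a (4, n_columns) count matrix."""
    totals = counts.sum(axis=0)
    f = np.divide(counts, totals, out=np.zeros(counts.shape, dtype=float), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, -f * np.log(f), 0.0)
    h = terms.sum(axis=0)
    if log_base == "base2":
        h = h / math.log(2)
    elif log_base != "natural":
        raise ValueError("log_base must be 'natural' or 'base2'")
    return h


def positional_entropy(
    seqs: Sequence[UniqueSequence],
    frame_offset: int = 3,
    log_base: str = "natural",
    weighting: str = "unique",
) -> EntropyProfile:
    """Mean column-wise Shannon entropy per codon position.

    For every alignment column, base frequencies are taken across sequences
    and the column's Shannon entropy computed; e_p is the mean over the
    columns whose codon position is p (given ``frame_offset``).  Identical
    sequences therefore give zero entropy at every position, and a column
    equiprobable over the four bases contributes log 4.
    ``weighting="read_weighted"`` weights each sequence's contribution by
    its read count.
    """
    if not seqs:
        raise ValueError("cannot compute entropy of an empty dataset")
    length = len(seqs[0].sequence)
    if length == 0:
        raise ValueError("zero-length sequences")
    if any(len(s.sequence) != length for s in seqs):
        raise ValueError("all sequences must have equal length")
    if weighting not in ("unique", "read_weighted"):
        raise ValueError("weighting must be 'unique' or 'read_weighted'")

    mat = np.frombuffer("".join(s.sequence for s in seqs).encode(), dtype=np.uint8)
    mat = mat.reshape(len(seqs), length)
    weights = (
        np.array([s.count for s in seqs], dtype=np.int64)
        if weighting == "read_weighted"
        else np.ones(len(seqs), dtype=np.int64)
    )
    positions = np.array([codon_position(c, frame_offset) for c in range(1, length + 1)])

    counts = np.stack(
        [(mat == ord(base)).astype(np.int64).T @ weights for base in _BASE_INDEX]
    )  # (4, n_columns)
    col_h = _column_entropies(counts, log_base)
    entropies = {
        p: float(col_h[positions == p].mean()) if (positions == p).any() else 0.0
        for p in (1, 2, 3)
    }
    return EntropyProfile(
        entropies[1], entropies[2], entropies[3],
        frame_offset=frame_offset, log_base=log_base, weighting=weighting,
    )


def entropy_ratio(profile: EntropyProfile) -> float:
    """Er = e2/e3, the diagnostic ratio of the least- to the most-variable
    codon position.  Undefined (raises) when e3 = 0."""
    if profile.e3 == 0:
        raise ValueError("entropy ratio undefined: third-position entropy is zero")
    return profile.e2 / profile.e3


def er_curve(
    seqs: Sequence[UniqueSequence],
    alphas: Iterable[float],
    denoise_params=None,
    frame_offset: int = 3,
    log_base: str = "natural",
    weighting: str = "unique",
) -> pd.DataFrame:
    """Denoise at each stringency α and report ESV count and Er of the
    retained set; rows ordered by decreasing α.  Er is NaN when the retained
    set has no third-position variability.

    The curve is emitted for inspection — the toolkit deliberately does not
    auto-detect a plateau; choosing α is the analyst's call.
    """
    from dataclasses import replace

    from .denoise import DenoiseParams, denoise

    alphas = list(alphas)
    if not alphas:
        raise ValueError("alphas must be non-empty")
    base = denoise_params if denoise_params is not None else DenoiseParams()
    rows = []
    for alpha in sorted(alphas, reverse=True):
        result = denoise(seqs, replace(base, alpha=alpha))
        esv_seqs = [
            UniqueSequence(id=e.centroid.id, sequence=e.centroid.sequence, count=e.total_reads)
            for e in result.esvs
        ]
        profile = positional_entropy(esv_seqs, frame_offset, log_base, weighting)
        er = entropy_ratio(profile) if profile.e3 > 0 else float("nan")
        rows.append({"alpha": alpha, "n_esv": len(esv_seqs), "er": er})
    return pd.DataFrame(rows, columns=["alpha", "n_esv", "er"])
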