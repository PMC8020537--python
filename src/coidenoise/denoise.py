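"""Abundance-skew denoising with optional codon-position entropy correction.

The merge rule is the zero-radius OTU (UNOISE3-style) skew test: a putative
error "daughter" sequence i is merged into a more abundant "mother" j when
their abundance skew (count_i / count_j) does not exceed

    beta(d) = 1 / 2**(alpha * d + 1)

where d is the sequence distance and alpha the stringency parameter.  Two
extensions are provided:

* **entropy correction** — d is replaced by d_corr, a reweighting of the
  per-codon-position difference counts by the positional entropies, so that
  third-position (naturally variable) differences count for more and are
  less readily merged away;
* **two-phase mother selection** — instead of merging into the first
  centroid that satisfies the test (abundance-ordered, skew precedence),
  all eligible mothers are collected first and one is chosen per daughter
  by a configurable criterion (minimum skew, minimum distance, or minimum
  skew/beta(d) ratio).

Merged reads always accrue to a terminal, motherless sequence; the full
daughter-to-mother map is returned so clusters of merged reads can be
audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import edlib
import numpy as np

from .entropy import EntropyProfile, codon_position
from .sequence_io import UniqueSequence, canonical_sort, check_dereplicated

__all__ = [
    "DenoiseParams",
    "MergeCandidate",
    "MergeRecord",
    "Esv",
    "DenoiseResult",
    "beta_threshold",
    "count_positional_differences",
    "corrected_distance",
    "pair_distance",
    "select_mother",
    "denoise",
]


def beta_threshold(alpha: float, d: float) -> float:
    """Maximum abundance skew at which sequences distance ``d`` apart merge.

    Accepts real-valued ``d`` (the entropy-corrected distance is fractional).
    At d=0 the threshold is 0.5, so equal-abundance pairs can never merge.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def count_positional_differences(
    a: str, b: str, frame_offset: int = 3
) -> tuple[int, int, int]:
    """Number of mismatching columns at each codon position.

    Requires equal lengths (aligned, indel-free input); the three counts sum
    to the Hamming distance.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    d = [0, 0, 0]
    for col, (x, y) in enumerate(zip(a, b), start=1):
        if x != y:
            d[codon_position(col, frame_offset) - 1] += 1
    return (d[0], d[1], d[2])


def corrected_distance(d1: int, d2: int, d3: int, profile: EntropyProfile) -> float:
    """Entropy-weighted distance: sum_i d_i * e_i * 3 / (e1 + e2 + e3).

    A difference at each codon position keeps a total of 3; a single
    third-position difference weighs more than a second-position one,
    reflecting that natural variation concentrates at third positions while
    errors do not.
    """
    total = profile.total
    if total <= 0:
        raise ValueError("entropy correction requires e1 + e2 + e3 > 0")
    return (d1 * profile.e1 + d2 * profile.e2 + d3 * profile.e3) * 3.0 / total


@dataclass(frozen=True, slots=True)
class DenoiseParams:
    """Parameters of a denoising run.

    alpha:
        Stringency; lower values merge more aggressively.  5 is the
        recommended value for the COI marker (2 is the ribosomal default).
    mode:
        ``"classic"`` merges each sequence into the first (most abundant)
        centroid passing the skew test; ``"two_phase"`` collects all eligible
        mothers first and picks one per daughter via ``criterion``.
    criterion:
        Mother choice in two-phase mode: ``"skew"`` (minimum abundance skew,
        the classic precedence), ``"distance"`` (minimum d), or ``"ratio"``
        (minimum skew/beta(d), combining both).
    entropy_correction:
        Replace d by the entropy-weighted d_corr; requires ``profile`` and
        the positional metric.
    distance_metric:
        ``"positional"`` (per-codon-position Hamming; equal lengths only) or
        ``"levenshtein"`` (edit distance; allows variable-length input but
        cannot track codon positions).
    """

    alpha: float = 5.0
    mode: Literal["classic", "two_phase"] = "classic"
    criterion: Literal["skew", "distance", "ratio"] = "skew"
    entropy_correction: bool = False
    profile: EntropyProfile | None = None
    distance_metric: Literal["positional", "levenshtein"] = "positional"
    frame_offset: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.entropy_correction:
            if self.distance_metric != "positional":
                raise ValueError(
                    "entropy correction tracks codon positions and requires "
                    "distance_metric='positional'"
                )
            if self.profile is None:
                raise ValueError("entropy correction requires an EntropyProfile")

    @property
    def effective_frame_offset(self) -> int:
        return self.profile.frame_offset if self.profile is not None else self.frame_offset


@dataclass(frozen=True, slots=True)
class MergeCandidate:
    """A potential mother for a daughter sequence, with the quantities the
    three selection criteria rank by."""

    mother_id: str
    d: float
    skew: float
    ratio: float
    mother_count: int = 0
    mother_sequence: str = ""


@dataclass(frozen=True, slots=True)
class MergeRecord:
    daughter_id: str
    mother_id: str
    d: float
    skew: float
    criterion_value: float


@dataclass(frozen=True, slots=True)
class Esv:
    """A retained sequence with the reads it accumulated from merged
    daughters.  ``members`` lists the merged daughter ids (transitively)."""

    centroid: UniqueSequence
    total_reads: int
    members: tuple[str, ...] = ()


@dataclass(frozen=True, slots=True)
class DenoiseResult:
    esvs: tuple[Esv, ...]
    merge_map: tuple[MergeRecord, ...]

    @property
    def total_reads(self) -> int:
        return sum(e.total_reads for e in self.esvs)

    def esv_sequences(self) -> list[UniqueSequence]:
        """The retained ESVs as a dataset (counts = accumulated reads)."""
        return [
            UniqueSequence(id=e.centroid.id, sequence=e.centroid.sequence, count=e.total_reads)
            for e in self.esvs
        ]


def pair_distance(a: str, b: str, params: DenoiseParams) -> float:
    """Distance between two sequences under the configured metric."""
    if params.distance_metric == "levenshtein":
        return float(edlib.align(a, b)["editDistance"])
    d1, d2, d3 = count_positional_differences(a, b, params.effective_frame_offset)
    if params.entropy_correction:
        return corrected_distance(d1, d2, d3, params.profile)
    return float(d1 + d2 + d3)


def select_mother(
    candidates: Sequence[MergeCandidate],
    criterion: Literal["skew", "distance", "ratio"] = "skew",
) -> MergeCandidate:
    """Pick one mother per daughter.

    Ranks by minimum skew, minimum distance, or minimum skew/beta(d) ratio;
    ties broken deterministically by larger mother abundance, then
    lexicographic mother sequence.
    """
    if not candidates:
        raise ValueError("no merge candidates")
    if criterion == "skew":
        key = lambda c: (c.skew, -c.mother_count, c.mother_sequence)
    elif criterion == "distance":
        key = lambda c: (c.d, -c.mother_count, c.mother_sequence)
    elif criterion == "ratio":
        key = lambda c: (c.ratio, -c.mother_count, c.mother_sequence)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return min(candidates, key=key)


def _encode(seqs: Sequence[UniqueSequence]) -> np.ndarray:
    return np.frombuffer(
        "".join(s.sequence for s in seqs).encode(), dtype=np.uint8
    ).reshape(len(seqs), -1)


def _positional_diffs_vs(
    mat: np.ndarray, i: int, js: np.ndarray, pos_masks: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """d1, d2, d3 between row i and each row in js (vectorised)."""
    neq = mat[js] != mat[i]
    return tuple(neq[:, m].sum(axis=1) for m in pos_masks)  # type: ignore[return-value]


def _distances_vs(
    seqs: Sequence[UniqueSequence],
    mat: np.ndarray | None,
    i: int,
    js: list[int],
    params: DenoiseParams,
    pos_masks,
) -> np.ndarray:
    if params.distance_metric == "levenshtein":
        return np.array(
            [edlib.align(seqs[i].sequence, seqs[j].sequence)["editDistance"] for j in js],
            dtype=float,
        )
    d1, d2, d3 = _positional_diffs_vs(mat, i, np.array(js, dtype=np.intp), pos_masks)
    if params.entropy_correction:
        p = params.profile
        return (d1 * p.e1 + d2 * p.e2 + d3 * p.e3) * 3.0 / p.total
    return (d1 + d2 + d3).astype(float)


def _min_possible_distance(params: DenoiseParams) -> float:
    """Smallest distance two distinct dereplicated sequences can have.

    Used to prune mothers that are not abundant enough to capture a given
    daughter at any distance; the pruning is a pure optimisation and cannot
    change the result (checked against the naive reference in tests).
    """
    if not params.entropy_correction:
        return 1.0
    p = params.profile
    return 3.0 * min(p.e1, p.e2, p.e3) / p.total


def _prepare(seqs: Sequence[UniqueSequence], params: DenoiseParams):
    ordered = canonical_sort(seqs)
    check_dereplicated(ordered)
    mat = None
    pos_masks = None
    if params.distance_metric == "positional" and ordered:
        lengths = {len(s.sequence) for s in ordered}
        if len(lengths) > 1:
            raise ValueError("positional metric requires equal-length sequences")
        mat = _encode(ordered)
        fo = params.effective_frame_offset
        positions = np.array([codon_position(c, fo) for c in range(1, mat.shape[1] + 1)])
        pos_masks = tuple(positions == p for p in (1, 2, 3))
    return ordered, mat, pos_masks


def denoise(seqs: Sequence[UniqueSequence], params: DenoiseParams | None = None) -> DenoiseResult:
    """Merge putative error sequences into mother ESVs.

    Input must be dereplicated; output ESVs are in canonical order and the
    total reads of the result equal the total reads of the input.
    """
    params = params or DenoiseParams()
    ordered, mat, pos_masks = _prepare(seqs, params)
    if not ordered:
        return DenoiseResult(esvs=(), merge_map=())
    if params.mode == "classic":
        return _denoise_classic(ordered, mat, pos_masks, params)
    if params.mode == "two_phase":
        return _denoise_two_phase(ordered, mat, pos_masks, params)
    raise ValueError(f"unknown mode {params.mode!r}")


def _denoise_classic(ordered, mat, pos_masks, params: DenoiseParams) -> DenoiseResult:
    # Sequences in decreasing abundance; each is tested against existing
    # centroids (also in decreasing abundance) and joins the FIRST one whose
    # skew test passes — skew precedence by construction.
    centroid_idx: list[int] = []
    totals: dict[int, int] = {}
    members: dict[int, list[str]] = {}
    merge_map: list[MergeRecord] = []
    beta_floor = beta_threshold(params.alpha, _min_possible_distance(params))
    for i, s in enumerate(ordered):
        merged = False
        eligible = [
            c for c in centroid_idx
            if ordered[c].count > s.count
            and ordered[c].count * beta_floor >= s.count * (1.0 - 1e-9)
        ]
        if eligible:
            dists = _distances_vs(ordered, mat, i, eligible, params, pos_masks)
            for c, d in zip(eligible, dists):
                skew = s.count / ordered[c].count
                if skew <= beta_threshold(params.alpha, float(d)):
                    totals[c] += s.count
                    members[c].append(s.id)
                    merge_map.append(MergeRecord(s.id, ordered[c].id, float(d), skew, skew))
                    merged = True
                    break
        if not merged:
            centroid_idx.append(i)
            totals[i] = s.count
            members[i] = []
    esvs = [
        Esv(centroid=ordered[c], total_reads=totals[c], members=tuple(members[c]))
        for c in centroid_idx
    ]
    return _finish(esvs, merge_map)


def _denoise_two_phase(ordered, mat, pos_masks, params: DenoiseParams) -> DenoiseResult:
    n = len(ordered)
    counts = np.array([s.count for s in ordered], dtype=np.int64)
    parent: dict[int, tuple[int, MergeCandidate]] = {}
    # Phase 1: every strictly-more-abundant sequence passing the skew test is
    # a potential mother.  Phase 2: one mother per daughter, by criterion.
    beta_floor = beta_threshold(params.alpha, _min_possible_distance(params))
    for i in range(n):
        js = [
            j for j in range(i)
            if counts[j] > counts[i]
            and counts[j] * beta_floor >= counts[i] * (1.0 - 1e-9)
        ]
        if not js:
            continue
        dists = _distances_vs(ordered, mat, i, js, params, pos_masks)
        cands: list[MergeCandidate] = []
        for j, d in zip(js, dists):
            skew = counts[i] / counts[j]
            beta = beta_threshold(params.alpha, float(d))
            if skew <= beta:
                cands.append(
                    MergeCandidate(
                        mother_id=ordered[j].id,
                        d=float(d),
                        skew=skew,
                        ratio=skew / beta,
                        mother_count=int(counts[j]),
                        mother_sequence=ordered[j].sequence,
                    )
                )
        if cands:
            chosen = select_mother(cands, params.criterion)
            j = next(
                k for k in js if ordered[k].id == chosen.mother_id
            )
            parent[i] = (j, chosen)

    # Chain resolution: reads flow transitively to the terminal motherless
    # sequence.  Parents are strictly more abundant, so chains cannot cycle.
    def terminal(i: int) -> int:
        while i in parent:
            i = parent[i][0]
        return i

    totals: dict[int, int] = {}
    members: dict[int, list[str]] = {}
    merge_map: list[MergeRecord] = []
    for i in range(n):
        t = terminal(i)
        if i not in parent:
            totals[i] = totals.get(i, 0) + ordered[i].count
            members.setdefault(i, [])
        else:
            j, cand = parent[i]
            crit_value = {"skew": cand.skew, "distance": cand.d, "ratio": cand.ratio}[
                params.criterion
            ]
            merge_map.append(MergeRecord(ordered[i].id, cand.mother_id, cand.d, cand.skew, crit_value))
            totals[t] = totals.get(t, 0) + ordered[i].count
            members.setdefault(t, []).append(ordered[i].id)
    esvs = [
        Esv(centroid=ordered[i], total_reads=totals[i], members=tuple(members[i]))
        for i in sorted(totals)
        if i not in parent
    ]
    return _finish(esvs, merge_map)


def _finish(esvs: list[Esv], merge_map: list[MergeRecord]) -> DenoiseResult:
    esvs.sort(key=lambda e: (-e.centroid.count, e.centroid.sequence))
    return DenoiseResult(esvs=tuple(esvs), merge_map=tuple(merge_map))
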