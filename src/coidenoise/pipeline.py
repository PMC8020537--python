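"""Composition of denoising and clustering, in either order, with dataset
summaries.

The two steps answer different questions — denoising recovers correct
sequences (ESVs), clustering recovers species-level entities (MOTUs) — and
can be run denoise-then-cluster or cluster-then-denoise.  In the latter
order denoising runs independently *within* each MOTU; any entropy profile
used for distance correction should be computed on the whole dataset
beforehand, since single MOTUs rarely contain enough sequences for a stable
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

from .cluster import DEFAULT_D, Motu, cluster
from .denoise import DenoiseParams, DenoiseResult, denoise
from .sequence_io import UniqueSequence, canonical_sort

__all__ = ["PipelineResult", "Summary", "run_pipeline", "summarize"]

Order = Literal["denoise_then_cluster", "cluster_then_denoise", "denoise_only", "cluster_only"]


def _round3(x: float) -> float:
    """Half-up rounding to 3 decimals, as in printed summary tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class Summary:
    """Headline statistics of an ESV- or MOTU-structured dataset.

    MOTU-level fields are None for a dataset that was only denoised.
    Ratio columns are rounded to 3 decimals (half-up).
    """

    n_esvs: int
    total_reads: int
    n_motus: int | None = None
    n_single_esv_motus: int | None = None
    esvs_per_motu: float | None = None
    reads_per_motu: float | None = None


@dataclass(frozen=True, slots=True)
class PipelineResult:
    order: Order
    summary: Summary
    motus: tuple[Motu, ...] | None = None
    denoise_result: DenoiseResult | None = None
    stage_log: tuple[str, ...] = ()


def summarize(dataset: Sequence[Motu] | Sequence[UniqueSequence] | DenoiseResult) -> Summary:
    """Summarise a dataset: ESV and MOTU counts, single-ESV MOTUs, and the
    ESVs-per-MOTU and reads-per-MOTU ratios."""
    if isinstance(dataset, DenoiseResult):
        seqs = dataset.esv_sequences()
        return Summary(n_esvs=len(seqs), total_reads=sum(s.count for s in seqs))
    dataset = list(dataset)
    if not dataset:
        return Summary(n_esvs=0, total_reads=0)
    if isinstance(dataset[0], Motu):
        n_motus = len(dataset)
        n_esvs = sum(len(m.members) for m in dataset)
        total = sum(m.total_reads for m in dataset)
        return Summary(
            n_esvs=n_esvs,
            total_reads=total,
            n_motus=n_motus,
            n_single_esv_motus=sum(1 for m in dataset if len(m.members) == 1),
            esvs_per_motu=_round3(n_esvs / n_motus),
            reads_per_motu=_round3(total / n_motus),
        )
    return Summary(n_esvs=len(dataset), total_reads=sum(s.count for s in dataset))


def run_pipeline(
    seqs: Sequence[UniqueSequence],
    order: Order = "denoise_then_cluster",
    denoise_params: DenoiseParams | None = None,
    d: int = DEFAULT_D,
    metric: Literal["positional", "levenshtein"] = "positional",
) -> PipelineResult:
    """Run the chosen composition of denoising and clustering.

    Read totals are conserved through every stage and order.
    """
    params = denoise_params or DenoiseParams()
    log: list[str] = [f"input: {len(seqs)} unique sequences, {sum(s.count for s in seqs)} reads"]

    if order == "denoise_only":
        result = denoise(seqs, params)
        log.append(f"denoise(alpha={params.alpha}, mode={params.mode}): {len(result.esvs)} ESVs")
        return PipelineResult(order, summarize(result), denoise_result=result, stage_log=tuple(log))

    if order == "cluster_only":
        motus = cluster(seqs, d=d, metric=metric)
        log.append(f"cluster(d={d}): {len(motus)} MOTUs")
        return PipelineResult(order, summarize(motus), motus=tuple(motus), stage_log=tuple(log))

    if order == "denoise_then_cluster":
        result = denoise(seqs, params)
        log.append(f"denoise(alpha={params.alpha}, mode={params.mode}): {len(result.esvs)} ESVs")
        motus = cluster(result.esv_sequences(), d=d, metric=metric)
        log.append(f"cluster(d={d}): {len(motus)} MOTUs")
        return PipelineResult(
            order, summarize(motus), motus=tuple(motus), denoise_result=result, stage_log=tuple(log)
        )

    if order == "cluster_then_denoise":
        raw_motus = cluster(seqs, d=d, metric=metric)
        log.append(f"cluster(d={d}): {len(raw_motus)} MOTUs")
        # Denoising is run independently within each MOTU; the entropy
        # profile inside `params` (if any) stays fixed across MOTUs.
        new_motus: list[Motu] = []
        n_esvs = 0
        for m in raw_motus:
            result = denoise(m.members, params)
            esvs = canonical_sort(result.esv_sequences())
            n_esvs += len(esvs)
            new_motus.append(
                Motu(representative=esvs[0], members=tuple(esvs), total_reads=sum(e.count for e in esvs))
            )
        new_motus.sort(key=lambda m: (-m.representative.count, m.representative.sequence))
        log.append(f"denoise within MOTUs(alpha={params.alpha}): {n_esvs} ESVs")
        return PipelineResult(order, summarize(new_motus), motus=tuple(new_motus), stage_log=tuple(log))

    raise ValueError(f"unknown order {order!r}")
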