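"""Synthetic COI-like amplicon communities with known ground truth.

The generator emulates the structure of a dereplicated metabarcoding
dataset from a protein-coding marker:

* multiple species, each with a divergent centroid haplotype (rejection-
  sampled to a minimum pairwise distance);
* intra-species haplotypes derived from the centroid by substitutions
  placed preferentially at third codon positions (where natural variation
  concentrates);
* skewed (lognormal) species abundances, a dominant haplotype per species;
* uniform per-base substitution errors applied independently to every read
  — the signature that distinguishes noise from biological variation;
* dereplication of the resulting reads.

All haplotypes are generated coding-plausible: no codon that is a stop
under any of the configured metazoan genetic codes, and fixed residues at
five conserved amino-acid positions.  Sequencing errors are unconstrained,
so error sequences can (and do) break these rules — which is what the
erroneous-ESV benchmark detects.

A single seeded generator drives all randomness, in a fixed stream order
(centroids → haplotypes → abundances → per-haplotype error reads), so a
seed fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .benchmark import DEFAULT_GENETIC_CODES, ErrorCheckConfig, translate_fragment
from .cluster import Motu
from .denoise import DenoiseResult, beta_threshold
from .entropy import codon_position
from .sequence_io import UniqueSequence, canonical_sort

__all__ = ["SimulationParams", "SyntheticTruth", "RecoveryScore", "simulate", "score_recovery"]

BASES = "ACGT"

# Codons that are a stop under at least one of the default genetic codes
# (TAA/TAG everywhere, TGA in the standard code, AGA/AGG in the vertebrate
# mitochondrial code).  Haplotypes avoid all of them so that every default
# code translates them without stops.
FORBIDDEN_CODONS = frozenset({"TAA", "TAG", "TGA", "AGA", "AGG"})

# Base composition per codon position used to draw centroid sequences;
# biased as in real COI (second positions strongly constrained, third
# positions closest to even).  Order A, C, G, T.
POSITION_COMPOSITION = {
    1: np.array([0.15, 0.10, 0.05, 0.70]),
    2: np.array([0.02, 0.04, 0.01, 0.93]),
    3: np.array([0.45, 0.15, 0.10, 0.30]),
}

# Conserved amino acids: canonical codons translating identically under all
# default genetic codes. 1-based codon indices within the translated frame.
CONSERVED_RESIDUES: tuple[tuple[int, str, str], ...] = (
    (20, "G", "GGA"),
    (40, "L", "CTT"),
    (60, "P", "CCA"),
    (80, "W", "TGG"),
    (100, "F", "TTT"),
)


@dataclass(frozen=True, slots=True)
class SimulationParams:
    """Community and noise model parameters.

    ``haplotypes_per_species`` and ``intra_species_substitutions`` are means
    of shifted-Poisson draws (minimum 1).  ``species_abundance`` gives the
    (mu, sigma) of the lognormal relative species abundances;
    ``within_species_skew`` is the read fraction of the dominant haplotype.
    ``codon_position_weights`` place intra-species substitutions — the
    default favours third positions, a modelling choice mirroring
    synonymous variation.  ``error_rate`` is the per-base substitution
    probability, uniform across positions.  With ``denoise_safe`` haplotype
    abundances are compressed so that no true-haplotype pair passes the
    skew merge test at ``alpha_ref``.
    """

    n_species: int = 50
    fragment_length: int = 313
    frame_offset: int = 3
    inter_species_divergence: int = 30
    haplotypes_per_species: float = 5.0
    intra_species_substitutions: float = 2.0
    codon_position_weights: tuple[float, float, float] = (0.15, 0.10, 0.75)
    species_abundance: tuple[float, float] = (0.0, 1.0)
    within_species_skew: float = 0.6
    error_rate: float = 0.0
    n_reads: int = 40_000
    seed: int = 0
    denoise_safe: bool = False
    alpha_ref: float = 5.0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.codon_position_weights), 1.0):
            raise ValueError("codon_position_weights must sum to 1")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be a probability")
        if not (0.0 < self.within_species_skew <= 1.0):
            raise ValueError("within_species_skew must be in (0, 1]")
        if self.fragment_length < 9:
            raise ValueError("fragment_length too short")


@dataclass(frozen=True, slots=True)
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset.

    ``haplotypes`` has columns (species_id, haplotype_id, sequence,
    true_count); ``provenance`` maps every observed unique sequence to its
    source haplotype and whether it carries at least one injected error.
    An error read that happens to reproduce another true haplotype is
    credited to that haplotype (is_error=False for the observed sequence).
    """

    haplotypes: pd.DataFrame
    provenance: pd.DataFrame
    conserved_config: ErrorCheckConfig
    total_reads: int


@dataclass(frozen=True, slots=True)
class RecoveryScore:
    recall: float
    precision: float | None
    motu_recall: float | None = None


def _draw_codon(rng: np.random.Generator, positions: tuple[int, int, int]) -> str:
    while True:
        codon = "".join(
            BASES[rng.choice(4, p=POSITION_COMPOSITION[p])] for p in positions
        )
        if codon not in FORBIDDEN_CODONS:
            return codon


def _draw_centroid(rng: np.random.Generator, params: SimulationParams) -> str:
    L, fo = params.fragment_length, params.frame_offset
    lead = (1 - fo) % 3
    n_codons = (L - lead) // 3
    trail = L - lead - 3 * n_codons
    conserved = {idx: codon for idx, _aa, codon in CONSERVED_RESIDUES if idx <= n_codons}
    parts = [
        BASES[rng.choice(4, p=POSITION_COMPOSITION[codon_position(c + 1, fo)])]
        for c in range(lead)
    ]
    for ci in range(1, n_codons + 1):
        parts.append(conserved.get(ci, None) or _draw_codon(rng, (1, 2, 3)))
    for c in range(trail):
        col = lead + 3 * n_codons + c + 1
        parts.append(BASES[rng.choice(4, p=POSITION_COMPOSITION[codon_position(col, fo)])])
    return "".join(parts)


def _is_valid_haplotype(seq: str, params: SimulationParams) -> bool:
    """No forbidden codon anywhere; conserved residues intact."""
    fo = params.frame_offset
    lead = (1 - fo) % 3
    n_codons = (len(seq) - lead) // 3
    for ci in range(n_codons):
        if seq[lead + 3 * ci : lead + 3 * ci + 3] in FORBIDDEN_CODONS:
            return False
    prot = translate_fragment(seq, 5, fo)
    for idx, aa, _codon in CONSERVED_RESIDUES:
        if idx <= len(prot) and prot[idx - 1] != aa:
            return False
    return True


def _mutate(
    rng: np.random.Generator, seq: str, n_subs: int, params: SimulationParams
) -> str:
    """Apply coding-plausible substitutions placed by codon-position weight."""
    fo = params.frame_offset
    cols_by_pos = {
        p: [c for c in range(len(seq)) if codon_position(c + 1, fo) == p] for p in (1, 2, 3)
    }
    out = list(seq)
    done = 0
    attempts = 0
    while done < n_subs:
        attempts += 1
        if attempts > 200 * max(1, n_subs):
            raise RuntimeError("could not place substitutions under coding constraints")
        p = 1 + rng.choice(3, p=np.asarray(params.codon_position_weights))
        col = cols_by_pos[p][rng.integers(len(cols_by_pos[p]))]
        old = out[col]
        comp = POSITION_COMPOSITION[p].copy()
        comp[BASES.index(old)] = 0.0
        new = BASES[rng.choice(4, p=comp / comp.sum())]
        out[col] = new
        if _is_valid_haplotype("".join(out), params):
            done += 1
        else:
            out[col] = old
    return "".join(out)


def _shifted_poisson(rng: np.random.Generator, mean: float) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def _min_pairwise_distance(haplotypes: list[str]) -> int:
    """Smallest pairwise Hamming distance among the true haplotypes."""
    mat = np.frombuffer("".join(haplotypes).encode(), dtype=np.uint8).reshape(
        len(haplotypes), -1
    )
    best = mat.shape[1]
    for i in range(len(haplotypes) - 1):
        best = min(best, int((mat[i + 1:] != mat[i]).sum(axis=1).min()))
    return best


def _apply_denoise_safe(
    counts: np.ndarray, haplotypes: list[str], params: SimulationParams
) -> np.ndarray:
    """Compress abundances so every true-haplotype pair fails the skew test.

    Requires min/max count > beta(alpha_ref, d_min) where d_min is the
    smallest pairwise haplotype distance; a power transform preserves the
    abundance ordering while bounding the ratio.
    """
    d_min = _min_pairwise_distance(haplotypes)
    beta = beta_threshold(params.alpha_ref, d_min)
    counts = np.maximum(counts, 1).astype(float)
    max_ratio = 0.9 / beta
    ratio = counts.max() / counts.min()
    if ratio > max_ratio:
        gamma = math.log(max_ratio) / math.log(ratio)
        counts = counts ** gamma
    counts = np.ceil(counts).astype(np.int64)
    assert counts.min() / counts.max() > beta, "denoise-safe floor violated"
    return counts


def simulate(params: SimulationParams) -> tuple[list[UniqueSequence], SyntheticTruth]:
    """Generate a dereplicated dataset and its ground truth."""
    rng = np.random.default_rng(params.seed)

    # Species centroids, rejection-sampled to the divergence floor.
    centroids: list[str] = []
    attempts = 0
    while len(centroids) < params.n_species:
        attempts += 1
        if attempts > 50 * params.n_species:
            raise RuntimeError(
                "cannot place species centroids at the requested divergence; "
                "lower inter_species_divergence or n_species"
            )
        cand = _draw_centroid(rng, params)
        if all(
            sum(a != b for a, b in zip(cand, c)) >= params.inter_species_divergence
            for c in centroids
        ):
            centroids.append(cand)

    # Haplotypes per species: the centroid plus mutated derivatives, all
    # globally unique.
    hap_rows: list[tuple[int, str, str]] = []  # species, hap_id, sequence
    seen: set[str] = set()
    for sp, centroid in enumerate(centroids):
        n_h = _shifted_poisson(rng, params.haplotypes_per_species)
        haps = [centroid]
        seen.add(centroid)
        guard = 0
        while len(haps) < n_h and guard < 100 * n_h:
            guard += 1
            k = _shifted_poisson(rng, params.intra_species_substitutions)
            h = _mutate(rng, centroid, k, params)
            if h not in seen:
                haps.append(h)
                seen.add(h)
        for hi, h in enumerate(haps):
            hap_rows.append((sp, f"s{sp}h{hi}", h))

    # Abundances: lognormal species weights, dominant-haplotype skew within.
    mu, sigma = params.species_abundance
    sp_weights = rng.lognormal(mu, sigma, size=params.n_species)
    sp_weights /= sp_weights.sum()
    weights = np.empty(len(hap_rows))
    by_species: dict[int, list[int]] = {}
    for idx, (sp, _hid, _h) in enumerate(hap_rows):
        by_species.setdefault(sp, []).append(idx)
    for sp, idxs in by_species.items():
        if len(idxs) == 1:
            weights[idxs[0]] = sp_weights[sp]
            continue
        # Heavy-tailed minor-haplotype frequencies: natural haplotype
        # frequency spectra have few common and many rare variants.
        rest = rng.lognormal(0.0, 1.5, size=len(idxs) - 1)
        rest = rest / rest.sum() * (1.0 - params.within_species_skew)
        weights[idxs[0]] = sp_weights[sp] * params.within_species_skew
        for k, idx in enumerate(idxs[1:]):
            weights[idx] = sp_weights[sp] * rest[k]
    counts = rng.multinomial(params.n_reads, weights / weights.sum())

    if params.denoise_safe:
        counts = _apply_denoise_safe(counts, [h for _s, _i, h in hap_rows], params)

    # Per-read uniform error injection, then dereplication.
    L = params.fragment_length
    observed: dict[str, int] = {}
    provenance: dict[str, tuple[str, bool]] = {}
    hap_seqs = {h for _s, _i, h in hap_rows}
    for (sp, hid, hap), c in zip(hap_rows, counts):
        if c == 0:
            continue
        if params.error_rate > 0:
            n_err_bases = rng.binomial(L, params.error_rate, size=int(c))
        else:
            n_err_bases = np.zeros(int(c), dtype=np.int64)
        n_clean = int((n_err_bases == 0).sum())
        if n_clean:
            observed[hap] = observed.get(hap, 0) + n_clean
            provenance.setdefault(hap, (hid, False))
        for k in n_err_bases[n_err_bases > 0]:
            cols = rng.choice(L, size=int(k), replace=False)
            read = list(hap)
            for col in cols:
                alternatives = [b for b in BASES if b != read[col]]
                read[col] = alternatives[rng.integers(3)]
            read_s = "".join(read)
            observed[read_s] = observed.get(read_s, 0) + 1
            # A read mutated into another true haplotype counts for that
            # haplotype, not as an error sequence.
            if read_s not in provenance:
                provenance[read_s] = (hid, read_s not in hap_seqs)

    ordered = canonical_sort(
        UniqueSequence(id="", sequence=s, count=c) for s, c in observed.items()
    )
    width = len(str(len(ordered)))
    dataset = [
        UniqueSequence(id=f"u{i:0{width}d}", sequence=s.sequence, count=s.count)
        for i, s in enumerate(ordered, start=1)
    ]

    hap_df = pd.DataFrame(
        {
            "species_id": [sp for sp, _h, _s in hap_rows],
            "haplotype_id": [hid for _sp, hid, _s in hap_rows],
            "sequence": [s for _sp, _h, s in hap_rows],
            "true_count": counts,
        }
    )
    prov_df = pd.DataFrame(
        {
            "observed_id": [s.id for s in dataset],
            "sequence": [s.sequence for s in dataset],
            "count": [s.count for s in dataset],
            "source_haplotype": [provenance[s.sequence][0] for s in dataset],
            "is_error": [provenance[s.sequence][1] for s in dataset],
        }
    )
    n_codons = (L - (1 - params.frame_offset) % 3) // 3
    config = ErrorCheckConfig(
        conserved_positions=tuple(
            (idx, frozenset({aa})) for idx, aa, _c in CONSERVED_RESIDUES if idx <= n_codons
        ),
        genetic_codes=DEFAULT_GENETIC_CODES,
        frame_offset=params.frame_offset,
    )
    truth = SyntheticTruth(
        haplotypes=hap_df,
        provenance=prov_df,
        conserved_config=config,
        total_reads=int(sum(observed.values())),
    )
    return dataset, truth


def score_recovery(
    result: DenoiseResult | Sequence[Motu], truth: SyntheticTruth
) -> RecoveryScore:
    """Score haplotype recovery of a denoise result, or species-level MOTU
    recovery of a clustering.

    Recall is the fraction of true haplotypes (with at least one read)
    recovered verbatim; precision the fraction of ESVs that are true
    haplotypes (None for an empty result).  MOTU recall is the fraction of
    species whose observed haplotypes all fall in a single MOTU containing
    no other species' haplotypes.
    """
    present = truth.haplotypes[truth.haplotypes["true_count"] >= 1]
    true_seqs = set(present["sequence"])
    seq_to_species = dict(zip(present["sequence"], present["species_id"]))

    if isinstance(result, DenoiseResult):
        esv_seqs = {e.centroid.sequence for e in result.esvs}
        motu_recall = None
    else:
        esv_seqs = {m.sequence for motu in result for m in motu.members}
        hits: dict[int, list[set[int]]] = {}
        species_motus: dict[int, set[int]] = {}
        contaminated: set[int] = set()
        for mi, motu in enumerate(result):
            species_here = {
                seq_to_species[m.sequence] for m in motu.members if m.sequence in seq_to_species
            }
            for sp in species_here:
                species_motus.setdefault(sp, set()).add(mi)
            if len(species_here) > 1:
                contaminated.update(species_here)
        observed_species = {
            seq_to_species[s] for s in true_seqs if s in esv_seqs
        }
        recovered = sum(
            1
            for sp in observed_species
            if len(species_motus.get(sp, ())) == 1 and sp not in contaminated
        )
        motu_recall = recovered / len(observed_species) if observed_species else None

    recall = (
        sum(1 for s in true_seqs if s in esv_seqs) / len(true_seqs) if true_seqs else 0.0
    )
    precision = (
        sum(1 for s in esv_seqs if s in true_seqs) / len(esv_seqs) if esv_seqs else None
    )
    return RecoveryScore(recall=recall, precision=precision, motu_recall=motu_recall)
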