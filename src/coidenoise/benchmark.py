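"""Dataset comparison and quality benchmarks.

Two complementary benchmark families:

* **comparison** — the symmetric match index and shared-unit reports used to
  contrast the ESV/MOTU sets produced by different denoising or clustering
  choices;
* **quality** — flagging putatively erroneous ESVs by coding-plausibility
  (internal stop codons and mismatches at amino-acid positions conserved
  across metazoans), and classifying MOTUs against an external species
  assignment table as closed / open / hybrid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd
from Bio.Seq import Seq

from .cluster import Motu
from .sequence_io import UniqueSequence

__all__ = [
    "ErrorCheckConfig",
    "ComparisonReport",
    "ErrorSummary",
    "match_index",
    "compare_datasets",
    "translate_fragment",
    "detect_erroneous_esvs",
    "classify_motus",
]

# Standard plus the metazoan mitochondrial translation tables (NCBI ids):
# vertebrate, mold/protozoan, invertebrate, echinoderm/flatworm, ascidian
# and alternative flatworm mitochondrial codes.
DEFAULT_GENETIC_CODES: tuple[int, ...] = (1, 2, 4, 5, 9, 13, 14)


@dataclass(frozen=True, slots=True)
class ErrorCheckConfig:
    """Configuration of the erroneous-ESV check.

    ``conserved_positions`` maps 1-based amino-acid indices (within the
    translated fragment, leading partial codon excluded) to the set of
    residues allowed there.  The positions are marker- and taxon-specific
    and must be supplied by the caller.
    """

    conserved_positions: tuple[tuple[int, frozenset[str]], ...]
    genetic_codes: tuple[int, ...] = DEFAULT_GENETIC_CODES
    frame_offset: int = 3

    def __post_init__(self) -> None:
        if not self.genetic_codes:
            raise ValueError("at least one genetic code is required")
        if self.frame_offset not in (1, 2, 3):
            raise ValueError("frame_offset must be 1, 2 or 3")
        for pos, residues in self.conserved_positions:
            if pos < 1:
                raise ValueError(f"conserved position {pos} must be >= 1")
            if not residues:
                raise ValueError(f"conserved position {pos}: empty residue set")


def match_index(
    set_a: Iterable, set_b: Iterable, key: Callable | None = None
) -> float:
    """Symmetric average shared fraction: (N_match_A/N_A + N_match_B/N_B)/2.

    ``key`` maps items to the identity under which matching is counted
    (e.g. the exact sequence for ESVs, the representative sequence for
    MOTUs).  Undefined (raises) when either side is empty.
    """
    key = key or (lambda x: x)
    a = [key(x) for x in set_a]
    b = [key(x) for x in set_b]
    if not a or not b:
        raise ValueError("match index undefined for an empty dataset")
    sb, sa = set(b), set(a)
    return (sum(1 for x in a if x in sb) / len(a) + sum(1 for x in b if x in sa) / len(b)) / 2


@dataclass(frozen=True, slots=True)
class ComparisonReport:
    level: str
    n_a: int
    n_b: int
    n_shared: int
    reads_a: int
    reads_b: int
    reads_shared_a: int
    reads_shared_b: int
    n_shared_identical_reads: int
    match_index_units: float
    match_index_reads: float


def _as_unit_counts(ds, level: str) -> dict[str, int]:
    """Map each unit's identity key to its read total."""
    out: dict[str, int] = {}
    for item in ds:
        if level == "motu":
            if not isinstance(item, Motu):
                raise TypeError("motu-level comparison requires Motu objects")
            out[item.representative.sequence] = item.total_reads
        else:
            if isinstance(item, UniqueSequence):
                out[item.sequence] = item.count
            else:  # Esv
                out[item.centroid.sequence] = item.total_reads
    return out


def compare_datasets(ds_a, ds_b, level: Literal["esv", "motu"] = "esv") -> ComparisonReport:
    """Shared/unshared units and reads between two datasets.

    ESVs are matched by exact sequence, MOTUs by exact representative
    sequence.  Also counts shared units carrying identical read totals — an
    indication that the same reads were merged on both sides.
    """
    a = _as_unit_counts(ds_a, level)
    b = _as_unit_counts(ds_b, level)
    if not a or not b:
        raise ValueError("comparison undefined for an empty dataset")
    shared = set(a) & set(b)
    reads_a, reads_b = sum(a.values()), sum(b.values())
    reads_shared_a = sum(a[k] for k in shared)
    reads_shared_b = sum(b[k] for k in shared)
    return ComparisonReport(
        level=level,
        n_a=len(a),
        n_b=len(b),
        n_shared=len(shared),
        reads_a=reads_a,
        reads_b=reads_b,
        reads_shared_a=reads_shared_a,
        reads_shared_b=reads_shared_b,
        n_shared_identical_reads=sum(1 for k in shared if a[k] == b[k]),
        match_index_units=(len(shared) / len(a) + len(shared) / len(b)) / 2,
        match_index_reads=(reads_shared_a / reads_a + reads_shared_b / reads_b) / 2,
    )


def translate_fragment(sequence: str, code: int, frame_offset: int) -> str:
    """Translate an aligned fragment under an NCBI translation table.

    ``frame_offset`` is the codon position of the first nucleotide; leading
    bases of a partial codon and any trailing partial codon are ignored.
    """
    lead = (1 - frame_offset) % 3
    coding = sequence[lead:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(table=code))


@dataclass(frozen=True, slots=True)
class ErrorSummary:
    n_esvs: int
    n_erroneous: int

    @property
    def fraction(self) -> float:
        return self.n_erroneous / self.n_esvs if self.n_esvs else 0.0


def detect_erroneous_esvs(
    motus: Sequence[Motu], config: ErrorCheckConfig
) -> tuple[pd.DataFrame, ErrorSummary]:
    """Flag ESVs showing stop codons or conserved-residue mismatches.

    Per MOTU, every member is translated under each configured genetic code
    and the code(s) yielding the fewest internal stops over the whole MOTU
    are selected (a conservative choice: the taxon's true code is unknown).
    An ESV is flagged erroneous only if under *every* selected code it shows
    at least one stop codon or at least one mismatch at a conserved
    position.
    """
    rows = []
    n_err = 0
    for mi, motu in enumerate(motus):
        translations: dict[int, list[str]] = {}
        stop_totals: dict[int, int] = {}
        for code in config.genetic_codes:
            prots = [
                translate_fragment(m.sequence, code, config.frame_offset) for m in motu.members
            ]
            translations[code] = prots
            stop_totals[code] = sum(p.count("*") for p in prots)
        best = min(stop_totals.values())
        selected = [c for c in config.genetic_codes if stop_totals[c] == best]
        for k, member in enumerate(motu.members):
            per_code_ok = []
            min_stops = min_mismatches = None
            for code in selected:
                prot = translations[code][k]
                stops = prot.count("*")
                mism = 0
                for pos, allowed in config.conserved_positions:
                    if pos > len(prot):
                        raise ValueError(
                            f"conserved position {pos} beyond translated length {len(prot)}"
                        )
                    if prot[pos - 1] not in allowed:
                        mism += 1
                per_code_ok.append(stops == 0 and mism == 0)
                min_stops = stops if min_stops is None else min(min_stops, stops)
                min_mismatches = mism if min_mismatches is None else min(min_mismatches, mism)
            erroneous = not any(per_code_ok)
            n_err += erroneous
            rows.append(
                {
                    "motu": mi,
                    "esv_id": member.id,
                    "erroneous": erroneous,
                    "min_stops": min_stops,
                    "min_conserved_mismatches": min_mismatches,
                    "selected_codes": ",".join(str(c) for c in selected),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["motu", "esv_id", "erroneous", "min_stops", "min_conserved_mismatches", "selected_codes"],
    )
    return df, ErrorSummary(n_esvs=len(rows), n_erroneous=n_err)


def classify_motus(
    motus: Sequence[Motu],
    assignments: pd.DataFrame,
    min_identity: float = 0.97,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify MOTUs against an ESV-to-species assignment table.

    ``assignments`` has columns ``esv_id, species, best_identity``; rows
    below ``min_identity`` count as unassigned.  Categories:

    * ``closed`` — the MOTU holds all of one species' assigned ESVs and
      nothing else;
    * ``open`` — a proper, non-empty subset of one species' assigned ESVs
      and nothing else;
    * ``hybrid`` — assigned ESVs of two or more species, or a mix of
      assigned and unassigned ESVs;
    * ``unassigned`` — no assigned members (excluded from the
      closed/open/hybrid denominator).
    """
    required = {"esv_id", "species", "best_identity"}
    if missing := required - set(assignments.columns):
        raise ValueError(f"assignments missing columns {sorted(missing)}")
    usable = assignments[assignments["best_identity"] >= min_identity]
    esv_to_species = dict(zip(usable["esv_id"].astype(str), usable["species"].astype(str)))
    species_members: dict[str, set[str]] = {}
    for esv_id, sp in esv_to_species.items():
        species_members.setdefault(sp, set()).add(esv_id)

    all_member_ids = {m.id for motu in motus for m in motu.members}
    orphans = set(esv_to_species) - all_member_ids
    if orphans:
        warnings.warn(
            f"{len(orphans)} assigned ESV id(s) absent from all MOTUs: "
            f"{sorted(orphans)[:5]}...",
            stacklevel=2,
        )

    rows = []
    counts = {"closed": 0, "open": 0, "hybrid": 0, "unassigned": 0}
    for mi, motu in enumerate(motus):
        member_ids = {m.id for m in motu.members}
        assigned = {mid: esv_to_species[mid] for mid in member_ids if mid in esv_to_species}
        species = set(assigned.values())
        if not assigned:
            cat = "unassigned"
        elif len(species) >= 2 or len(assigned) < len(member_ids):
            cat = "hybrid"
        else:
            (sp,) = species
            cat = "closed" if set(assigned) == species_members[sp] else "open"
        counts[cat] += 1
        rows.append(
            {
                "motu": mi,
                "representative_id": motu.representative.id,
                "category": cat,
                "n_members": len(member_ids),
                "n_assigned": len(assigned),
                "species": ";".join(sorted(species)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["motu", "representative_id", "category", "n_members", "n_assigned", "species"]
    )
    return df, counts
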