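"""Reading, writing and pre-filtering of dereplicated amplicon datasets.

Datasets are collections of unique (dereplicated) nucleotide sequences with
read counts, as produced upstream by read pairing, quality filtering and
dereplication.  Two on-disk representations are supported:

* ``fasta_size`` — FASTA with USEARCH-style abundance annotations in the
  header (``>id;size=N`` or ``>id;size=N;``);
* ``tabular`` — CSV with columns ``id,count,sequence``.

Everywhere in the package datasets are kept in *canonical order*: decreasing
read count, ties broken by lexicographic sequence.  This makes every
downstream step deterministic.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "UniqueSequence",
    "DatasetError",
    "FilterReport",
    "read_dataset",
    "write_dataset",
    "filter_dataset",
    "canonical_sort",
    "check_dereplicated",
]

_VALID_BASES = frozenset("ACGT")
_SIZE_RE = re.compile(r"^(?P<id>.+?);size=(?P<size>\d+);?$")


class DatasetError(ValueError):
    """Raised for malformed or contract-violating dataset files."""


@dataclass(frozen=True, slots=True)
class UniqueSequence:
    """A dereplicated amplicon: an id, a nucleotide sequence and a read count."""

    id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise DatasetError(f"sequence {self.id!r}: count must be >= 1, got {self.count}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise DatasetError(
                f"sequence {self.id!r}: invalid characters {sorted(bad)} (only A/C/G/T accepted)"
            )


@dataclass(frozen=True, slots=True)
class FilterReport:
    """Bookkeeping for :func:`filter_dataset`: records removed per rule."""

    n_removed_length: int
    n_removed_abundance: int
    reads_removed: int


def canonical_sort(seqs: Iterable[UniqueSequence]) -> list[UniqueSequence]:
    """Sort by decreasing count, ties broken lexicographically by sequence."""
    return sorted(seqs, key=lambda s: (-s.count, s.sequence))


def check_dereplicated(seqs: Sequence[UniqueSequence]) -> None:
    """Raise :class:`DatasetError` if any sequence string occurs twice."""
    seen: dict[str, str] = {}
    for s in seqs:
        if s.sequence in seen:
            raise DatasetError(
                f"dataset is not dereplicated: {s.id!r} duplicates {seen[s.sequence]!r}"
            )
        seen[s.sequence] = s.id


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".csv", ".tsv", ".tab"}:
        return "tabular"
    return "fasta_size"


def read_dataset(path: str | Path, format: str | None = None) -> list[UniqueSequence]:
    """Read a dereplicated dataset, returning records in canonical order.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"fasta_size"`` or ``"tabular"``; inferred from the extension when
        omitted (``.csv`` → tabular, anything else → FASTA).

    Raises
    ------
    DatasetError
        On malformed size annotations, non-ACGT characters or duplicate
        sequences; the message carries the offending line number.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "fasta_size":
        records = _read_fasta_size(path)
    elif fmt == "tabular":
        records = _read_tabular(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    check_dereplicated(records)
    return canonical_sort(records)


def _read_fasta_size(path: Path) -> list[UniqueSequence]:
    text = path.read_text()
    # Header line numbers, so parse errors can point at the file.
    header_lines = [i + 1 for i, line in enumerate(text.splitlines()) if line.startswith(">")]
    records: list[UniqueSequence] = []
    for rec_idx, (title, seq) in enumerate(SimpleFastaParser(io.StringIO(text))):
        lineno = header_lines[rec_idx]
        m = _SIZE_RE.match(title.strip())
        if m is None:
            raise DatasetError(
                f"{path}:{lineno}: malformed size annotation in header {title!r} "
                "(expected 'id;size=N' or 'id;size=N;')"
            )
        seq = seq.upper()
        try:
            records.append(UniqueSequence(id=m["id"], sequence=seq, count=int(m["size"])))
        except DatasetError as exc:
            raise DatasetError(f"{path}:{lineno}: {exc}") from None
    return records


def _read_tabular(path: Path) -> list[UniqueSequence]:
    df = pd.read_csv(path, dtype={"id": str, "count": "int64", "sequence": str})
    missing = {"id", "count", "sequence"} - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=True):
        lineno = row.Index + 2  # header line is 1
        try:
            records.append(
                UniqueSequence(id=str(row.id), sequence=str(row.sequence).upper(), count=int(row.count))
            )
        except DatasetError as exc:
            raise DatasetError(f"{path}:{lineno}: {exc}") from None
    return records


def write_dataset(
    seqs: Iterable[UniqueSequence], path: str | Path, format: str | None = None
) -> None:
    """Write a dataset in canonical order; round-trips losslessly with
    :func:`read_dataset`.  FASTA headers always carry the trailing ``;``."""
    path = Path(path)
    fmt = format or _infer_format(path)
    ordered = canonical_sort(seqs)
    if fmt == "fasta_size":
        with path.open("w") as fh:
            for s in ordered:
                fh.write(f">{s.id};size={s.count};\n{s.sequence}\n")
    elif fmt == "tabular":
        pd.DataFrame(
            {"id": [s.id for s in ordered],
             "count": [s.count for s in ordered],
             "sequence": [s.sequence for s in ordered]}
        ).to_csv(path, index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def filter_dataset(
    seqs: Iterable[UniqueSequence], length: int = 313, minsize: int = 2
) -> tuple[list[UniqueSequence], FilterReport]:
    """Apply the pre-filters: exact fragment length and minimum abundance.

    Keeps only sequences of exactly ``length`` nucleotides with at least
    ``minsize`` reads (``minsize=2`` drops singletons).  Returns the kept
    records in canonical order plus a :class:`FilterReport` with the number of
    records removed by each rule.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    if minsize < 1:
        raise ValueError("minsize must be >= 1")
    kept: list[UniqueSequence] = []
    n_len = n_ab = reads_removed = 0
    for s in seqs:
        if len(s.sequence) != length:
            n_len += 1
            reads_removed += s.count
        elif s.count < minsize:
            n_ab += 1
            reads_removed += s.count
        else:
            kept.append(s)
    return canonical_sort(kept), FilterReport(n_len, n_ab, reads_removed)
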