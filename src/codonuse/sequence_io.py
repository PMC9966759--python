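"""Reading, validation and quality filtering of in-frame CDS sets.

Input coding sequences are expected in frame starting at their first base.
The quality filter removes records that are shorter than a minimum length,
carry too large a fraction of N, or contain more than a permitted number of
in-frame stop codons before the final codon.  Each failing record is
tallied once, under the first rule it fails, in the fixed order
short -> N fraction -> internal stops, so the report is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .genetic_code import STOP_CODONS

__all__ = [
    "DataQualityWarning",
    "GeneRecord",
    "FilterReport",
    "read_cds_fasta",
    "write_fasta",
    "attach_expression",
    "attach_subset_labels",
    "filter_cds",
    "count_internal_stops",
]

_VALID_CHARS = frozenset("ACGTN")


class DataQualityWarning(UserWarning):
    """Non-fatal data anomaly (unmatched ids, trailing bases, ...)."""


@dataclass(frozen=True)
class GeneRecord:
    """One in-frame coding sequence with optional expression and subset label."""

    gene_id: str
    sequence: str
    fpkm: float | None = None
    subset_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError(
                f"record {self.gene_id!r}: sequence shorter than one codon"
            )
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError(f"record {self.gene_id!r}: negative FPKM")

    @property
    def n_codons(self) -> int:
        """Number of complete codons (trailing 1-2 bases ignored)."""
        return len(self.sequence) // 3


@dataclass(frozen=True)
class FilterReport:
    """Tallies of the CDS quality filter, one count per first-failing rule."""

    n_input: int
    n_too_short: int
    n_too_many_n: int
    n_internal_stops: int
    n_pass: int
    min_len: int = 200
    max_n_frac: float = 0.10
    max_internal_stops: int = 1

    def __post_init__(self) -> None:
        removed = self.n_too_short + self.n_too_many_n + self.n_internal_stops
        if self.n_pass + removed != self.n_input:
            raise ValueError("filter tallies do not add up to the input count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "too_short", "too_many_n", "internal_stops", "pass"],
                "count": [
                    self.n_input,
                    self.n_too_short,
                    self.n_too_many_n,
                    self.n_internal_stops,
                    self.n_pass,
                ],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _clean_sequence(gene_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"record {gene_id!r}: invalid characters {sorted(bad)}; "
            "expected A/C/G/T/U/N"
        )
    return seq


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a CDS FASTA into GeneRecords (uppercased, RNA mapped to DNA).

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids and characters outside the A/C/G/T/U/N alphabet are
    errors; an empty file is an error.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GeneRecord(rec.id, _clean_sequence(rec.id, str(rec.seq))))
    if not records:
        raise ValueError(f"no records found in {path}")
    return records


def write_fasta(records: list[GeneRecord], path: str | Path, width: int = 60) -> None:
    """Write records verbatim (sequences untouched), wrapped at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _read_two_column_tsv(path: str | Path, value_col: str) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, {value_col})")
    table = table.iloc[:, :2]
    table.columns = ["gene_id", value_col]
    return table.set_index("gene_id")[value_col]


def attach_expression(
    records: list[GeneRecord], table: str | Path
) -> list[GeneRecord]:
    """Attach FPKM values from a two-column TSV (header row: gene_id, fpkm).

    Records with no matching row keep ``fpkm=None``; table rows that match
    no record trigger a :class:`DataQualityWarning`.  Negative FPKM values
    are an error.
    """
    fpkm = _read_two_column_tsv(table, "fpkm").astype(float)
    if (fpkm < 0).any():
        bad = fpkm.index[fpkm < 0].tolist()
        raise ValueError(f"negative FPKM for gene(s) {bad}")
    known = {r.gene_id for r in records}
    unmatched = [g for g in fpkm.index if g not in known]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} expression row(s) match no record "
            f"(first: {unmatched[0]!r})",
            DataQualityWarning,
            stacklevel=2,
        )
    return [
        replace(r, fpkm=float(fpkm[r.gene_id])) if r.gene_id in fpkm.index else r
        for r in records
    ]


def attach_subset_labels(
    records: list[GeneRecord], table: str | Path
) -> list[GeneRecord]:
    """Attach subset/family labels from a two-column TSV (gene_id, label)."""
    labels = _read_two_column_tsv(table, "subset_label").astype(str)
    known = {r.gene_id for r in records}
    unmatched = [g for g in labels.index if g not in known]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} subset row(s) match no record "
            f"(first: {unmatched[0]!r})",
            DataQualityWarning,
            stacklevel=2,
        )
    return [
        replace(r, subset_label=str(labels[r.gene_id]))
        if r.gene_id in labels.index
        else r
        for r in records
    ]


def count_internal_stops(sequence: str) -> int:
    """In-frame stop codons strictly before the final complete codon.

    The terminal codon is never counted: a trailing stop is the expected
    end of a complete CDS, not a defect.
    """
    n_codons = len(sequence) // 3
    count = 0
    for i in range(n_codons - 1):
        if sequence[3 * i : 3 * i + 3] in STOP_CODONS:
            count += 1
    return count


def filter_cds(
    records: list[GeneRecord],
    min_len: int = 200,
    max_n_frac: float = 0.10,
    max_internal_stops: int = 1,
) -> tuple[list[GeneRecord], FilterReport]:
    """Apply the CDS quality filter and report per-rule tallies.

    A record is removed when its length is below ``min_len`` bp, when its
    N fraction (over the whole sequence) exceeds ``max_n_frac``, or when it
    has more than ``max_internal_stops`` in-frame stop codons before the
    final codon.  Passing records are returned unmodified, in input order.
    """
    if min_len < 3:
        raise ValueError("min_len must be at least one codon (3 bp)")
    kept: list[GeneRecord] = []
    n_short = n_n = n_stops = 0
    for rec in records:
        seq = rec.sequence
        if len(seq) < min_len:
            n_short += 1
        elif seq.count("N") / len(seq) > max_n_frac:
            n_n += 1
        elif count_internal_stops(seq) > max_internal_stops:
            n_stops += 1
        else:
            kept.append(rec)
    report = FilterReport(
        n_input=len(records),
        n_too_short=n_short,
        n_too_many_n=n_n,
        n_internal_stops=n_stops,
        n_pass=len(kept),
        min_len=min_len,
        max_n_frac=max_n_frac,
        max_internal_stops=max_internal_stops,
    )
    return kept, report
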