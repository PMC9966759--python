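"""Base composition by codon position and dinucleotide observed/expected ratios.

Composition is computed over complete codons only; N bases are excluded
from both numerator and denominator.  Dinucleotide usage is summarised at
the three codon-position junctions: within-codon positions 1-2 and 2-3,
and the 3-1 junction between the third base of one codon and the first
base of the next codon of the *same* gene (no wrap across gene
boundaries).  The expected frequency of a dinucleotide at a junction is
the product of the marginal base frequencies at the junction's two
positions; under no neighbour dependence each ratio is 1 and each of the
16 dinucleotides has frequency 1/16.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import BASES, encode_bases
from .sequence_io import DataQualityWarning, GeneRecord

__all__ = [
    "EQUAL_DINUCLEOTIDE_FREQUENCY",
    "JUNCTIONS",
    "PositionComposition",
    "position_composition",
    "composition_table",
    "pooled_composition",
    "dinucleotide_ratios",
    "all_junction_ratios",
]

#: Reference frequency of each of the 16 dinucleotides under equal usage.
EQUAL_DINUCLEOTIDE_FREQUENCY: float = 1.0 / 16.0

JUNCTIONS: tuple[int, ...] = (12, 23, 31)

DINUCLEOTIDES: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(BASES, BASES)
)


@dataclass(frozen=True)
class PositionComposition:
    """Base fractions at codon positions 1-3 and overall for one sequence.

    ``by_position`` is a 3x4 array (rows: codon positions, columns ACGT);
    ``overall`` is the pooled 4-vector.  Each row sums to 1 with N excluded
    from the denominator.
    """

    by_position: np.ndarray
    overall: np.ndarray
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return 0.5 * (self.gc1 + self.gc2)

    @property
    def gc_overall(self) -> float:
        return float(self.overall[1] + self.overall[2])


def _position_counts(record: GeneRecord) -> np.ndarray:
    """4x3 count matrix (base x codon position) over complete codons."""
    n_codons = record.n_codons
    if n_codons < 1:
        raise ValueError(f"record {record.gene_id!r}: no complete codon")
    codes = encode_bases(record.sequence[: 3 * n_codons]).reshape(n_codons, 3)
    counts = np.zeros((4, 3), dtype=np.int64)
    for pos in range(3):
        counts[:, pos] = np.bincount(codes[:, pos], minlength=5)[:4]
    return counts


def position_composition(record: GeneRecord) -> PositionComposition:
    """Per-position base fractions and GC1/GC2/GC3 for one CDS."""
    counts = _position_counts(record)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(
            f"record {record.gene_id!r}: a codon position is entirely N"
        )
    frac = (counts / totals).T  # 3 x 4, rows positions
    overall = counts.sum(axis=1) / counts.sum()
    gc = frac[:, 1] + frac[:, 2]  # C + G columns
    return PositionComposition(
        by_position=frac,
        overall=overall,
        gc1=float(gc[0]),
        gc2=float(gc[1]),
        gc3=float(gc[2]),
    )


def composition_table(records: list[GeneRecord]) -> pd.DataFrame:
    """Per-gene GC1/GC2/GC3/GC12 and overall base fractions."""
    rows = []
    for rec in records:
        comp = position_composition(rec)
        row = {
            "gene_id": rec.gene_id,
            "length": len(rec.sequence),
            "gc1": comp.gc1,
            "gc2": comp.gc2,
            "gc3": comp.gc3,
            "gc12": comp.gc12,
            "gc_overall": comp.gc_overall,
        }
        for i, base in enumerate(BASES):
            row[f"frac_{base}"] = float(comp.overall[i])
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def pooled_composition(records: list[GeneRecord]) -> PositionComposition:
    """Composition over all complete codons of all records pooled together."""
    counts = np.zeros((4, 3), dtype=np.int64)
    for rec in records:
        counts += _position_counts(rec)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("pooled dataset has an all-N codon position")
    frac = (counts / totals).T
    overall = counts.sum(axis=1) / counts.sum()
    gc = frac[:, 1] + frac[:, 2]
    return PositionComposition(
        by_position=frac,
        overall=overall,
        gc1=float(gc[0]),
        gc2=float(gc[1]),
        gc3=float(gc[2]),
    )


def _junction_pairs(record: GeneRecord, junction: int) -> np.ndarray:
    """(n, 2) array of base codes for the pairs at one junction of one gene."""
    n_codons = record.n_codons
    codes = encode_bases(record.sequence[: 3 * n_codons]).reshape(n_codons, 3)
    if junction == 12:
        pairs = codes[:, [0, 1]]
    elif junction == 23:
        pairs = codes[:, [1, 2]]
    elif junction == 31:
        if n_codons < 2:
            return np.empty((0, 2), dtype=np.int64)
        pairs = np.column_stack([codes[:-1, 2], codes[1:, 0]])
    else:
        raise ValueError(f"junction must be one of {JUNCTIONS}, got {junction}")
    return pairs


def dinucleotide_ratios(
    records: list[GeneRecord], junction: int
) -> pd.DataFrame:
    """Observed/expected/ratio for the 16 dinucleotides at one junction.

    Pairs containing N are skipped.  The expected frequency is the product
    of the marginal base frequencies of the two sides of the junction,
    computed over the same counted pairs; a dinucleotide whose expected
    frequency is 0 gets an undefined (NaN) ratio with a warning.
    """
    pair_counts = np.zeros((4, 4), dtype=np.int64)
    for rec in records:
        pairs = _junction_pairs(rec, junction)
        valid = (pairs < 4).all(axis=1)
        pairs = pairs[valid]
        if len(pairs):
            np.add.at(pair_counts, (pairs[:, 0], pairs[:, 1]), 1)
    total = pair_counts.sum()
    if total == 0:
        raise ValueError(f"no countable pairs at junction {junction}")
    observed = pair_counts / total
    first_marginal = observed.sum(axis=1)
    second_marginal = observed.sum(axis=0)
    expected = np.outer(first_marginal, second_marginal)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    if (expected == 0).any():
        warnings.warn(
            f"junction {junction}: some dinucleotides have expected "
            "frequency 0; their ratios are undefined",
            DataQualityWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "junction": junction,
            "dinucleotide": DINUCLEOTIDES,
            "observed": observed.ravel(),
            "expected": expected.ravel(),
            "ratio": ratio.ravel(),
        }
    )


def all_junction_ratios(records: list[GeneRecord]) -> pd.DataFrame:
    """Dinucleotide ratio table for all three junctions, concatenated."""
    return pd.concat(
        [dinucleotide_ratios(records, j) for j in JUNCTIONS],
        ignore_index=True,
    )
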