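"""Per-gene codon-usage metrics: RSCU, Wright's ENC, and protein indices.

RSCU (relative synonymous codon usage) for codon j of amino acid i is

    RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij)

where n_i is the degeneracy of the family, so RSCU sums to n_i within each
observed family and equals 1 for unbiased usage.  Families that do not
occur in a gene yield undefined (NaN) entries, never 0; the single-codon
amino acids Met and Trp are reported as exactly 1.0 when present.

ENC (effective number of codons) follows Wright (1990).  For an amino
acid observed n >= 2 times with usage proportions p_j, the codon
homozygosity is F = (n * sum p_j^2 - 1) / (n - 1).  Class means F2, F3,
F4, F6 are taken over amino acids of degeneracy 2/3/4/6 with defined,
positive F, and

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,   capped at 61.

A missing F3 (Ile absent) is replaced by (F2 + F4)/2, Wright's own
fallback; if F2, F4 or F6 cannot be estimated the gene's ENC is undefined
(NaN).  Under pure mutation pressure toward third-position GC content s,
the expected ENC is the closed form 2 + s + 29/(s^2 + (1-s)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import (
    AA_INDEX,
    AA_ORDER,
    AA_TO_CODONS,
    AROMATIC_AAS,
    CODON64_IS_STOP,
    CODON64_TO_SENSE,
    CODON_INDEX,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERACY_CLASSES,
    KYTE_DOOLITTLE,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    THIRD_BASE_IS_GC,
    encode_bases,
)
from .sequence_io import DataQualityWarning, GeneRecord

__all__ = [
    "CodonCountTable",
    "count_codons",
    "rscu",
    "enc",
    "expected_enc",
    "expected_enc_curve",
    "deviation_ratio",
    "protein_indices",
    "gc3_from_counts",
    "gene_metrics",
    "pooled_rscu",
]

# per-family codon index lists, fixed order, reused by rscu() and enc()
_FAMILY_IDX: dict[str, np.ndarray] = {
    aa: np.array([CODON_INDEX[c] for c in codons])
    for aa, codons in AA_TO_CODONS.items()
}


@dataclass(frozen=True)
class CodonCountTable:
    """Sense-codon counts for one gene, in ``SENSE_CODONS`` order.

    Stop codons are tallied separately in ``n_stops`` and never enter the
    61-vector.  Codons containing N are skipped entirely.
    """

    gene_id: str
    counts: np.ndarray  # shape (61,), int
    n_stops: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != (len(SENSE_CODONS),):
            raise ValueError("counts must be a 61-vector in SENSE_CODONS order")
        if (self.counts < 0).any():
            raise ValueError("codon counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(SENSE_CODONS, self.counts)}


def count_codons(record: GeneRecord) -> CodonCountTable:
    """Count sense codons over the complete, N-free codons of a CDS."""
    n_codons = record.n_codons
    if n_codons < 1:
        raise ValueError(f"record {record.gene_id!r}: no complete codon")
    if len(record.sequence) % 3:
        warnings.warn(
            f"record {record.gene_id!r}: {len(record.sequence) % 3} trailing "
            "base(s) ignored",
            DataQualityWarning,
            stacklevel=2,
        )
    codes = encode_bases(record.sequence[: 3 * n_codons]).reshape(n_codons, 3)
    clean = (codes < 4).all(axis=1)
    flat = codes[clean] @ np.array([16, 4, 1])
    if flat.size == 0:
        raise ValueError(f"record {record.gene_id!r}: no countable codon")
    n_stops = int(CODON64_IS_STOP[flat].sum())
    sense = CODON64_TO_SENSE[flat]
    counts = np.bincount(sense[sense >= 0], minlength=len(SENSE_CODONS))
    return CodonCountTable(record.gene_id, counts, n_stops)


def rscu(table: CodonCountTable) -> np.ndarray:
    """RSCU 61-vector; NaN for families with zero occurrences."""
    counts = table.counts.astype(float)
    out = np.full(len(SENSE_CODONS), np.nan)
    for aa, idx in _FAMILY_IDX.items():
        n_i = len(idx)
        if n_i == 1:
            if counts[idx[0]] > 0:
                out[idx[0]] = 1.0
            continue
        family_total = counts[idx].sum()
        if family_total > 0:
            out[idx] = counts[idx] / (family_total / n_i)
    return out


def enc(table: CodonCountTable) -> float:
    """Wright's effective number of codons for one gene (NaN if undefined)."""
    counts = table.counts.astype(float)
    f_bar: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            idx = _FAMILY_IDX[aa]
            n = counts[idx].sum()
            if n < 2:
                continue
            p = counts[idx] / n
            f = (n * (p**2).sum() - 1.0) / (n - 1.0)
            if f > 0:
                fs.append(f)
        f_bar[k] = float(np.mean(fs)) if fs else np.nan
    if np.isnan(f_bar[2]) or np.isnan(f_bar[4]) or np.isnan(f_bar[6]):
        return float("nan")
    if np.isnan(f_bar[3]):
        f_bar[3] = 0.5 * (f_bar[2] + f_bar[4])
    value = 2.0 + 9.0 / f_bar[2] + 1.0 / f_bar[3] + 5.0 / f_bar[4] + 3.0 / f_bar[6]
    return min(value, 61.0)


def expected_enc(gc3: float | np.ndarray) -> float | np.ndarray:
    """Mutation-pressure-only ENC expectation, 2 + s + 29/(s^2 + (1-s)^2)."""
    s = np.asarray(gc3, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("gc3 must lie in [0, 1]")
    value = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(value) if np.isscalar(gc3) else value


def expected_enc_curve(n_points: int = 1000) -> pd.DataFrame:
    """Expected-ENC curve on GC3 values equally spaced in [0.001, 1.000]."""
    s = np.linspace(0.001, 1.000, n_points)
    return pd.DataFrame({"gc3": s, "enc_expected": expected_enc(s)})


def deviation_ratio(enc_obs: float, gc3: float) -> float:
    """(ENC_expected - ENC_observed) / ENC_expected at the gene's GC3."""
    if np.isnan(enc_obs):
        return float("nan")
    expected = expected_enc(gc3)
    return (expected - enc_obs) / expected


_INFORMATIVE_MASK = np.array(
    [CODON_TO_AA[c] not in SINGLE_CODON_AAS for c in SENSE_CODONS]
)


def gc3_from_counts(table: CodonCountTable) -> float:
    """G+C fraction at synonymous third codon positions (CodonW's GC3s).

    Stops and the single-codon amino acids Met and Trp are excluded: their
    third base is fixed by the amino acid and carries no usage signal, and
    the ENC-GC3 expectation concerns synonymous choice only.
    """
    informative = table.counts[_INFORMATIVE_MASK]
    total = informative.sum()
    if total == 0:
        return float("nan")
    return float(
        table.counts[THIRD_BASE_IS_GC & _INFORMATIVE_MASK].sum() / total
    )


def protein_indices(record: GeneRecord) -> tuple[float, float, np.ndarray]:
    """GRAVY, aromaticity and amino-acid profile of the translated CDS.

    GRAVY is the mean Kyte-Doolittle hydropathy over translated residues;
    aromaticity is the fraction of Phe/Tyr/Trp.  Codons containing N and
    internal stop codons are skipped (the latter with a warning).
    """
    n_codons = record.n_codons
    seq = record.sequence[: 3 * n_codons]
    profile = np.zeros(len(AA_ORDER))
    skipped_stops = 0
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            if "N" not in codon and i < n_codons - 1:
                skipped_stops += 1
            continue
        profile[AA_INDEX[aa]] += 1
    if skipped_stops:
        warnings.warn(
            f"record {record.gene_id!r}: {skipped_stops} internal stop "
            "codon(s) skipped in translation",
            DataQualityWarning,
            stacklevel=2,
        )
    n_residues = profile.sum()
    if n_residues == 0:
        raise ValueError(f"record {record.gene_id!r}: no translatable residue")
    profile /= n_residues
    gravy = float(sum(KYTE_DOOLITTLE[aa] * profile[AA_INDEX[aa]] for aa in AA_ORDER))
    aromo = float(sum(profile[AA_INDEX[aa]] for aa in AROMATIC_AAS))
    return gravy, aromo, profile


def gene_metrics(
    records: list[GeneRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Per-gene metric table, RSCU matrix and amino-acid profile matrix.

    Returns ``(metrics, rscu_matrix, aa_profiles)`` where ``metrics`` has
    one row per gene (length, GC by position, ENC, deviation ratio, GRAVY,
    aromaticity, FPKM), ``rscu_matrix`` is genes x 61 with NaN for absent
    families, and ``aa_profiles`` is genes x 20.  GC3 here is computed
    over sense codons only, matching the codon table behind ENC.
    """
    # first/second-position GC indicator per sense codon, shared across genes
    pos12_gc = np.array(
        [[c[0] in "GC", c[1] in "GC"] for c in SENSE_CODONS], dtype=float
    )
    rows = []
    rscu_rows = []
    profiles = []
    for rec in records:
        table = count_codons(rec)
        gc3 = gc3_from_counts(table)
        enc_value = enc(table)
        gravy, aromo, profile = protein_indices(rec)
        total = table.total
        gc1 = float((table.counts * pos12_gc[:, 0]).sum() / total)
        gc2 = float((table.counts * pos12_gc[:, 1]).sum() / total)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "length": len(rec.sequence),
                "n_codons": total,
                "gc1": gc1,
                "gc2": gc2,
                "gc3": gc3,
                "gc12": 0.5 * (gc1 + gc2),
                "enc": enc_value,
                "deviation_ratio": deviation_ratio(enc_value, gc3),
                "gravy": gravy,
                "aromo": aromo,
                "fpkm": np.nan if rec.fpkm is None else rec.fpkm,
                "subset_label": rec.subset_label,
            }
        )
        rscu_rows.append(rscu(table))
        profiles.append(profile)
    metrics = pd.DataFrame(rows).set_index("gene_id")
    rscu_matrix = pd.DataFrame(
        np.array(rscu_rows), index=metrics.index, columns=list(SENSE_CODONS)
    )
    return metrics, rscu_matrix, np.array(profiles)


def pooled_rscu(tables: list[CodonCountTable]) -> pd.DataFrame:
    """Genome-level RSCU from summed counts (not averaged per-gene RSCU)."""
    total = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for t in tables:
        total += t.counts
    pooled = CodonCountTable("__pooled__", total)
    values = rscu(pooled)
    return pd.DataFrame(
        {
            "amino_acid": [CODON_TO_AA[c] for c in SENSE_CODONS],
            "codon": SENSE_CODONS,
            "count": total,
            "rscu": values,
            "degeneracy": [DEGENERACY[CODON_TO_AA[c]] for c in SENSE_CODONS],
        }
    ).sort_values(["amino_acid", "codon"], ignore_index=True)
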