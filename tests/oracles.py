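"""Independent from-definition reference implementations for cross-checks.

These are written directly from the textbook definitions of RSCU, Wright's
ENC and synonymous-position GC content, using plain dict/loop code and
Biopython's codon table, deliberately sharing no code with the package.
They exist so the package's vectorised implementations can be verified
against an independent route; they are never used as the implementation.
"""

from __future__ import annotations

import math

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)

FAMILIES: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(aa, []).append(codon)


def count_codons_oracle(sequence: str) -> dict[str, int]:
    """Sense-codon counts over complete, N-free codons; stops excluded."""
    counts: dict[str, int] = {}
    for i in range(len(sequence) // 3):
        codon = sequence[3 * i : 3 * i + 3]
        if codon in CODON_TO_AA:
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def rscu_oracle(counts: dict[str, int]) -> dict[str, float]:
    """RSCU per codon: observed count over the equal-use expectation."""
    out: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        expected = total / len(codons)
        for c in codons:
            out[c] = counts.get(c, 0) / expected
    return out


def enc_oracle(counts: dict[str, int]) -> float:
    """Wright's ENC, computed codon family by codon family.

    Homozygosity F = (n * sum p^2 - 1)/(n - 1) per amino acid with n >= 2
    codons; class means over degeneracy 2/3/4/6 with positive F;
    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 capped at 61, with a missing F3
    replaced by (F2 + F4)/2 and a missing F2/F4/F6 making ENC undefined.
    """
    f_values: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if len(codons) < 2:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f > 0:
            f_values[aa] = f
    class_mean: dict[int, float | None] = {}
    for k in (2, 3, 4, 6):
        vals = [f for aa, f in f_values.items() if len(FAMILIES[aa]) == k]
        class_mean[k] = sum(vals) / len(vals) if vals else None
    if class_mean[2] is None or class_mean[4] is None or class_mean[6] is None:
        return math.nan
    if class_mean[3] is None:
        class_mean[3] = (class_mean[2] + class_mean[4]) / 2.0
    value = (
        2.0
        + 9.0 / class_mean[2]
        + 1.0 / class_mean[3]
        + 5.0 / class_mean[4]
        + 3.0 / class_mean[6]
    )
    return min(value, 61.0)


def gc3s_oracle(counts: dict[str, int]) -> float:
    """GC fraction at synonymous third positions (multi-codon families)."""
    total = gc = 0
    for aa, codons in FAMILIES.items():
        if len(codons) < 2:
            continue
        for c in codons:
            n = counts.get(c, 0)
            total += n
            if c[2] in "GC":
                gc += n
    return math.nan if total == 0 else gc / total


def conservative_pairs_oracle() -> list[tuple[str, str]]:
    """Brute-force scan of all 64x64 codon pairs for the GC-conservative set."""
    pairs = []
    bases = "ACGT"
    all_codons = [a + b + c for a in bases for b in bases for c in bases]
    for x in all_codons:
        for y in all_codons:
            if x >= y or x in STOPS or y in STOPS:
                continue
            if x[:2] != y[:2]:
                continue
            if CODON_TO_AA[x] != CODON_TO_AA[y]:
                continue
            third = {x[2], y[2]}
            if third == {"A", "T"} or third == {"C", "G"}:
                pairs.append((x, y))
    return sorted(pairs)
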