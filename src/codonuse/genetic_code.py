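"""Standard genetic-code tables shared across the package.

All tables are derived once, at import time, from Biopython's standard
(NCBI table 1) codon table.  Codons are DNA-alphabet (T, not U) and the
fixed ``SENSE_CODONS`` ordering (alphabetical) defines the column order of
every per-gene codon-count vector and RSCU vector in the package.

Synonymous families are defined purely by amino acid, so Leu, Ser and Arg
are each a single six-fold family (the CodonW convention).
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))  # TAA TAG TGA
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))  # 61
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

AA_ORDER: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))  # 20
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}

AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AA_ORDER
}
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

# Met and Trp have a single codon each; they carry no synonymous choice and
# are excluded from bias summaries (their RSCU is 1 by definition).
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, k in DEGENERACY.items() if k == 1
)
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)  # 59

# Degeneracy classes feeding Wright's ENC: 9 two-fold, 1 three-fold (Ile),
# 5 four-fold, 3 six-fold amino acids.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa in AA_ORDER if DEGENERACY[aa] == k) for k in (2, 3, 4, 6)
}

AROMATIC_AAS: frozenset[str] = frozenset("FWY")

BASES: tuple[str, ...] = ("A", "C", "G", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

# codon index (0..63, base-4 over ACGT) -> sense index (0..60) or -1 for stops
_codon64_to_sense = np.full(64, -1, dtype=np.int64)
_codon64_is_stop = np.zeros(64, dtype=bool)
for _i, _b1 in enumerate(BASES):
    for _j, _b2 in enumerate(BASES):
        for _k, _b3 in enumerate(BASES):
            _codon = _b1 + _b2 + _b3
            _flat = 16 * _i + 4 * _j + _k
            if _codon in STOP_CODONS:
                _codon64_is_stop[_flat] = True
            else:
                _codon64_to_sense[_flat] = CODON_INDEX[_codon]
CODON64_TO_SENSE = _codon64_to_sense
CODON64_IS_STOP = _codon64_is_stop

# third-position base of each sense codon, as index into BASES
THIRD_BASE_INDEX = np.array([BASE_INDEX[c[2]] for c in SENSE_CODONS])
THIRD_BASE_IS_GC = np.array([c[2] in "GC" for c in SENSE_CODONS])

# byte-level encoder: A/C/G/T -> 0..3, N (and anything else) -> 4
_ENCODE = np.full(256, 4, dtype=np.int64)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


def encode_bases(sequence: str) -> np.ndarray:
    """Map an uppercase DNA string to integer codes (A=0 C=1 G=2 T=3, N=4)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def translate_codon(codon: str) -> str | None:
    """Amino-acid letter for a sense codon, '*' for a stop, None otherwise."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA.get(codon)
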