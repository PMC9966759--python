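"""Synthetic CDS datasets with known ground truth.

The generator emulates the two regimes whose contrast drives codon-usage
inference on real transcriptomes:

* **mutation pressure only** (``selection_strength = 0``): each gene draws
  a third-position GC preference *s* from a Beta law; within every
  synonymous family, codons ending in G or C receive weight *s*/2 and
  codons ending in A or T receive (1-*s*)/2 (restricted to the family's
  available third bases and renormalised).  Realised per-gene GC3 then
  tracks *s*, and the (GC3, ENC) cloud hugs the mutation-only expected
  ENC curve.
* **translational selection** (``selection_strength > 0``): codons in the
  configured ``preferred_set`` get an extra weight factor
  ``exp(selection_strength * z)`` where *z* in [0, 1] is the gene's
  normalised log-expression rank, so preference grows with expression —
  the signature the GC-conservative preferred-codon test is built to
  detect.

Amino acids are drawn independently from a fixed profile (uniform over
the 20 by default) and codon choices are independent across residues.
Gene lengths follow a lognormal law with mean near 489 bp (a typical
insect-transcriptome mean CDS length) floored so that clean genes always
pass the 200 bp quality filter; FPKM values are lognormal.  Corrupted
records (short, N-rich, multi-internal-stop) can be appended to exercise
the quality filter, each built to fail exactly one rule.  The seed fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import AA_ORDER, AA_TO_CODONS, CODON_INDEX, SENSE_CODONS, STOP_CODONS
from .sequence_io import GeneRecord, write_fasta

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "plant_corruptions",
    "write_dataset",
    "make_fixtures",
    "DEFAULT_PREFERRED_SET",
]

#: One C-ending codon from the C/G conservative pair of each four-fold
#: family — the default planted "optimal" codons for the selection regime.
DEFAULT_PREFERRED_SET: tuple[str, ...] = ("ACC", "CCC", "GCC", "GGC", "GTC")

_N_FAMILIES = len(AA_ORDER)
_MAX_DEGEN = max(len(c) for c in AA_TO_CODONS.values())

# (20, 6) padded family structure shared by all draws
_FAM_CODON = np.full((_N_FAMILIES, _MAX_DEGEN), -1, dtype=np.int64)
_FAM_AVAIL = np.zeros((_N_FAMILIES, _MAX_DEGEN), dtype=bool)
_FAM_GC3 = np.zeros((_N_FAMILIES, _MAX_DEGEN), dtype=bool)
for _i, _aa in enumerate(AA_ORDER):
    for _j, _codon in enumerate(AA_TO_CODONS[_aa]):
        _FAM_CODON[_i, _j] = CODON_INDEX[_codon]
        _FAM_AVAIL[_i, _j] = True
        _FAM_GC3[_i, _j] = _codon[2] in "GC"

_CODON_BYTES = np.array(SENSE_CODONS, dtype="S3")
_STOP_GC3 = np.array([c[2] in "GC" for c in STOP_CODONS])


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; the seed fully determines the dataset."""

    n_genes: int = 1000
    mean_length: float = 489.0  # bp including the terminal stop
    length_sigma: float = 0.45  # lognormal sd on the log scale
    min_codons: int = 67  # floor on amino-acid count; keeps clean genes >= 204 bp
    gc3_alpha: float = 2.0  # Beta law of the per-gene GC3 preference
    gc3_beta: float = 2.0
    selection_strength: float = 0.0
    preferred_set: tuple[str, ...] = DEFAULT_PREFERRED_SET
    fpkm_meanlog: float = 1.0
    fpkm_sdlog: float = 1.5
    aa_profile: tuple[float, ...] | None = None  # None = uniform over 20
    n_short: int = 0
    n_n_rich: int = 0
    n_multi_stop: int = 0
    subset_sizes: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.length_sigma <= 0 or self.mean_length < 3 * (self.min_codons + 1):
            raise ValueError("invalid length law parameters")
        if self.gc3_alpha <= 0 or self.gc3_beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.fpkm_sdlog <= 0:
            raise ValueError("fpkm_sdlog must be positive")
        for codon in self.preferred_set:
            if codon not in CODON_INDEX:
                raise ValueError(f"preferred codon {codon!r} is not a sense codon")
        if self.aa_profile is not None and (
            len(self.aa_profile) != _N_FAMILIES
            or any(w < 0 for w in self.aa_profile)
            or sum(self.aa_profile) <= 0
        ):
            raise ValueError("aa_profile must be 20 non-negative weights")


@dataclass(frozen=True)
class GroundTruth:
    """Per-gene generative parameters, aligned one-to-one with the records."""

    frame: pd.DataFrame  # gene_id, true_gc3, fpkm, expression_rank, corruption
    preferred_set: tuple[str, ...]
    selection_strength: float


def _preferred_mask(preferred_set: tuple[str, ...]) -> np.ndarray:
    mask = np.zeros_like(_FAM_AVAIL)
    wanted = {CODON_INDEX[c] for c in preferred_set}
    mask[np.isin(_FAM_CODON, list(wanted))] = True
    return mask


def _codon_probs(
    s: float, sel_boost: float, pref_mask: np.ndarray
) -> np.ndarray:
    """(20, 6) within-family codon probabilities for one gene."""
    w = np.where(_FAM_GC3, s / 2.0, (1.0 - s) / 2.0)
    w = np.where(_FAM_AVAIL, w, 0.0)
    if sel_boost != 0.0:
        w = np.where(pref_mask, w * np.exp(sel_boost), w)
    return w / w.sum(axis=1, keepdims=True)


def _draw_gene(
    rng: np.random.Generator,
    n_residues: int,
    probs: np.ndarray,
    aa_p: np.ndarray,
    s: float,
) -> str:
    residues = rng.choice(_N_FAMILIES, size=n_residues, p=aa_p)
    cum = probs.cumsum(axis=1)[residues]
    u = rng.random(n_residues)
    slot = (u[:, None] > cum).sum(axis=1)
    codons = _FAM_CODON[residues, slot]
    stop_w = np.where(_STOP_GC3, s, 1.0 - s)
    stop = rng.choice(len(STOP_CODONS), p=stop_w / stop_w.sum())
    return _CODON_BYTES[codons].tobytes().decode("ascii") + STOP_CODONS[stop]


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[GeneRecord], GroundTruth]:
    """Generate a CDS set (with FPKM attached) and its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    aa_p = (
        np.full(_N_FAMILIES, 1.0 / _N_FAMILIES)
        if config.aa_profile is None
        else np.asarray(config.aa_profile, dtype=float)
        / sum(config.aa_profile)
    )
    mean_residues = config.mean_length / 3.0 - 1.0
    mu = np.log(mean_residues) - 0.5 * config.length_sigma**2
    lengths = np.maximum(
        np.round(rng.lognormal(mu, config.length_sigma, n)).astype(int),
        config.min_codons,
    )
    fpkm = rng.lognormal(config.fpkm_meanlog, config.fpkm_sdlog, n)
    # normalised log-expression rank in [0, 1]; drives the selection term
    order = np.argsort(np.argsort(fpkm))
    z = order / max(n - 1, 1)
    s_true = rng.beta(config.gc3_alpha, config.gc3_beta, n)
    pref_mask = _preferred_mask(config.preferred_set)
    width = len(str(n))
    records = []
    for g in range(n):
        boost = config.selection_strength * z[g]
        probs = _codon_probs(s_true[g], boost, pref_mask)
        seq = _draw_gene(rng, int(lengths[g]), probs, aa_p, s_true[g])
        records.append(
            GeneRecord(f"gene_{g + 1:0{width}d}", seq, fpkm=float(fpkm[g]))
        )
    truth_rows = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "true_gc3": s_true,
            "fpkm": fpkm,
            "expression_rank": z,
            "corruption": [None] * n,
        }
    )
    if config.subset_sizes:
        records, truth_rows = _assign_subsets(rng, records, truth_rows, config)
    records, truth_rows = plant_corruptions(records, config, rng=rng, truth=truth_rows)
    truth = GroundTruth(
        frame=truth_rows.reset_index(drop=True),
        preferred_set=tuple(config.preferred_set),
        selection_strength=config.selection_strength,
    )
    return records, truth


def _assign_subsets(
    rng: np.random.Generator,
    records: list[GeneRecord],
    truth_rows: pd.DataFrame,
    config: SyntheticConfig,
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Label random genes with family names (null draw from the background)."""
    from dataclasses import replace

    total = sum(config.subset_sizes.values())
    if total > len(records):
        raise ValueError("subset sizes exceed the number of genes")
    chosen = rng.choice(len(records), size=total, replace=False)
    truth_rows = truth_rows.assign(subset_label=None)
    start = 0
    records = list(records)
    for label, size in sorted(config.subset_sizes.items()):
        for idx in chosen[start : start + size]:
            records[idx] = replace(records[idx], subset_label=label)
            truth_rows.loc[idx, "subset_label"] = label
        start += size
    return records, truth_rows


def _clean_codons(rng: np.random.Generator, n_residues: int) -> str:
    """Uniform-composition codon string with no stop codons and no N."""
    probs = _codon_probs(0.5, 0.0, _preferred_mask(()))
    aa_p = np.full(_N_FAMILIES, 1.0 / _N_FAMILIES)
    residues = rng.choice(_N_FAMILIES, size=n_residues, p=aa_p)
    cum = probs.cumsum(axis=1)[residues]
    slot = (rng.random(n_residues)[:, None] > cum).sum(axis=1)
    return _CODON_BYTES[_FAM_CODON[residues, slot]].tobytes().decode("ascii")


def plant_corruptions(
    records: list[GeneRecord],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[list[GeneRecord], pd.DataFrame | None]:
    """Append records engineered to fail exactly one quality-filter rule.

    ``n_short`` records of 150 bp (clean), ``n_n_rich`` records of 300 bp
    with 15% N, and ``n_multi_stop`` records of 300 bp with 3 internal
    stop codons.  A record with exactly one internal stop would *pass*
    the filter, so the multi-stop records always carry more than one.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    records = list(records)
    extra_rows = []

    def _add(record: GeneRecord, kind: str) -> None:
        records.append(record)
        extra_rows.append(
            {
                "gene_id": record.gene_id,
                "true_gc3": np.nan,
                "fpkm": np.nan,
                "expression_rank": np.nan,
                "corruption": kind,
            }
        )

    for i in range(config.n_short):
        seq = _clean_codons(rng, 49) + STOP_CODONS[rng.choice(3)]  # 150 bp
        _add(GeneRecord(f"corrupt_short_{i + 1}", seq), "short")
    for i in range(config.n_n_rich):
        seq = list(_clean_codons(rng, 99) + STOP_CODONS[rng.choice(3)])  # 300 bp
        for pos in rng.choice(len(seq), size=45, replace=False):  # 15% N
            seq[pos] = "N"
        _add(GeneRecord(f"corrupt_nrich_{i + 1}", "".join(seq)), "n_rich")
    for i in range(config.n_multi_stop):
        codons = [
            _clean_codons(rng, 1) for _ in range(99)
        ]  # 99 codons + terminal stop = 300 bp
        for pos in rng.choice(98, size=3, replace=False):  # internal only
            codons[pos] = STOP_CODONS[rng.choice(3)]
        seq = "".join(codons) + STOP_CODONS[rng.choice(3)]
        _add(GeneRecord(f"corrupt_stops_{i + 1}", seq), "multi_stop")

    if truth is None:
        return records, None
    if extra_rows:
        truth = pd.concat([truth, pd.DataFrame(extra_rows)], ignore_index=True)
    return records, truth


def write_dataset(
    records: list[GeneRecord], truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write FASTA, expression TSV, subset TSV and ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": outdir / "synthetic_cds.fasta"}
    write_fasta(records, paths["fasta"])
    expr = pd.DataFrame(
        [(r.gene_id, r.fpkm) for r in records if r.fpkm is not None],
        columns=["gene_id", "fpkm"],
    )
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False)
    subsets = pd.DataFrame(
        [(r.gene_id, r.subset_label) for r in records if r.subset_label],
        columns=["gene_id", "subset_label"],
    )
    if len(subsets):
        paths["subsets"] = outdir / "subsets.tsv"
        subsets.to_csv(paths["subsets"], sep="\t", index=False)
    paths["truth"] = outdir / "ground_truth.tsv"
    truth.frame.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the standard small fixture set used by the test suite."""
    config = SyntheticConfig(
        n_genes=300,
        n_short=5,
        n_n_rich=5,
        n_multi_stop=5,
        subset_sizes={"OBP": 20, "CSP": 10},
        seed=seed,
    )
    records, truth = generate_dataset(config)
    return write_dataset(records, truth, outdir)
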