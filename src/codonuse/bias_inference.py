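"""Genome-level inference on codon usage: PCA, correlation screens,
GC-conservative preferred-codon detection and subset comparison.

The preferred-codon test works on GC-conservative synonymous codon pairs:
two codons of the same amino acid that differ only at the third position
by A<->T or by C<->G.  Because both members of a pair share their GC
content, the relative usage count(a)/(count(a)+count(b)) is immune to
AT/GC mutation bias and GC-biased gene conversion; a correlation between
relative usage and expression level is therefore evidence of translational
selection rather than mutation pressure.  The standard genetic code
contains exactly 17 such pairs.  A codon is called preferred when the
absolute correlation coefficient with (log-transformed) expression exceeds
``r_threshold`` and the p-value falls below ``p_threshold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .genetic_code import (
    CODON_INDEX,
    CODON_TO_AA,
    INFORMATIVE_CODONS,
    SENSE_CODONS,
)
from .codon_metrics import CodonCountTable
from .sequence_io import DataQualityWarning

__all__ = [
    "ConservativePair",
    "enumerate_conservative_pairs",
    "build_rscu_matrix",
    "pca_rscu",
    "correlation_screen",
    "relative_pair_usage",
    "detect_preferred_codons",
    "subset_bias_comparison",
]


@dataclass(frozen=True)
class ConservativePair:
    """A GC-conservative synonymous codon pair (third base A/T or C/G)."""

    amino_acid: str
    codon_a: str  # third base A or C
    codon_b: str  # third base T or G
    pair_class: str  # "AT" or "CG"

    @property
    def name(self) -> str:
        return f"{self.codon_a}/{self.codon_b}"


def enumerate_conservative_pairs() -> list[ConservativePair]:
    """Scan the standard genetic code for third-position A/T and C/G pairs.

    Both members must be sense codons coding for the same amino acid;
    stop codons and the single-codon amino acids can never qualify.  The
    result is deterministic: sorted by codon_a.
    """
    pairs = []
    prefixes = sorted({c[:2] for c in SENSE_CODONS})
    for prefix in prefixes:
        for third_a, third_b, pair_class in (("A", "T", "AT"), ("C", "G", "CG")):
            a, b = prefix + third_a, prefix + third_b
            if a in CODON_TO_AA and b in CODON_TO_AA and CODON_TO_AA[a] == CODON_TO_AA[b]:
                pairs.append(ConservativePair(CODON_TO_AA[a], a, b, pair_class))
    return sorted(pairs, key=lambda p: p.codon_a)


def build_rscu_matrix(rscu_matrix: pd.DataFrame) -> pd.DataFrame:
    """Genes x 59 informative-codon RSCU matrix, NaN imputed with 1.0.

    Met and Trp columns are dropped (no synonymous choice); absent
    families are imputed with the no-bias value 1.0 so they add no
    spurious variance direction.  Row order is preserved.
    """
    if len(rscu_matrix) < 3:
        raise ValueError("need at least 3 genes to build an RSCU matrix")
    matrix = rscu_matrix.loc[:, list(INFORMATIVE_CODONS)].copy()
    return matrix.fillna(1.0)


def _fix_signs(
    scores: np.ndarray, loadings: np.ndarray, gc3: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic component signs.

    PC1 is oriented to correlate non-negatively with GC3 (when supplied
    and non-constant); every other component has its largest-magnitude
    loading made positive.
    """
    for k in range(scores.shape[1]):
        flip = False
        if k == 0 and gc3 is not None and np.nanstd(gc3) > 0:
            valid = ~np.isnan(gc3)
            if valid.sum() >= 3 and np.std(scores[valid, 0]) > 0:
                flip = np.corrcoef(scores[valid, 0], gc3[valid])[0, 1] < 0
            else:
                flip = loadings[k, np.abs(loadings[k]).argmax()] < 0
        else:
            flip = loadings[k, np.abs(loadings[k]).argmax()] < 0
        if flip:
            scores[:, k] *= -1
            loadings[k] *= -1
    return scores, loadings


def pca_rscu(
    matrix: pd.DataFrame,
    gc3: np.ndarray | pd.Series | None = None,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of the centred (not variance-scaled) RSCU matrix.

    Returns ``(scores, variance_fraction, loadings)``.  Components are
    sign-fixed (PC1 non-negatively correlated with GC3) so outputs are
    deterministic; variance fractions are sorted descending and sum to
    <= 1, with rank-deficient directions carrying 0 variance.
    """
    x = matrix.to_numpy(dtype=float)
    max_k = min(x.shape)
    k = max_k if n_components is None else min(n_components, max_k)
    model = PCA(n_components=k, svd_solver="full")
    with np.errstate(invalid="ignore"):
        scores = model.fit_transform(x)
    loadings = model.components_.copy()
    variance_fraction = model.explained_variance_ratio_.copy()
    # a constant matrix has zero total variance; report 0, not NaN
    variance_fraction[~np.isfinite(variance_fraction)] = 0.0
    gc3_arr = None if gc3 is None else np.asarray(gc3, dtype=float)
    scores, loadings = _fix_signs(scores, loadings, gc3_arr)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=cols)
    loadings_df = pd.DataFrame(loadings, index=cols, columns=matrix.columns)
    return scores_df, variance_fraction, loadings_df


def _correlate(
    x: np.ndarray, y: np.ndarray, method: str
) -> tuple[float, float, int]:
    valid = ~(np.isnan(x) | np.isnan(y))
    n = int(valid.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    xv, yv = x[valid], y[valid]
    if (xv == xv[0]).all() or (yv == yv[0]).all():
        return float("nan"), float("nan"), n
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), n


def correlation_screen(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    aa_profiles: np.ndarray | None = None,
    method: str = "pearson",
    n_aa_components: int = 3,
) -> pd.DataFrame:
    """Correlate ENC and RSCU PCs against GC3, expression and protein traits.

    Expression enters as log2(FPKM + 1).  Amino-acid composition is
    summarised by the first ``n_aa_components`` PCs of the genes x 20
    profile matrix.  Missing values are deleted pairwise and the n used
    for each correlation is reported, alongside Benjamini-Hochberg
    adjusted p-values (raw p-values are kept as the primary column).
    """
    predictors: dict[str, np.ndarray] = {
        "gc3": metrics["gc3"].to_numpy(float),
        "log2_fpkm": np.log2(metrics["fpkm"].to_numpy(float) + 1.0),
        "gravy": metrics["gravy"].to_numpy(float),
        "aromo": metrics["aromo"].to_numpy(float),
    }
    if aa_profiles is not None and len(aa_profiles) >= 3:
        k = min(n_aa_components, min(aa_profiles.shape))
        aa_scores = PCA(n_components=k, svd_solver="full").fit_transform(
            np.asarray(aa_profiles, dtype=float)
        )
        for i in range(k):
            predictors[f"aa_PC{i + 1}"] = aa_scores[:, i]
    responses: dict[str, np.ndarray] = {"enc": metrics["enc"].to_numpy(float)}
    for col in scores.columns[:2]:
        responses[col] = scores[col].to_numpy(float)
    rows = []
    for resp_name, resp in responses.items():
        for pred_name, pred in predictors.items():
            r, p, n = _correlate(resp, pred, method)
            rows.append(
                {
                    "variable_pair": f"{resp_name}~{pred_name}",
                    "r": r,
                    "r_squared": r**2 if not np.isnan(r) else float("nan"),
                    "p": p,
                    "n": n,
                }
            )
    table = pd.DataFrame(rows)
    defined = table["p"].notna()
    adjusted = np.full(len(table), np.nan)
    if defined.any():
        adjusted[defined.to_numpy()] = multipletests(
            table.loc[defined, "p"], method="fdr_bh"
        )[1]
    table["p_bh"] = adjusted
    return table


def _counts_matrix(tables: list[CodonCountTable]) -> np.ndarray:
    return np.array([t.counts for t in tables], dtype=float)


def relative_pair_usage(tables: list[CodonCountTable]) -> pd.DataFrame:
    """Genes x 17 relative usage count(a)/(count(a)+count(b)); NaN when 0/0."""
    pairs = enumerate_conservative_pairs()
    counts = _counts_matrix(tables)
    data = {}
    for pair in pairs:
        a = counts[:, CODON_INDEX[pair.codon_a]]
        b = counts[:, CODON_INDEX[pair.codon_b]]
        denom = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            data[pair.name] = np.where(denom > 0, a / denom, np.nan)
    return pd.DataFrame(data, index=[t.gene_id for t in tables])


def detect_preferred_codons(
    tables: list[CodonCountTable],
    fpkm: np.ndarray | pd.Series,
    r_threshold: float = 0.05,
    p_threshold: float = 0.001,
    method: str = "pearson",
) -> pd.DataFrame:
    """Screen the 17 GC-conservative pairs for expression-correlated usage.

    Per pair, the relative usage of codon_a is correlated across genes
    with log2(FPKM + 1); genes where the pair never occurs (or expression
    is missing) are dropped pairwise.  A pair with |r| > ``r_threshold``
    and p < ``p_threshold`` yields a preferred-codon call: codon_a when
    r > 0, codon_b when r < 0.  Pairs with fewer than 3 usable genes are
    reported with no call.
    """
    fpkm_arr = np.asarray(fpkm, dtype=float)
    if len(tables) != len(fpkm_arr):
        raise ValueError("fpkm vector length must match number of genes")
    with_expr = int((~np.isnan(fpkm_arr)).sum())
    if with_expr < 10:
        raise ValueError(
            f"need at least 10 genes with expression, got {with_expr}"
        )
    log_expr = np.log2(fpkm_arr + 1.0)
    defined_expr = log_expr[~np.isnan(log_expr)]
    if (defined_expr == defined_expr[0]).all():
        warnings.warn(
            "expression vector is constant; no preferred-codon call possible",
            DataQualityWarning,
            stacklevel=2,
        )
    usage = relative_pair_usage(tables)
    rows = []
    for pair in enumerate_conservative_pairs():
        r, p, n = _correlate(usage[pair.name].to_numpy(), log_expr, method)
        called = (not np.isnan(r)) and abs(r) > r_threshold and p < p_threshold
        preferred = (pair.codon_a if r > 0 else pair.codon_b) if called else None
        rows.append(
            {
                "amino_acid": pair.amino_acid,
                "codon_a": pair.codon_a,
                "codon_b": pair.codon_b,
                "pair_class": pair.pair_class,
                "r": r,
                "p": p,
                "n_genes_used": n,
                "preferred_codon": preferred,
            }
        )
    return pd.DataFrame(rows)


def subset_bias_comparison(
    metrics: pd.DataFrame, min_family_size: int = 3
) -> pd.DataFrame:
    """Rank-test each labelled gene family against the unlabelled background.

    For every distinct ``subset_label`` in ``metrics``, the family's ENC
    and GC3 distributions are compared with the unlabelled genes by a
    two-sided Mann-Whitney U test.  Families smaller than
    ``min_family_size`` (after dropping undefined ENC) are reported with
    their n and no test.
    """
    labelled = metrics["subset_label"].notna()
    background = metrics.loc[~labelled]
    rows = []
    for family, fam in sorted(metrics.loc[labelled].groupby("subset_label")):
        fam_enc = fam["enc"].dropna()
        fam_gc3 = fam["gc3"].dropna()
        row: dict[str, object] = {
            "family": family,
            "n": len(fam),
            "median_enc": float(fam_enc.median()) if len(fam_enc) else np.nan,
            "median_gc3": float(fam_gc3.median()) if len(fam_gc3) else np.nan,
            "u_enc": np.nan,
            "p_enc": np.nan,
            "u_gc3": np.nan,
            "p_gc3": np.nan,
        }
        bg_enc = background["enc"].dropna()
        bg_gc3 = background["gc3"].dropna()
        if len(fam_enc) >= min_family_size and len(bg_enc) >= min_family_size:
            u, p = stats.mannwhitneyu(fam_enc, bg_enc, alternative="two-sided")
            row["u_enc"], row["p_enc"] = float(u), float(p)
        if len(fam_gc3) >= min_family_size and len(bg_gc3) >= min_family_size:
            u, p = stats.mannwhitneyu(fam_gc3, bg_gc3, alternative="two-sided")
            row["u_gc3"], row["p_gc3"] = float(u), float(p)
        rows.append(row)
    return pd.DataFrame(rows)
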