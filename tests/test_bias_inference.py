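"""PCA of the RSCU matrix, correlation screens, GC-conservative
preferred-codon detection and subset-vs-background comparison."""

import numpy as np
import pandas as pd
import pytest

import oracles
from codonuse import (
    build_rscu_matrix,
    correlation_screen,
    count_codons,
    detect_preferred_codons,
    enumerate_conservative_pairs,
    gene_metrics,
    pca_rscu,
    relative_pair_usage,
    subset_bias_comparison,
)
from codonuse.bias_inference import _correlate
from codonuse.codon_metrics import CodonCountTable
from codonuse.genetic_code import CODON_INDEX, CODON_TO_AA, SENSE_CODONS
from codonuse.sequence_io import DataQualityWarning
from codonuse.synthetic_data import DEFAULT_PREFERRED_SET


class TestConservativePairs:
    def test_exactly_seventeen_pairs(self):
        assert len(enumerate_conservative_pairs()) == 17

    def test_matches_brute_force_scan(self):
        ours = sorted(
            tuple(sorted((p.codon_a, p.codon_b)))
            for p in enumerate_conservative_pairs()
        )
        assert ours == oracles.conservative_pairs_oracle()

    def test_pairs_are_synonymous_and_third_position_only(self):
        for pair in enumerate_conservative_pairs():
            assert CODON_TO_AA[pair.codon_a] == CODON_TO_AA[pair.codon_b]
            assert pair.codon_a[:2] == pair.codon_b[:2]
            third = {pair.codon_a[2], pair.codon_b[2]}
            assert third in ({"A", "T"}, {"C", "G"})

    def test_excludes_met_trp_and_stops(self):
        codons = {c for p in enumerate_conservative_pairs() for c in (p.codon_a, p.codon_b)}
        assert codons.isdisjoint({"ATG", "TGG", "TAA", "TAG", "TGA"})


class TestRscuMatrix:
    def test_uniform_genes_give_all_ones_and_zero_variance(self):
        rscu = pd.DataFrame(
            1.0, index=[f"g{i}" for i in range(3)], columns=list(SENSE_CODONS)
        )
        matrix = build_rscu_matrix(rscu)
        assert matrix.shape == (3, 59)
        assert (matrix == 1.0).all().all()
        _, var_frac, _ = pca_rscu(matrix)
        assert np.allclose(var_frac, 0.0)

    def test_absent_family_imputed_with_neutral_value(self):
        rscu = pd.DataFrame(
            1.0, index=[f"g{i}" for i in range(4)], columns=list(SENSE_CODONS)
        )
        rscu.loc["g0", ["CAT", "CAC"]] = np.nan  # His absent in g0
        matrix = build_rscu_matrix(rscu)
        assert matrix.loc["g0", "CAT"] == 1.0

    def test_defined_values_pass_through(self, mutation_dataset):
        records, _ = mutation_dataset
        _, rscu_matrix, _ = gene_metrics(records[:20])
        matrix = build_rscu_matrix(rscu_matrix)
        defined = rscu_matrix.loc[:, matrix.columns].notna()
        assert (
            matrix.to_numpy()[defined.to_numpy()]
            == rscu_matrix.loc[:, matrix.columns].to_numpy()[defined.to_numpy()]
        ).all()

    def test_too_few_genes_rejected(self):
        rscu = pd.DataFrame(1.0, index=["g0"], columns=list(SENSE_CODONS))
        with pytest.raises(ValueError, match="3 genes"):
            build_rscu_matrix(rscu)


class TestPcaRscu:
    def test_single_axis_variation_concentrates_variance(self):
        rscu = pd.DataFrame(
            1.0, index=[f"g{i}" for i in range(10)], columns=list(SENSE_CODONS)
        )
        rscu["GCT"] = np.linspace(0, 4, 10)
        matrix = build_rscu_matrix(rscu)
        _, var_frac, _ = pca_rscu(matrix)
        assert var_frac[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_at_most_one(self, mutation_dataset):
        records, _ = mutation_dataset
        metrics, rscu_matrix, _ = gene_metrics(records[:100])
        _, var_frac, _ = pca_rscu(build_rscu_matrix(rscu_matrix), metrics["gc3"])
        assert var_frac.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(var_frac) <= 1e-12)

    def test_pc1_sign_follows_gc3(self, mutation_dataset):
        records, _ = mutation_dataset
        metrics, rscu_matrix, _ = gene_metrics(records[:200])
        scores, _, _ = pca_rscu(build_rscu_matrix(rscu_matrix), metrics["gc3"])
        r = np.corrcoef(scores["PC1"], metrics["gc3"])[0, 1]
        assert r >= 0

    def test_scores_invariant_to_row_permutation(self, mutation_dataset):
        records, _ = mutation_dataset
        metrics, rscu_matrix, _ = gene_metrics(records[:50])
        matrix = build_rscu_matrix(rscu_matrix)
        scores, _, _ = pca_rscu(matrix, metrics["gc3"], n_components=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix))
        scores_p, _, _ = pca_rscu(
            matrix.iloc[perm], metrics["gc3"].iloc[perm], n_components=2
        )
        assert np.allclose(
            scores_p.loc[scores.index].to_numpy(), scores.to_numpy(), atol=1e-8
        )


class TestCorrelationScreen:
    def test_perfect_linear_relation(self):
        # y = x exactly: r = 1, r^2 = 1
        x = np.linspace(0, 1, 50)
        r, p, n = _correlate(x, x, "pearson")
        assert r == pytest.approx(1.0) and n == 50 and p < 1e-10

    def test_screen_reports_all_pairs_with_n(self, mutation_dataset):
        records, _ = mutation_dataset
        metrics, rscu_matrix, profiles = gene_metrics(records[:200])
        scores, _, _ = pca_rscu(build_rscu_matrix(rscu_matrix), metrics["gc3"])
        table = correlation_screen(metrics, scores, profiles)
        assert {"enc~gc3", "PC1~gc3", "PC2~log2_fpkm"} <= set(table["variable_pair"])
        assert (table["n"] > 0).all()
        assert table["p_bh"].notna().sum() == table["p"].notna().sum()

    def test_null_variables_not_systematically_significant(self):
        # independent simulated variables: calls at alpha = 0.001 stay near
        # the binomial expectation over 100 replicates
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            x, y = rng.normal(size=(2, 1000))
            _, p, _ = _correlate(x, y, "pearson")
            hits += p < 0.001
        assert hits <= 3  # Binomial(100, 0.001): P(>3) ~ 4e-6

    def test_selection_regime_enc_declines_with_expression(
        self, selection_dataset
    ):
        records, _ = selection_dataset
        metrics, rscu_matrix, _ = gene_metrics(records[:1000])
        scores, _, _ = pca_rscu(build_rscu_matrix(rscu_matrix), metrics["gc3"])
        table = correlation_screen(metrics, scores).set_index("variable_pair")
        assert table.loc["enc~log2_fpkm", "r"] < 0


def _tables_from_matrix(counts: np.ndarray) -> list[CodonCountTable]:
    return [
        CodonCountTable(f"g{i}", row.astype(np.int64))
        for i, row in enumerate(counts)
    ]


class TestDetectPreferredCodons:
    def test_planted_pairs_recovered(self, selection_dataset):
        records, truth = selection_dataset
        tables = [count_codons(r) for r in records]
        fpkm = np.array([r.fpkm for r in records])
        result = detect_preferred_codons(tables, fpkm)
        called = set(result.loc[result["preferred_codon"].notna(), "preferred_codon"])
        assert called == set(DEFAULT_PREFERRED_SET)

    def test_mutation_only_regime_yields_no_calls(self, mutation_dataset):
        records, _ = mutation_dataset
        tables = [count_codons(r) for r in records]
        fpkm = np.array([r.fpkm for r in records])
        result = detect_preferred_codons(tables, fpkm)
        assert result["preferred_codon"].notna().sum() == 0

    def test_constant_expression_warns_and_calls_nothing(self, mutation_dataset):
        records, _ = mutation_dataset
        tables = [count_codons(r) for r in records[:50]]
        with pytest.warns(DataQualityWarning, match="constant"):
            result = detect_preferred_codons(tables, np.full(50, 2.0))
        assert result["preferred_codon"].isna().all()

    def test_too_few_expressed_genes_rejected(self, mutation_dataset):
        records, _ = mutation_dataset
        tables = [count_codons(r) for r in records[:5]]
        with pytest.raises(ValueError, match="at least 10"):
            detect_preferred_codons(tables, np.ones(5))

    def test_relative_usage_scale_invariance(self):
        # multiplying both codons of a pair by the same factor leaves the
        # relative usage unchanged
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 20, size=(10, len(SENSE_CODONS)))
        usage = relative_pair_usage(_tables_from_matrix(counts))
        scaled = counts.copy()
        for pair in enumerate_conservative_pairs():
            scaled[:, CODON_INDEX[pair.codon_a]] *= 7
            scaled[:, CODON_INDEX[pair.codon_b]] *= 7
        usage_scaled = relative_pair_usage(_tables_from_matrix(scaled))
        assert np.allclose(usage.to_numpy(), usage_scaled.to_numpy())

    def test_undefined_usage_when_pair_absent(self):
        counts = np.zeros((3, len(SENSE_CODONS)), dtype=np.int64)
        counts[:, CODON_INDEX["AAA"]] = 5  # only Lys observed
        usage = relative_pair_usage(_tables_from_matrix(counts))
        assert usage.isna().all().all()


@pytest.fixture(scope="module")
def metrics(mutation_dataset):
    m, _, _ = gene_metrics(mutation_dataset[0])
    return m


class TestSubsetComparison:
    def test_null_family_rarely_significant(self, metrics):
        # family drawn from the background: p > 0.05 in >= 90% of replicates
        rng = np.random.default_rng(17)
        non_sig = 0
        for _ in range(100):
            m = metrics.copy()
            chosen = rng.choice(len(m), size=30, replace=False)
            labels = pd.Series([None] * len(m), index=m.index, dtype=object)
            labels.iloc[chosen] = "FAM"
            m["subset_label"] = labels
            table = subset_bias_comparison(m)
            non_sig += table.loc[0, "p_enc"] > 0.05
        assert non_sig >= 90

    def test_shifted_family_detected(self, metrics):
        rng = np.random.default_rng(18)
        m = metrics.copy()
        chosen = rng.choice(len(m), size=30, replace=False)
        labels = pd.Series([None] * len(m), index=m.index, dtype=object)
        labels.iloc[chosen] = "SHIFTED"
        m["subset_label"] = labels
        m.iloc[chosen, m.columns.get_loc("enc")] -= 10.0
        table = subset_bias_comparison(m)
        assert table.loc[0, "p_enc"] < 0.01

    def test_identical_family_statistic_at_null_centre(self, metrics):
        # family = exact copy of background rows: U at its null midpoint
        background = metrics.head(100).copy()
        background["subset_label"] = None
        family = metrics.head(100).copy()
        family["subset_label"] = "COPY"
        family.index = [f"{i}_copy" for i in family.index]
        m = pd.concat([background, family])
        table = subset_bias_comparison(m)
        n_bg = background["enc"].notna().sum()
        n_fam = family["enc"].notna().sum()
        assert table.loc[0, "u_enc"] == pytest.approx(n_bg * n_fam / 2)

    def test_small_family_reported_without_test(self, metrics):
        m = metrics.copy()
        labels = pd.Series([None] * len(m), index=m.index, dtype=object)
        labels.iloc[:2] = "TINY"
        m["subset_label"] = labels
        table = subset_bias_comparison(m)
        assert table.loc[0, "n"] == 2 and np.isnan(table.loc[0, "p_enc"])
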