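import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from lsmsurv import (
    ExpressionMatrix,
    SignatureGene,
    SimulationConfig,
    cluster_genes_cosine,
    dendrogram_to_newick,
    fuzzy_cluster_samples,
    gene_correlation,
    match_labels,
    simulate,
)


def expr(rows: dict) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"S{j + 1}" for j in range(df.shape[1])]
    return ExpressionMatrix(df.astype(float))


class TestGeneCorrelation:
    def test_self_correlation_is_one_and_matrix_symmetric(self):
        rng = np.random.default_rng(1)
        m = expr({g: rng.normal(8, 1, 20) for g in "ABCD"})
        res = gene_correlation(m, list("ABCD"))
        assert np.allclose(np.diag(res.r), 1.0)
        assert np.array_equal(res.r, res.r.T)
        assert np.nanmax(np.abs(res.r)) <= 1.0

    def test_negated_gene_gives_minus_one(self):
        base = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        m = expr({"A": base, "B": 16 - base})
        res = gene_correlation(m, ["A", "B"])
        assert res.r[0, 1] == pytest.approx(-1.0)

    def test_latent_factor_correlation_recovered(self):
        cfg = SimulationConfig(
            n_samples=5000,
            signature_genes=(
                SignatureGene("A", 0.0, 1),
                SignatureGene("B", 0.0, 1),
            ),
            n_background_genes=0,
            block_correlations={1: 0.46},
            seed=33,
        )
        d = simulate(cfg)
        res = gene_correlation(d.expression, ["A", "B"])
        assert 0.42 <= res.r[0, 1] <= 0.50

    def test_constant_gene_flagged_not_zero(self):
        m = expr({"A": [5, 6, 7, 8.0], "K": [3.0, 3.0, 3.0, 3.0]})
        res = gene_correlation(m, ["A", "K"])
        assert res.constant_genes == ["K"]
        assert np.isnan(res.r[0, 1])


class TestCosineClustering:
    def test_identical_vectors_merge_at_zero(self):
        m = expr({"A": [1, 2, 3.0], "B": [1, 2, 3.0], "C": [3, 1, 0.5]})
        link = cluster_genes_cosine(m, ["A", "B", "C"])
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_proportional_pair_merges_first(self):
        m = expr({"A": [1, 2, 0.5], "B": [2, 4, 1.0], "C": [4, 0.1, 8.0]})
        link = cluster_genes_cosine(m, ["A", "B", "C"])
        assert sorted(link[0, :2].astype(int)) == [0, 1]

    def test_anticorrelated_gene_joins_last(self):
        # seven mutually correlated genes plus one anti-correlated outlier
        # (centered data so cosine tracks the correlation structure)
        rng = np.random.default_rng(9)
        f = rng.standard_normal(200)
        rows = {
            f"G{i}": 0.8 * f + 0.6 * rng.standard_normal(200) for i in range(7)
        }
        rows["OUT"] = -0.8 * f + 0.6 * rng.standard_normal(200)
        m = ExpressionMatrix(pd.DataFrame(rows).T)
        panel = list(rows)
        link = cluster_genes_cosine(m, panel)
        labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
        out_label = labels[panel.index("OUT")]
        assert (labels == out_label).sum() == 1  # singleton vs the other seven

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(10)
        rows = {g: rng.uniform(1, 10, 15) for g in "ABCD"}
        m1 = expr(rows)
        rows["B"] = rows["B"] * 7.5
        m2 = expr(rows)
        l1 = cluster_genes_cosine(m1, list("ABCD"))
        l2 = cluster_genes_cosine(m2, list("ABCD"))
        assert np.allclose(l1, l2)

    def test_zero_norm_vector_errors(self):
        m = expr({"A": [1, 2.0], "Z": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero-norm.*Z"):
            cluster_genes_cosine(m, ["A", "Z"])

    def test_newick_round_trips_through_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        m = expr({g: np.random.default_rng(3).uniform(1, 9, 10) for g in "ABCDE"})
        link = cluster_genes_cosine(m, list("ABCDE"))
        nwk = dendrogram_to_newick(link, list("ABCDE"))
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("ABCDE")


class TestFuzzyClustering:
    def _two_blobs(self, n=60, delta=5.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(8, 1, size=(4, n))
        truth = (np.arange(n) < n // 2).astype(int) + 1
        X[:, truth == 2] += delta
        df = pd.DataFrame(
            X,
            index=["A", "B", "C", "D"],
            columns=[f"S{j}" for j in range(n)],
        )
        return ExpressionMatrix(df), truth

    def test_memberships_sum_to_one(self):
        m, _ = self._two_blobs()
        part = fuzzy_cluster_samples(m, ["A", "B", "C", "D"], seed=1)
        assert np.allclose(part.membership.sum(axis=1), 1.0)
        assert np.array_equal(part.hard_label, part.membership.argmax(axis=1) + 1)

    def test_separated_groups_recovered(self):
        m, truth = self._two_blobs(delta=5.0, seed=2)
        part = fuzzy_cluster_samples(m, ["A", "B", "C", "D"], seed=3)
        matched = match_labels(part.hard_label, truth)
        assert (matched == truth).mean() >= 0.99

    def test_agreement_with_kmeans_on_separated_data(self):
        m, _ = self._two_blobs(delta=4.0, seed=5)
        panel = ["A", "B", "C", "D"]
        part = fuzzy_cluster_samples(m, panel, seed=6)
        X = m.values.T
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(X) + 1
        matched = match_labels(part.hard_label, km)
        assert (matched == km).mean() >= 0.90

    def test_reproducible_from_seed(self):
        m, _ = self._two_blobs(seed=7)
        a = fuzzy_cluster_samples(m, ["A", "B", "C", "D"], seed=9)
        b = fuzzy_cluster_samples(m, ["A", "B", "C", "D"], seed=9)
        assert np.array_equal(a.membership, b.membership)

    def test_single_cluster_errors(self):
        m, _ = self._two_blobs()
        with pytest.raises(ValueError, match="at least 2 clusters"):
            fuzzy_cluster_samples(m, ["A", "B", "C", "D"], c=1)
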