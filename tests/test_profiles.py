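"""Abundance matrices, PCA, Ward clustering and habitat association."""

import numpy as np
import pandas as pd
import pytest

from plantsig import (build_abundance_matrix, habitat_association,
                      hierarchical_clusters, run_pca)
from plantsig.pool import PprPool
from plantsig.profiles import AbundanceMatrix, ClusterAssignment


def _pool_and_genes(rows):
    """rows: (strain, gene, ko, cog) tuples; all genes pooled."""
    genes = pd.DataFrame([
        {"strain_id": s, "gene_id": g, "cog_category": cog, "ko": ko,
         "pfam_ids": "", "tigrfam_ids": "", "orthogroup": ""}
        for s, g, ko, cog in rows])
    frame = genes[["strain_id", "gene_id"]].copy()
    frame["is_prb"] = True
    frame["is_gfobap"] = False
    pool = PprPool(frame=frame,
                   per_strain_count=frame.groupby("strain_id").size())
    return pool, genes


class TestAbundance:
    def test_unique_strain_ko_dropped(self):
        pool, genes = _pool_and_genes([("s1", "a", "K00001", "")])
        m = build_abundance_matrix(pool, genes, "ko")
        assert m.feature_ids == []

    def test_shared_ko_retained(self):
        pool, genes = _pool_and_genes([("s1", "a", "K00001", ""),
                                       ("s2", "b", "K00001", "")])
        m = build_abundance_matrix(pool, genes, "ko")
        assert m.counts.to_numpy().tolist() == [[1], [1]]

    def test_multi_letter_cog_increments_both(self):
        pool, genes = _pool_and_genes([("s1", "a", "", "GK"),
                                       ("s2", "b", "", "G")])
        m = build_abundance_matrix(pool, genes, "cog_category")
        assert m.counts.loc["s1", "G"] == 1
        assert m.counts.loc["s1", "K"] == 1

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        rows = [(f"s{rng.integers(6)}", f"g{i}", f"K{rng.integers(8):05d}", "")
                for i in range(400)]
        pool, genes = _pool_and_genes(rows)
        m = build_abundance_matrix(pool, genes, "ko")
        tally: dict[tuple[str, str], int] = {}
        strain_presence: dict[str, set] = {}
        for s, _, ko, _ in rows:
            tally[(s, ko)] = tally.get((s, ko), 0) + 1
            strain_presence.setdefault(ko, set()).add(s)
        kept = {k for k, v in strain_presence.items() if len(v) >= 2}
        assert set(m.feature_ids) == kept
        for (s, ko), n in tally.items():
            if ko in kept:
                assert m.counts.loc[s, ko] == n

    def test_tally_conservation_before_filter(self):
        rng = np.random.default_rng(8)
        rows = [(f"s{rng.integers(4)}", f"g{i}", "", "G") for i in range(100)]
        pool, genes = _pool_and_genes(rows)
        m = build_abundance_matrix(pool, genes, "cog_category")
        assert m.counts.to_numpy().sum() == 100


class TestPca:
    def test_collinear_points_put_all_variance_on_pc1(self):
        X = pd.DataFrame({"f1": [0.0, 1, 2, 3], "f2": [0.0, 2, 4, 6]},
                         index=list("abcd"))
        res = run_pca(X, scale=False)
        assert res.variance_pct.iloc[0] == pytest.approx(100.0)

    def test_reconstruction_identity_and_orthonormal_loadings(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.poisson(3.0, (20, 10)).astype(float))
        res = run_pca(X)
        Z = (X - X.mean()) / X.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Z.to_numpy(), atol=1e-8)
        V = res.loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-9)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.allclose(res.contributions_pct.sum(axis=0), 100.0)

    def test_eigenvalues_match_covariance_spectrum(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 10)))
        res = run_pca(X, scale=False)
        n = len(X)
        sv = res.scores.to_numpy()
        eig_pca = np.sort((sv**2).sum(axis=0) / (n - 1))[::-1]
        cov = np.cov(X.to_numpy(), rowvar=False)
        eig_cov = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(eig_pca, eig_cov, atol=1e-9)

    def test_zero_variance_columns_dropped(self):
        X = pd.DataFrame({"f1": [1.0, 2, 3], "f2": [5.0, 5, 5],
                          "f3": [0.0, 1, 0]})
        res = run_pca(X)
        assert res.dropped_features == ["f2"]
        with pytest.raises(ValueError):
            run_pca(pd.DataFrame({"a": [1.0, 1], "b": [2.0, 2]}))

    def test_row_permutation_permutes_scores(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(12, 5)),
                         index=[f"s{i:02d}" for i in range(12)])
        res = run_pca(X)
        perm = X.sample(frac=1.0, random_state=0)
        res_p = run_pca(perm)
        pd.testing.assert_frame_equal(res_p.scores.loc[X.index], res.scores)


def _blob_pca(sep=10.0, seed=0, n=8):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0], [sep, 0], [0, sep]])
    pts, labels = [], []
    for lab, c in enumerate(centers):
        pts.append(rng.normal(c, 1.0, size=(n, 2)))
        labels += [lab] * n
    X = pd.DataFrame(np.vstack(pts), index=[f"s{i:02d}" for i in range(3 * n)])
    return run_pca(X, scale=False), np.array(labels)


class TestClustering:
    def test_k1_single_cluster(self):
        pca, _ = _blob_pca()
        assert set(hierarchical_clusters(pca, 1).cluster_of) == {1}

    def test_k_equals_n_singletons(self):
        pca, _ = _blob_pca(n=4)
        asg = hierarchical_clusters(pca, 12)
        assert asg.cluster_of.nunique() == 12

    def test_recovers_separated_blobs(self):
        from sklearn.metrics import adjusted_rand_score
        pca, labels = _blob_pca(sep=10.0)
        asg = hierarchical_clusters(pca, 3)
        assert adjusted_rand_score(labels, asg.cluster_of.to_numpy()) == 1.0

    def test_clusters_numbered_by_decreasing_size(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.5, (10, 2)),
                         rng.normal(20, 0.5, (4, 2))])
        X = pd.DataFrame(pts, index=[f"s{i:02d}" for i in range(14)])
        asg = hierarchical_clusters(run_pca(X, scale=False), 2)
        sizes = asg.cluster_of.value_counts()
        assert sizes[1] == 10 and sizes[2] == 4

    def test_invalid_k_rejected(self):
        pca, _ = _blob_pca()
        with pytest.raises(ValueError):
            hierarchical_clusters(pca, 0)
        with pytest.raises(ValueError):
            hierarchical_clusters(pca, 999)

    def test_deterministic(self):
        pca, _ = _blob_pca(sep=2.0, seed=3)
        a = hierarchical_clusters(pca, 3).cluster_of
        b = hierarchical_clusters(pca, 3).cluster_of
        pd.testing.assert_series_equal(a, b)


def _strains(habitats):
    return pd.DataFrame({
        "strain_id": [f"s{i:02d}" for i in range(len(habitats))],
        "habitat": habitats,
        "genome_length_bp": 1000, "n_genes": 10})


def _assignment(clusters):
    cl = pd.Series(clusters, index=[f"s{i:02d}" for i in range(len(clusters))])
    return ClusterAssignment(cluster_of=cl, k=int(cl.max()), linkage_record=None)


class TestAssociation:
    def test_perfect_diagonal_table(self):
        strains = _strains(["plant_associated"] * 10 + ["soil_rhizosphere"] * 10)
        asg = _assignment([1] * 10 + [2] * 10)
        rep = habitat_association(asg, strains)
        assert rep.statistic == pytest.approx(20.0)
        assert rep.df == 1
        # expected counts are 5 everywhere; margins preserved
        assert np.allclose(rep.expected.to_numpy(), 5.0)

    def test_identical_rows_zero_statistic(self):
        strains = _strains(["plant_associated"] * 10 + ["soil_rhizosphere"] * 10)
        asg = _assignment([1, 2] * 10)
        rep = habitat_association(asg, strains)
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        habs = ["plant_associated", "soil_rhizosphere", "marine_mangrove"]
        for _ in range(10):
            habitats = [habs[i] for i in rng.integers(0, 3, 60)]
            clusters = list(rng.integers(1, 5, 60))
            if len(set(habitats)) < 2 or len(set(clusters)) < 2:
                continue
            strains = _strains(habitats)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = habitat_association(_assignment(clusters), strains)
            obs = rep.observed.to_numpy().astype(float)
            n = obs.sum()
            exp = np.outer(obs.sum(1), obs.sum(0)) / n
            stat = ((obs - exp) ** 2 / exp).sum()
            assert rep.statistic == pytest.approx(stat, abs=1e-9)
            assert np.allclose(rep.expected.sum(1), obs.sum(1), atol=1e-9)

    def test_degenerate_table_rejected(self):
        strains = _strains(["plant_associated"] * 6)
        with pytest.raises(ValueError, match="degenerate"):
            habitat_association(_assignment([1, 1, 1, 2, 2, 2]), strains)
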