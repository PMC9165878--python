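"""Normalization, variable genes, PCA, graph clustering, marker tests and
annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from graftsc.cluster import (ClusterParams, annotate_by_markers,
                             cluster_graph, cluster_pipeline, log_normalize,
                             rank_sum_test, run_pca, scale_matrix,
                             select_variable_genes, subcluster,
                             wilcoxon_markers)
from graftsc.simulate import ConfigurationError, generate_dataset
from tests.conftest import make_adata, mismatched_config


class TestLogNormalize:
    def test_zero_preserved_and_scale_cancels(self):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [100, 9900, 0]
        norm = log_normalize(make_adata(counts, ["A", "B", "C"]))
        x = norm.X.toarray()[0]
        assert x[2] == 0.0
        # cell total exactly 10,000 so the scale factor cancels
        assert x[0] == pytest.approx(np.log(101), abs=1e-12)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(2.0, size=(7, 11))
        counts[:, 0] += 1  # guarantee no all-zero cell
        adata = make_adata(counts, [f"G{i}" for i in range(11)])
        norm = log_normalize(adata).X.toarray()
        for i in range(7):
            total = counts[i].sum()
            for j in range(11):
                expected = np.log1p(counts[i, j] / total * 10_000)
                assert norm[i, j] == pytest.approx(expected, abs=1e-12)

    def test_monotone_within_cell(self):
        counts = np.array([[0, 1, 5, 9, 20]])
        x = log_normalize(make_adata(counts, list("ABCDE"))).X.toarray()[0]
        assert (np.diff(x) > 0).all()

    def test_all_zero_cell_names_barcode(self):
        adata = make_adata([[1, 1], [0, 0]], ["A", "B"])
        with pytest.raises(ValueError, match="cell2"):
            log_normalize(adata)


class TestVariableGenes:
    def test_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5.0, size=(200, 30))
        # same mean, 100x the variance: symmetric large-amplitude swings
        swing = np.where(rng.random(200) < 0.5, 0, 10)
        base[:, 0] = swing + rng.poisson(0.01, 200)
        adata = make_adata(base, [f"G{i}" for i in range(30)])
        top = select_variable_genes(adata, n=5)
        assert top[0] == "G0"

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(100, 10))
        counts[:, 4] = 7  # constant, zero variance
        adata = make_adata(counts, [f"G{i}" for i in range(10)])
        assert "G4" not in select_variable_genes(adata, n=9)

    def test_boosted_markers_recovered(self):
        cfg = mismatched_config(n_per_type=40, seed=17, marker_boost=50.0)
        adata, _ = generate_dataset(cfg)
        panels = cfg.resolved_marker_panels()
        markers = {g for genes in panels.values() for g in genes}
        top = set(select_variable_genes(adata, n=100))
        assert len(markers & top) >= 0.9 * len(markers)


class TestPCA:
    def test_planar_data_has_rank_two(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 8))
        data = rng.normal(size=(50, 2)) @ basis
        emb = run_pca(data - data.mean(0), n_dims=5)
        var = emb.var(axis=0)
        assert var[2:].max() < 1e-20 * var[0]

    def test_full_rank_embedding_preserves_distances(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(40, 6))
        emb = run_pca(data - data.mean(0), n_dims=6)
        np.testing.assert_allclose(pdist(emb), pdist(data), atol=1e-8)

    def test_sign_convention_is_stable(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(30, 4))
        a = run_pca(data, n_dims=3)
        b = run_pca(data.copy(), n_dims=3)
        assert (a == b).all()

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError):
            run_pca(np.zeros((5, 3)), n_dims=10)


class TestClusterGraph:
    def blobs(self, seed=0, n=100, sigma=0.1, sep=10.0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [sep, 0], [0, sep]], dtype=float)
        pts = np.vstack([c + rng.normal(scale=sigma, size=(n, 2))
                         for c in centers])
        labels = np.repeat([0, 1, 2], n)
        return pts, labels

    def test_three_blobs_recovered_exactly(self):
        pts, labels = self.blobs()
        assignment = cluster_graph(pts, seed=0)
        assert adjusted_rand_score(labels, assignment.labels) == 1.0

    def test_single_blob_is_one_cluster(self):
        # dimensionality matches the PCA embeddings the graph is built on;
        # low-dimensional geometric clouds fragment under any modularity
        # clustering, a 10-d isotropic Gaussian does not
        rng = np.random.default_rng(6)
        pts = rng.normal(scale=0.1, size=(150, 10))
        assignment = cluster_graph(pts, resolution=0.5, seed=0)
        assert len(assignment.clusters) == 1

    def test_deterministic_for_fixed_seed(self):
        pts, _ = self.blobs(seed=2)
        a = cluster_graph(pts, seed=42)
        b = cluster_graph(pts, seed=42)
        assert (a.labels == b.labels).all()

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            cluster_graph(np.zeros((10, 2)), k_neighbors=10)


class TestWilcoxonMarkers:
    def two_group_data(self, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2.0, size=(60, 20)) + 1
        counts[:30, 0] *= 50  # boosted marker in cluster 0
        adata = make_adata(counts, [f"G{i}" for i in range(20)])
        labels = pd.Series([0] * 30 + [1] * 30, index=adata.obs_names)
        return adata, labels

    def test_identical_gene_excluded_by_logfc(self):
        adata, labels = self.two_group_data()
        norm = log_normalize(adata)
        table = wilcoxon_markers(norm, labels)
        lfc_zero = [f"G{i}" for i in range(1, 20)]
        strong = table[table["gene"] == "G0"]
        assert len(strong) >= 1
        assert strong["adjusted_p"].min() < 0.05
        # background genes share one distribution: |logFC| < 0.25 excludes
        assert not set(table["gene"]) & set(lfc_zero) or \
            table[table["gene"].isin(lfc_zero)]["log_fold_change"].abs().min() >= 0.25

    def test_small_sample_p_matches_enumeration(self):
        import itertools
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=4), rng.normal(size=5)
        p = rank_sum_test(x, y)
        allv = np.concatenate([x, y])

        def ustat(xs, ys):
            return sum((xi > yj) + 0.5 * (xi == yj)
                       for xi in xs for yj in ys)

        u_obs = ustat(x, y)
        us = np.array([ustat(allv[list(c)],
                             np.delete(allv, list(c)))
                       for c in itertools.combinations(range(9), 4)])
        p_exact = min(1.0, 2 * min((us >= u_obs).mean(), (us <= u_obs).mean()))
        assert p == pytest.approx(p_exact, abs=1e-10)

    def test_relabeling_permutes_table(self):
        adata, labels = self.two_group_data(seed=9)
        norm = log_normalize(adata)
        t1 = wilcoxon_markers(norm, labels)
        swapped = labels.map({0: 1, 1: 0})
        t2 = wilcoxon_markers(norm, swapped)
        for cl in (0, 1):
            a = t1[t1["cluster"] == cl].drop(columns="cluster")
            b = t2[t2["cluster"] == 1 - cl].drop(columns="cluster")
            pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                          b.reset_index(drop=True))

    def test_single_cluster_rejected(self):
        adata, _ = self.two_group_data()
        labels = pd.Series([0] * 60, index=adata.obs_names)
        with pytest.raises(ValueError):
            wilcoxon_markers(log_normalize(adata), labels)


class TestAnnotate:
    def test_dcn_only_cluster_is_fibroblast(self):
        genes = ["DCN", "PECAM1", "CDH5", "CD3D"]
        counts = np.array([[40, 0, 0, 0]] * 5 + [[0, 30, 30, 0]] * 5)
        adata = make_adata(counts, genes)
        labels = pd.Series([0] * 5 + [1] * 5, index=adata.obs_names)
        catalog = {"FB": ["DCN"], "EC": ["PECAM1", "CDH5"], "TC": ["CD3D"]}
        ann = annotate_by_markers(log_normalize(adata), labels, catalog)
        assert ann.loc[0, "cell_type"] == "FB"
        assert ann.loc[1, "cell_type"] == "EC"

    def test_tie_breaks_lexicographically_and_is_recorded(self):
        counts = np.array([[10, 10]] * 4)
        adata = make_adata(counts, ["AAA", "BBB"])
        labels = pd.Series([0] * 4, index=adata.obs_names)
        ann = annotate_by_markers(log_normalize(adata), labels,
                                  {"beta": ["BBB"], "alpha": ["AAA"]})
        assert ann.loc[0, "cell_type"] == "alpha"
        assert bool(ann.loc[0, "tie"])

    def test_all_genes_absent_raises(self, clean_sim_dataset):
        _, adata, _ = clean_sim_dataset
        with pytest.raises(ConfigurationError):
            annotate_by_markers(log_normalize(adata),
                                pd.Series(0, index=adata.obs_names),
                                {"X": ["NOPE1"], "Y": ["NOPE2"]})

    def test_simulated_types_annotated_perfectly(self, clean_sim_dataset):
        cfg, adata, truth = clean_sim_dataset
        assignment, norm, _ = cluster_pipeline(adata, ClusterParams(seed=1))
        catalog = cfg.resolved_marker_panels()
        ann = annotate_by_markers(norm, assignment.labels, catalog)
        # cluster-level accuracy: every cluster is labeled with the majority
        # truth type of its member cells, and every simulated type appears
        df = pd.DataFrame({"cluster": assignment.labels.to_numpy(),
                           "truth": truth["cell_type"].to_numpy()})
        majority = df.groupby("cluster")["truth"].agg(
            lambda s: s.value_counts().index[0])
        assert (ann["cell_type"] == majority).all()
        assert set(ann["cell_type"]) == set(cfg.cell_types())
        # per-cell agreement is bounded by graph-clustering noise only
        cell_types = assignment.labels.map(ann["cell_type"])
        agree = (cell_types.to_numpy() == truth["cell_type"].to_numpy()).mean()
        assert agree >= 0.95


class TestSubcluster:
    def test_barcodes_conserved_and_namespaced(self, clean_sim_dataset):
        _, adata, truth = clean_sim_dataset
        fb = list(truth.index[truth["cell_type"] == "FB"])
        labels = subcluster(adata, fb, ClusterParams(seed=0, k_neighbors=15),
                            parent_label="FB")
        assert set(labels.index) == set(fb)
        assert labels.str.startswith("FB").all()

    def test_homogeneous_pool_is_single_subcluster(self, clean_sim_dataset):
        _, adata, truth = clean_sim_dataset
        pt = list(truth.index[(truth["cell_type"] == "PT")
                              & (truth["sample_id"] == "HK")])
        labels = subcluster(adata, pt, ClusterParams(seed=0, k_neighbors=15),
                            parent_label="PT")
        assert labels.nunique() == 1

    def test_too_small_subset_raises(self, clean_sim_dataset):
        _, adata, _ = clean_sim_dataset
        with pytest.raises(ValueError):
            subcluster(adata, list(adata.obs_names[:5]),
                       ClusterParams(k_neighbors=20))
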