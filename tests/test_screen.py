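"""QC filtering, hashtag demultiplexing, normalisation and the candidate screen."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from arcpipe import synthetic
from arcpipe.errors import ConfigurationError, DegenerateInputError, EmptyResultError
from arcpipe.screen import (
    ClusterProfile,
    QCThresholds,
    ScreenCriteria,
    classify_clusters,
    cluster_profiles,
    demux_hashtags,
    log_normalize,
    profiles_frame,
    qc_filter,
    run_screen,
    screen_candidates,
)

TOY_THRESHOLDS = QCThresholds(min_features=2, max_features=5, max_counts=30,
                              max_mito_fraction=0.2, min_cells_per_gene=1)


def toy_matrix():
    """Six cells, one QC violation each for four cells, two clean.

    Genes: g1..g4 plus mt-x. Rules (strict bounds as in the thresholds):
    features must lie in (2, 5), totals <= 30, mito fraction <= 0.2.
    """
    genes = ["g1", "g2", "g3", "g4", "mt-x"]
    X = np.array(
        [
            [5, 4, 3, 0, 1],    # clean: 4 features, total 13, mito 1/13
            [3, 0, 0, 0, 0],    # too few features (1 <= 2)
            [6, 6, 6, 6, 6],    # too many features (5 >= 5); total/mito at bound
            [20, 10, 5, 0, 1],  # total 36 > 30
            [5, 5, 0, 0, 5],    # mito 5/15 > 0.2
            [4, 3, 2, 0, 1],    # clean: 4 features, total 10, mito 0.1
        ],
        dtype=np.int32,
    )
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(6)]),
        var=pd.DataFrame(index=genes),
    )


class TestQCFilter:
    def test_toy_matrix_survivors_and_per_rule_counts(self):
        filtered, report = qc_filter(toy_matrix(), TOY_THRESHOLDS)
        assert list(filtered.obs_names) == ["c0", "c5"]
        assert report.removed_low_features == 1
        assert report.removed_high_features == 1
        assert report.removed_high_counts == 1
        assert report.removed_high_mito == 1
        assert report.n_cells_out == 2

    def test_vacuous_thresholds_keep_everything(self):
        adata = toy_matrix()
        loose = QCThresholds(min_features=0, max_features=10**9,
                             max_counts=10**9, max_mito_fraction=1.0,
                             min_cells_per_gene=0)
        filtered, _ = qc_filter(adata, loose)
        assert filtered.shape == adata.shape
        assert np.array_equal(np.asarray(filtered.X), np.asarray(adata.X))

    def test_gene_detection_boundary_is_strict(self):
        # "fewer than three cells" is strict: detected in exactly 3 -> kept
        X = np.zeros((4, 2), dtype=np.int32)
        X[:, 0] = [1, 1, 1, 0]  # detected in 3 cells -> kept
        X[:, 1] = [1, 1, 0, 0]  # detected in 2 cells -> dropped
        X = np.hstack([X, np.full((4, 3), 5, dtype=np.int32)])  # keep cells alive
        adata = ad.AnnData(X=X, var=pd.DataFrame(index=["a", "b", "f1", "f2", "f3"]))
        thr = QCThresholds(min_features=0, max_features=100, max_counts=100,
                           max_mito_fraction=1.0, min_cells_per_gene=3)
        filtered, _ = qc_filter(adata, thr)
        assert "a" in filtered.var_names and "b" not in filtered.var_names

    def test_idempotence(self):
        once, _ = qc_filter(toy_matrix(), TOY_THRESHOLDS)
        twice, report = qc_filter(once, TOY_THRESHOLDS)
        assert twice.shape == once.shape
        assert report.n_cells_in == report.n_cells_out

    def test_all_cells_removed_is_explicit(self):
        thr = QCThresholds(min_features=100, max_features=200, max_counts=10,
                           max_mito_fraction=0.0, min_cells_per_gene=1)
        with pytest.raises(EmptyResultError):
            qc_filter(toy_matrix(), thr)


class TestDemuxHashtags:
    def test_perfectly_separated_populations_all_singlets(self):
        n = 60
        counts = np.zeros((2 * n, 2), dtype=int)
        counts[:n, 0] = 500
        counts[n:, 1] = 500
        hto = pd.DataFrame(counts, columns=["HTO1", "HTO2"])
        result = demux_hashtags(hto, positive_quantile=0.8)
        assert (result.calls[:n] == "HTO1").all()
        assert (result.calls[n:] == "HTO2").all()

    def test_planted_doublet_recall_and_singlet_identity(self):
        recalls, mislabels = [], []
        for seed in range(5):
            cfg = synthetic.CountsGenConfig(
                n_cells={"Other": 2000}, n_filler_genes=5,
                doublet_rate=0.10, negative_rate=0.0, seed=seed,
            )
            adata, truth = synthetic.simulate_counts(cfg)
            res = demux_hashtags(adata.obsm["hto"], positive_quantile=0.8)
            is_dbl = truth["is_doublet"].to_numpy()
            recalls.append((res.calls[is_dbl] == "doublet").mean())
            singlet_called = (~is_dbl) & res.singlet_mask
            mislabels.append(
                (res.calls[singlet_called] != truth["hashtag"][singlet_called]).mean()
            )
        assert np.mean(recalls) >= 0.8
        assert np.mean(mislabels) <= 0.05

    def test_determinism(self, small_counts):
        adata, _ = small_counts
        r1 = demux_hashtags(adata.obsm["hto"])
        r2 = demux_hashtags(adata.obsm["hto"])
        pd.testing.assert_series_equal(r1.calls, r2.calls)

    def test_single_hashtag_rejected(self):
        with pytest.raises(ConfigurationError):
            demux_hashtags(pd.DataFrame({"HTO1": [1, 2, 3]}))


class TestLogNormalize:
    def test_stated_formula_arithmetic(self):
        X = np.zeros((1, 3))
        X[0] = [1, 0, 9999]
        out = log_normalize(X)  # cell total 10,000
        assert out[0, 0] == pytest.approx(np.log(2.0))
        assert out[0, 1] == 0.0

    def test_rowwise_identity_sums_to_scale_factor(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 50, size=(20, 30)).astype(float)
        X[:, 0] += 1  # no zero-total cells
        out = log_normalize(X)
        assert np.allclose((np.exp(out) - 1).sum(axis=1), 1e4, rtol=1e-10)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(DegenerateInputError):
            log_normalize(np.zeros((2, 3)))


class TestClusterProfiles:
    def test_single_cluster_profile_is_column_mean(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(15, 4))
        (profile,) = cluster_profiles(mat, ["a", "b", "c", "d"], ["k"] * 15)
        assert np.allclose(profile.mean_expression, mat.mean(axis=0))
        assert profile.n_cells == 15

    def test_disjoint_constant_clusters(self):
        mat = np.vstack([np.full((5, 2), 2.0), np.full((3, 2), 7.0)])
        labels = ["x"] * 5 + ["y"] * 3
        profs = {p.cluster: p for p in cluster_profiles(mat, ["g1", "g2"], labels)}
        assert profs["x"].mean_expression["g1"] == 2.0
        assert profs["y"].mean_expression["g2"] == 7.0

    def test_random_labels_match_brute_force(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(50, 6))
        labels = rng.choice(["p", "q", "r"], size=50)
        for p in cluster_profiles(mat, [f"g{i}" for i in range(6)], labels):
            brute = mat[labels == p.cluster].mean(axis=0)
            assert np.allclose(p.mean_expression.to_numpy(), brute)

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            cluster_profiles(np.zeros((4, 2)), ["g1", "g2"], ["a", "b"])


def profile(cluster, n_cells=10, **means):
    base = {g: 0.0 for g in ("Slc17a6", "Slc32a1", "Gad1", "Gad2", "Lepr",
                             "Agrp", "Npy", "Pomc", "Nr5a1")}
    base.update(means)
    return ClusterProfile(cluster=cluster, mean_expression=pd.Series(base),
                          n_cells=n_cells)


class TestClassifyAndScreen:
    def test_pure_marker_profiles_classified(self):
        classes = classify_clusters([profile("e", Slc17a6=1.0),
                                     profile("i", Gad1=1.0),
                                     profile("amb", Slc17a6=1.0, Gad1=1.0)])
        assert classes["e"] == "excitatory"
        assert classes["i"] == "inhibitory"
        assert classes["amb"] == "ambiguous"

    def test_missing_classifier_gene_rejected(self):
        p = ClusterProfile("x", pd.Series({"Slc17a6": 1.0}), 5)
        with pytest.raises(ConfigurationError):
            classify_clusters([p])

    def test_planted_populations_classified_correctly(self, small_counts):
        adata, _ = small_counts
        result = run_screen(adata)
        classes = result.report.table["neurotransmitter_class"]
        assert classes["Agrp_Npy"] == "inhibitory"
        assert classes["Bnc2_Lepr"] == "inhibitory"
        assert classes["Nr5a1"] == "excitatory"
        assert classes["Pomc"] == "excitatory"

    def test_nr5a1_positive_cluster_excluded_by_arc_origin(self):
        report = screen_candidates(
            [profile("vmh", Lepr=1.0, Nr5a1=2.0, Slc17a6=1.0)]
        )
        row = report.table.loc["vmh"]
        assert row["lepr_positive"] and not row["arc_origin"]
        assert not row["candidate"]

    def test_no_lepr_anywhere_means_no_candidates(self):
        report = screen_candidates([profile("a", Gad1=1.0), profile("b")])
        assert report.candidates == []

    def test_verdict_sorted_by_lepr_mean(self):
        report = screen_candidates([profile("lo", Lepr=0.2),
                                    profile("hi", Lepr=2.0, Gad1=1.0)])
        assert list(report.table.index) == ["hi", "lo"]

    def test_missing_screen_gene_rejected(self):
        p = ClusterProfile(
            "x",
            pd.Series({g: 0.0 for g in ("Slc17a6", "Slc32a1", "Gad1", "Gad2")}),
            3,
        )
        with pytest.raises(ConfigurationError):
            screen_candidates([p])

    def test_planted_candidate_recovered(self, small_counts):
        adata, _ = small_counts
        result = run_screen(adata)
        assert result.report.candidates == ["Bnc2_Lepr"]

    def test_cell_before_gene_filter_order_matters(self):
        # a gene detected in exactly min_cells cells, one of which fails
        # cell QC: the implemented cell-then-gene order drops it, the
        # swapped order would keep it
        X = np.array(
            [
                [1, 5, 5, 0],
                [1, 5, 5, 0],
                [1, 0, 0, 40],  # fails the total-counts rule
                [0, 5, 5, 0],
            ],
            dtype=np.int32,
        )
        adata = ad.AnnData(X=X, var=pd.DataFrame(index=["g", "f1", "f2", "f3"]))
        thr = QCThresholds(min_features=0, max_features=10, max_counts=30,
                           max_mito_fraction=1.0, min_cells_per_gene=3)
        filtered, _ = qc_filter(adata, thr)
        assert "g" not in filtered.var_names  # detected in 2 retained cells
        detected_before_cell_qc = int((np.asarray(adata.X)[:, 0] > 0).sum())
        assert detected_before_cell_qc == 3  # swapped order would keep it

    def test_skipping_demux_pollutes_cluster_profiles(self, small_counts):
        # keeping doublet barcodes inflates marker cross-contamination
        adata, truth = small_counts
        norm_all = log_normalize(adata)
        labels = truth["primary_population"].to_numpy()
        all_profiles = {p.cluster: p for p in cluster_profiles(
            norm_all, adata.var_names, labels)}
        singlet = ~truth["is_doublet"].to_numpy()
        clean = {p.cluster: p for p in cluster_profiles(
            norm_all[singlet], adata.var_names, labels[singlet])}
        # Agrp/Npy/Pomc contamination of marker-free clusters arises only
        # through retained doublets
        def contamination(profiles):
            return sum(
                profiles[c].mean_expression[g]
                for c in ("Bnc2_Lepr", "Other", "Nr5a1")
                for g in ("Agrp", "Npy", "Pomc")
            )

        assert contamination(all_profiles) > contamination(clean)
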