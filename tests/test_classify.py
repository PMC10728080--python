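import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import panemt
from panemt.classify import SUBTYPE_NAMES, MissingGeneWarning, TieWarning


def toy_model(n_genes=2):
    genes = [f"g{i}" for i in range(n_genes)]
    centroids = pd.DataFrame(
        np.zeros((4, n_genes)), index=list(SUBTYPE_NAMES), columns=genes
    )
    centroids.iloc[1] = 1.0
    centroids.iloc[2] = 2.0
    centroids.iloc[3] = 3.0
    return panemt.ReferenceModel(
        genes=genes,
        centroids=centroids,
        gene_means=pd.Series(0.0, index=genes),
        gene_sds=pd.Series(1.0, index=genes),
    )


class TestReferenceScale:
    def test_value_minus_mean_over_sd(self):
        model = toy_model()
        model.gene_means[:] = 2.0
        model.gene_sds[:] = 2.0
        expr = panemt.ExpressionMatrix(
            pd.DataFrame({"s": [4.0, 2.0]}, index=model.genes)
        )
        scaled = panemt.reference_scale(expr, model)
        assert scaled.loc["g0", "s"] == pytest.approx(1.0)
        assert scaled.loc["g1", "s"] == pytest.approx(0.0)

    def test_sample_at_reference_mean_is_all_zero(self):
        model = toy_model(5)
        model.gene_means[:] = 3.0
        expr = panemt.ExpressionMatrix(
            pd.DataFrame({"s": [3.0] * 5}, index=model.genes)
        )
        assert (panemt.reference_scale(expr, model) == 0).all().all()

    def test_coverage_below_threshold_raises(self):
        genes = [f"g{i}" for i in range(35)]
        model = panemt.ReferenceModel(
            genes=genes,
            centroids=pd.DataFrame(np.zeros((4, 35)), index=list(SUBTYPE_NAMES),
                                   columns=genes),
            gene_means=pd.Series(0.0, index=genes),
            gene_sds=pd.Series(1.0, index=genes),
        )
        expr = panemt.ExpressionMatrix(
            pd.DataFrame({"s": np.zeros(27)}, index=genes[:27])  # 77% coverage
        )
        with pytest.raises(ValueError, match="signature genes present"):
            panemt.reference_scale(expr, model)

    def test_missing_genes_warn(self):
        model = toy_model(10)
        expr = panemt.ExpressionMatrix(
            pd.DataFrame({"s": np.zeros(9)}, index=model.genes[:9])
        )
        with pytest.warns(MissingGeneWarning):
            scaled = panemt.reference_scale(expr, model)
        assert scaled.shape[0] == 9


class TestCentroidAssignment:
    def test_two_gene_hand_example(self):
        """Centroids (0,0) and (1,1); sample (0.9, 1.2) sits 0.2236 from the second."""
        genes = ["g0", "g1"]
        centroids = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]],
                                 index=["EMTlow", "EMTmid"], columns=genes)
        model = panemt.ReferenceModel(
            genes=genes, centroids=centroids,
            gene_means=pd.Series(0.0, index=genes),
            gene_sds=pd.Series(1.0, index=genes),
            subtype_names=["EMTlow", "EMTmid"],
        )
        scaled = pd.DataFrame({"s": [0.9, 1.2]}, index=genes)
        out = panemt.assign_by_centroid(scaled, model)
        assert out.loc[0, "d_EMTlow"] == pytest.approx(1.5, abs=1e-4)
        assert out.loc[0, "d_EMTmid"] == pytest.approx(0.2236, abs=1e-4)
        assert out.loc[0, "subtype"] == "EMTmid"
        assert out.loc[0, "margin"] == pytest.approx(1.5 - 0.2236, abs=1e-4)

    def test_sample_at_centroid_has_zero_distance(self):
        model = toy_model(3)
        scaled = pd.DataFrame({"s": model.centroids.loc["EMThigh-NOS"]})
        out = panemt.assign_by_centroid(scaled, model)
        assert out.loc[0, "subtype"] == "EMThigh-NOS"
        assert out.loc[0, "d_EMThigh-NOS"] == 0.0

    def test_tie_warns_and_keeps_fixed_order(self):
        model = toy_model(1)
        # centroids at 0,1,2,3 on one gene; 0.5 is equidistant from the first two
        scaled = pd.DataFrame({"s": [0.5]}, index=model.genes)
        with pytest.warns(TieWarning):
            out = panemt.assign_by_centroid(scaled, model)
        assert out.loc[0, "subtype"] == "EMTlow"

    def test_missing_gene_distance_rescaled(self):
        model = toy_model(4)
        full = pd.DataFrame({"s": [0.0, 0.0, 0.0, 0.0]}, index=model.genes)
        partial = full.iloc[:2]
        d_full = panemt.assign_by_centroid(full, model)
        d_part = panemt.assign_by_centroid(partial, model)
        # distance over 2 of 4 genes to the all-ones centroid: sqrt(2)*sqrt(4/2)=2
        assert d_part.loc[0, "d_EMTmid"] == pytest.approx(2.0)
        assert d_full.loc[0, "d_EMTmid"] == pytest.approx(2.0)
        assert d_part.loc[0, "n_genes_used"] == 2

    def test_distances_satisfy_triangle_inequality(self):
        rng = np.random.default_rng(0)
        model = toy_model(6)
        scaled = pd.DataFrame(rng.normal(size=(6, 3)), index=model.genes,
                              columns=["a", "b", "c"])
        out = panemt.assign_by_centroid(scaled, model).set_index("sample_id")
        dcols = [f"d_{n}" for n in SUBTYPE_NAMES]
        for s in ["a", "b", "c"]:
            d = out.loc[s, dcols].to_numpy(dtype=float)
            # distances from one sample to the 4 centroids vs centroid spacing
            for i in range(4):
                for j in range(4):
                    cij = np.linalg.norm(
                        model.centroids.iloc[i] - model.centroids.iloc[j]
                    )
                    assert d[i] <= d[j] + cij + 1e-9


class TestKnnAssignment:
    def _reference(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(4)]
        ref = pd.DataFrame(rng.normal(size=(4, 12)), index=genes,
                           columns=[f"r{i}" for i in range(12)])
        labels = pd.Series(["A"] * 7 + ["B"] * 5, index=ref.columns)
        return ref, labels

    def test_query_equal_to_reference_sample_k1(self):
        ref, labels = self._reference()
        query = ref[["r9"]].rename(columns={"r9": "q"})
        out = panemt.assign_by_knn(query, ref, labels, k=1)
        assert out.loc[0, "subtype"] == "B"

    def test_k_equal_n_gives_global_majority(self):
        ref, labels = self._reference()
        query = pd.DataFrame({"q": [0.0, 0.0, 0.0, 0.0]}, index=ref.index)
        out = panemt.assign_by_knn(query, ref, labels, k=12)
        assert out.loc[0, "subtype"] == "A"

    def test_invalid_k_raises(self):
        ref, labels = self._reference()
        query = ref[["r0"]]
        with pytest.raises(ValueError):
            panemt.assign_by_knn(query, ref, labels, k=0)
        with pytest.raises(ValueError):
            panemt.assign_by_knn(query, ref, labels, k=13)


class TestReferenceModelLifecycle:
    def test_round_trip_serialization(self, tmp_path, planted_pipeline):
        model = self._built(planted_pipeline)
        model.save(tmp_path / "model")
        back = panemt.ReferenceModel.load(tmp_path / "model")
        assert back.genes == model.genes
        assert back.subtype_names == model.subtype_names
        pd.testing.assert_frame_equal(back.centroids, model.centroids)
        pd.testing.assert_series_equal(back.gene_means, model.gene_means,
                                       check_names=False)

    @staticmethod
    def _built(planted_pipeline):
        cohort = planted_pipeline["cohort"]
        akt_block = cohort.signature["EMTCG_AKT_block"]
        akt_score = cohort.expression.data.loc[akt_block].mean(axis=0)
        return panemt.ReferenceModel.from_clustering(
            cohort.expression,
            planted_pipeline["model"],
            cohort.signature["EMTCG"],
            emt_scores=planted_pipeline["scores"],
            secondary_scores=akt_score,
            provenance={"cohort": "synthetic"},
        )

    def test_subtype_naming_tracks_planted_truth(self, planted_pipeline):
        """Score ranking + AKT-block activity maps clusters onto the right names."""
        model = self._built(planted_pipeline)
        cohort = planted_pipeline["cohort"]
        name_map = model.cluster_to_subtype(
            planted_pipeline["model"],
            planted_pipeline["scores"],
            cohort.expression.data.loc[cohort.signature["EMTCG_AKT_block"]].mean(axis=0),
        )
        named = planted_pipeline["model"].labels.map(name_map)
        truth = cohort.true_labels[named.index]
        agreement = (named == truth).mean()
        assert agreement >= 0.95

    def test_self_classification_reproduces_consensus_labels(self, planted_pipeline):
        model = self._built(planted_pipeline)
        cohort = planted_pipeline["cohort"]
        scaled = panemt.reference_scale(cohort.expression, model)
        out = panemt.assign_by_centroid(scaled, model).set_index("sample_id")
        truth = cohort.true_labels[out.index]
        assert (out["subtype"] == truth).mean() >= 0.95

    def test_heldout_knn_recovers_subtypes(self, planted_pipeline):
        model = self._built(planted_pipeline)
        cohort = planted_pipeline["cohort"]
        scaled = panemt.reference_scale(cohort.expression, model)
        samples = scaled.columns
        train, test = samples[::2], samples[1::2]
        named = cohort.true_labels
        out = panemt.assign_by_knn(scaled[test], scaled[train], named[train], k=5)
        acc = (out.set_index("sample_id")["subtype"] == named[test]).mean()
        assert acc >= 0.95

    def test_classification_deterministic_and_order_invariant(self, planted_pipeline):
        model = self._built(planted_pipeline)
        cohort = planted_pipeline["cohort"]
        scaled = panemt.reference_scale(cohort.expression, model)
        a = panemt.assign_by_centroid(scaled, model).set_index("sample_id")
        b = panemt.assign_by_centroid(scaled.iloc[:, ::-1], model).set_index("sample_id")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())
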