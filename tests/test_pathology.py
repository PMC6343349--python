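"""Outcome derivation, the AD-likelihood lookup and the centered PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from dsindex.pathology import (BRAAK_STAGES, CERAD_SCORES,
                               default_niaaa_matrix, derive_outcomes,
                               niaaa_likelihood, pc_dementia_auc, run_pca)


def _panel(**overrides):
    base = {"amyloid_load": 0.1, "tangle_count": 2.0, "caa_percent": 10.0,
            "macroinfarct_count": 0.0, "cortical_macroinfarct_count": 0.0,
            "wm_macroinfarct_count": 0.0, "microinfarct_count": 0.0,
            "alpha_synuclein": "absent", "hs_severity": "no_minor",
            "tdp43_positive": 0.0, "braak_stage": "II", "cerad_score": "none"}
    base.update(overrides)
    return pd.DataFrame([base])


class TestDeriveOutcomes:
    def test_strictly_positive_rule_boundary(self):
        absent = derive_outcomes(_panel(amyloid_load=0.0)).iloc[0]
        present = derive_outcomes(_panel(amyloid_load=1e-9)).iloc[0]
        assert absent["amyloid"] == 0.0
        assert present["amyloid"] == 1.0

    def test_macroinfarct_count_rule(self):
        row = derive_outcomes(_panel(macroinfarct_count=2.0)).iloc[0]
        assert row["macroinfarcts"] == 1.0

    @pytest.mark.parametrize("stage,expected", [
        ("absent", 0.0), ("brainstem", 1.0), ("limbic", 1.0),
        ("diffuse_neocortical", 1.0)])
    def test_alpha_synuclein_staging(self, stage, expected):
        row = derive_outcomes(_panel(alpha_synuclein=stage)).iloc[0]
        assert row["alpha_synuclein"] == expected

    def test_hs_and_tdp43(self):
        row = derive_outcomes(_panel(hs_severity="severe_marked_total",
                                     tdp43_positive=1.0)).iloc[0]
        assert row["hs"] == 1.0 and row["tdp43"] == 1.0

    def test_missing_input_yields_missing_single_outcome(self):
        row = derive_outcomes(_panel(amyloid_load=np.nan)).iloc[0]
        assert np.isnan(row["amyloid"])
        assert row["tangles"] == 1.0  # other outcomes unaffected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            derive_outcomes(_panel(microinfarct_count=-1.0))

    def test_deterministic_and_idempotent(self):
        p = _panel(macroinfarct_count=1.0, braak_stage="V",
                   cerad_score="frequent")
        out1 = derive_outcomes(p)
        out2 = derive_outcomes(p)
        pd.testing.assert_frame_equal(out1, out2)


class TestNiaaaLikelihood:
    def test_no_pathology_corner_is_low(self):
        assert niaaa_likelihood("0", "none") == "low"

    def test_maximal_corner_is_high(self):
        assert niaaa_likelihood("VI", "frequent") == "high"

    def test_mid_braak_moderate_is_intermediate(self):
        assert niaaa_likelihood("III", "moderate") == "intermediate"

    def test_low_braak_moderate_is_low(self):
        # early tangle stage caps the likelihood regardless of plaques
        assert niaaa_likelihood("II", "moderate") == "low"

    def test_high_braak_sparse_is_intermediate(self):
        assert niaaa_likelihood("V", "sparse") == "intermediate"

    def test_matrix_covers_all_combinations(self):
        m = default_niaaa_matrix()
        assert set(m) == {(b, c) for b in BRAAK_STAGES for c in CERAD_SCORES}
        assert set(m.values()) == {"low", "intermediate", "high"}

    def test_custom_mapping_overrides(self):
        m = {(b, c): "high" for b in BRAAK_STAGES for c in CERAD_SCORES}
        assert niaaa_likelihood("0", "none", m) == "high"

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            niaaa_likelihood("VII", "none")
        with pytest.raises(ValueError):
            niaaa_likelihood("0", "lots")

    def test_neuropath_ad_follows_matrix(self):
        present = derive_outcomes(_panel(braak_stage="IV",
                                         cerad_score="frequent")).iloc[0]
        absent = derive_outcomes(_panel(braak_stage="I",
                                        cerad_score="sparse")).iloc[0]
        assert present["neuropath_ad"] == 1.0
        assert absent["neuropath_ad"] == 0.0


class TestRunPca:
    def _toy(self):
        return pd.DataFrame([[2, 0, 1], [4, 1, 1], [6, 0, 3],
                             [8, 1, 5], [10, 0, 5]],
                            columns=["a", "b", "c"], dtype=float)

    def test_single_varying_column_concentrates_pc1(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        res = run_pca(X)
        assert abs(res.loadings.loc["PC1", "a"]) == pytest.approx(1.0)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_constant_column_changes_nothing(self):
        base = run_pca(self._toy())
        extended = run_pca(self._toy().assign(const=7.0))
        # the constant column adds one zero-variance component at the end
        np.testing.assert_allclose(extended.scores.to_numpy()[:, :3],
                                   base.scores.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(extended.variance_explained[:3],
                                   base.variance_explained, atol=1e-10)

    def test_toy_matrix_matches_eigendecomposition_oracle(self):
        X = self._toy().to_numpy()
        res = run_pca(self._toy())
        # independent route: eigendecomposition of the covariance matrix
        C = np.cov((X - X.mean(0)).T, ddof=1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        np.testing.assert_allclose(res.variance_explained, w / w.sum(),
                                   atol=1e-10)
        scores_oracle = (X - X.mean(0)) @ V
        for i in range(3):
            got = res.scores.iloc[:, i].to_numpy()
            want = scores_oracle[:, i]
            # orientation is a convention; compare up to sign
            assert (np.allclose(got, want, atol=1e-8) or
                    np.allclose(got, -want, atol=1e-8))

    def test_matches_sklearn_centered_unscaled(self):
        res = run_pca(self._toy())
        sk = SkPCA().fit(self._toy().to_numpy())
        np.testing.assert_allclose(res.variance_explained,
                                   sk.explained_variance_ratio_, atol=1e-10)

    def test_reconstruction_identity(self):
        res = run_pca(self._toy())
        X = self._toy().to_numpy()
        centered = X - X.mean(0)
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.loadings.to_numpy(), centered,
            atol=1e-8)

    def test_variance_explained_sums_to_one_and_decreases(self):
        res = run_pca(self._toy())
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_scores_are_column_centered(self):
        res = run_pca(self._toy())
        np.testing.assert_allclose(res.scores.mean(0), 0.0, atol=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        res = run_pca(self._toy())
        for comp in res.loadings.index:
            row = res.loadings.loc[comp].to_numpy()
            assert row[np.argmax(np.abs(row))] > 0

    def test_incomplete_rows_dropped_and_counted(self):
        X = self._toy()
        X.loc[1, "b"] = np.nan
        res = run_pca(X)
        assert res.n_dropped == 1
        assert len(res.index) == 4

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            run_pca(pd.DataFrame({"a": [1.0]}))


class TestPcDementiaAuc:
    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (300, 4)))
        res = run_pca(X)
        labels = rng.permutation([1] * 150 + [0] * 150)
        tab = pc_dementia_auc(res, labels)
        assert (np.abs(tab["auc"] - 0.5) < 0.12).all()

    def test_labels_thresholded_on_pc1_give_auc_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (50, 3)))
        res = run_pca(X)
        labels = (res.scores["PC1"] > res.scores["PC1"].median()).astype(int)
        tab = pc_dementia_auc(res, labels.to_numpy())
        assert tab.loc[tab["component"] == "PC1", "auc"].iloc[0] == 1.0

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(2).normal(0, 1, (10, 2)))
        res = run_pca(X)
        with pytest.raises(ValueError):
            pc_dementia_auc(res, np.ones(10))

    def test_inverted_components_flagged(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(0, 1, (80, 2)))
        res = run_pca(X)
        labels = (res.scores["PC1"] < res.scores["PC1"].median()).astype(int)
        tab = pc_dementia_auc(res, labels.to_numpy())
        row = tab[tab["component"] == "PC1"].iloc[0]
        assert row["inverted"] and row["oriented_auc"] == 1.0
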