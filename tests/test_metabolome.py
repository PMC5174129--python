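"""Normalization, PCA, OPLS-DA/VIP and differential-metabolite calling."""

import numpy as np
import pandas as pd
import pytest

import droughtmine as dm
from droughtmine import io, metabolome


def pls_da_oracle(X, y, tol=1e-12, max_iter=1000):
    """Independent textbook NIPALS PLS1: returns (w unit norm, t = Xw).

    Deliberately written from the classic algorithm statement, not shared
    with the implementation under test.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    u = y.copy()
    t_prev = np.zeros(X.shape[0])
    for _ in range(max_iter):
        w = X.T @ u
        w = w / np.sqrt(w @ w)
        t = X @ w
        q = (y @ t) / (t @ t)
        u = y * q / (q * q)
        if np.sqrt(((t - t_prev) ** 2).sum()) < tol:
            break
        t_prev = t
    return w, t


class TestNormalization:
    def test_direct_normalization(self):
        t = pd.DataFrame({"s1": [2.0, 3.0, 5.0]}, index=["a", "b", "c"])
        out = metabolome.normalize_sum_intensity(t)
        np.testing.assert_allclose(out["s1"], [0.2, 0.3, 0.5])

    def test_idempotent(self):
        t = pd.DataFrame({"s1": [0.2, 0.3, 0.5]})
        out = metabolome.normalize_sum_intensity(t)
        pd.testing.assert_frame_equal(out, t)

    def test_missing_peaks_excluded_from_sum(self):
        t = pd.DataFrame({"s1": [4.0, np.nan, 6.0]}, index=["a", "b", "c"])
        out = metabolome.normalize_sum_intensity(t)
        np.testing.assert_allclose(out["s1"].dropna(), [0.4, 0.6])
        assert np.isnan(out.loc["b", "s1"])

    def test_all_missing_sample_rejected(self):
        t = pd.DataFrame({"s1": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="no detected peaks"):
            metabolome.normalize_sum_intensity(t)


class TestAutoscale:
    def test_hand_example(self):
        m = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        scaled, means, sds = dm.autoscale(m)
        np.testing.assert_allclose(scaled["v"], [-1.0, 0.0, 1.0])
        assert means["v"] == 2.0 and sds["v"] == 1.0

    def test_constant_variable_dropped(self):
        m = pd.DataFrame({"v": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        scaled, _, _ = dm.autoscale(m)
        assert list(scaled.columns) == ["v"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(8, 3)))
        scaled, _, _ = dm.autoscale(m)
        again, _, _ = dm.autoscale(scaled)
        np.testing.assert_allclose(again.to_numpy(), scaled.to_numpy(), atol=1e-12)


class TestPca:
    def test_rank_one_matrix(self):
        u = np.arange(6.0)[:, None]
        v = np.array([[1.0, 2.0, 3.0, 4.0]])
        scores, loadings, ev = dm.pca(u @ v, n_components=2)
        assert ev[1] == pytest.approx(0.0, abs=1e-10)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        scores, loadings, _ = dm.pca(X, n_components=4)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(scores @ loadings.T, Xc, atol=1e-9)

    def test_eigenvalues_match_covariance_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        _, _, ev = dm.pca(X, n_components=4)
        Xc = X - X.mean(axis=0)
        oracle = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        np.testing.assert_allclose(ev, oracle[:4], atol=1e-10)

    def test_rank_deficient_request_rejected(self):
        with pytest.raises(ValueError):
            dm.pca(np.zeros((3, 5)), n_components=3)


def _blobs(n=10, p=6, sep=4.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p)) * (noise if noise else 1.0)
    labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
    if sep:
        X = np.zeros((n, p)) + (noise * rng.normal(size=(n, p)) if noise else 0.0)
        X[np.array(labels) == "b", 0] += sep
    return X, labels


class TestOplsDa:
    def test_separable_classes_zero_overlap(self):
        X, labels = _blobs(sep=4.0, noise=0.0)
        scaled = (X - X.mean(0)) / np.where(X.std(0, ddof=1) > 0, X.std(0, ddof=1), 1.0)
        model = dm.opls_da(scaled, labels, n_orthogonal=0)
        a = model.scores[np.array(labels) == "a"]
        b = model.scores[np.array(labels) == "b"]
        assert a.max() < b.min() or b.max() < a.min()

    def test_orthogonal_scores_uncorrelated_with_class(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 8))
        labels = ["a"] * 6 + ["b"] * 6
        model = dm.opls_da(X, labels, n_orthogonal=2)
        y = model.y
        for k in range(model.n_orthogonal):
            t_o = model.ortho_scores[:, k]
            corr = abs(np.corrcoef(t_o, y)[0, 1])
            assert corr < 1e-8

    def test_matches_independent_nipals_with_no_orthogonal(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(10, 6))
            labels = ["a"] * 5 + ["b"] * 5
            model = dm.opls_da(X, labels, n_orthogonal=0)
            y = model.y
            w_ref, t_ref = pls_da_oracle(X, y)
            sign = np.sign(w_ref @ model.weights)
            np.testing.assert_allclose(model.weights, sign * w_ref, atol=1e-8)
            np.testing.assert_allclose(model.scores, sign * t_ref, atol=1e-8)

    def test_permuted_labels_kill_r2y(self):
        rng = np.random.default_rng(5)
        X, labels = _blobs(n=12, sep=3.0, noise=0.5, seed=5)
        model = dm.opls_da(X, labels, n_orthogonal=0)
        null_r2 = []
        labels_arr = np.array(labels)
        for _ in range(200):
            perm = rng.permutation(labels_arr)
            if len(set(perm[:6])) == 1:  # degenerate split cannot occur with 6/6, keep all
                continue
            null_r2.append(dm.opls_da(X, list(perm), n_orthogonal=0).r2y)
        assert model.r2y > np.quantile(null_r2, 0.95)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dm.opls_da(np.zeros((4, 3)), ["a", "a", "a", "a"])


class TestVip:
    def test_single_variable_is_one(self):
        X = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        model = dm.opls_da(X, ["a", "a", "b", "b"], n_orthogonal=0)
        np.testing.assert_allclose(model.vip, [1.0], atol=1e-10)

    def test_symmetric_variables_both_one(self):
        base = np.array([1.0, 2.0, -1.0, -2.0, 1.5, -1.5])
        X = np.column_stack([base, base])
        model = dm.opls_da(X, ["a", "a", "b", "b", "a", "b"], n_orthogonal=0)
        np.testing.assert_allclose(model.vip, [1.0, 1.0], atol=1e-10)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 5))
        model = dm.opls_da(X, ["a"] * 6 + ["b"] * 6, n_orthogonal=1)
        w = model.weights / np.linalg.norm(model.weights)
        expected = np.sqrt(5 * w ** 2)   # single predictive component
        np.testing.assert_allclose(model.vip, expected, atol=1e-10)

    def test_rms_is_one_for_random_models(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10, 7))
            model = dm.opls_da(X, ["a"] * 5 + ["b"] * 5, n_orthogonal=1)
            assert np.sqrt(np.mean(model.vip ** 2)) == pytest.approx(1.0, abs=1e-10)


class TestDifferentialMetabolites:
    def test_dual_criterion_and_recovery(self, worked_bundle, default_config):
        normalized = metabolome.normalize_sum_intensity(worked_bundle.metabolites)
        shared = metabolome.shared_metabolites(normalized, worked_bundle.metadata)
        period_map = {"A": "I", "B": "I", "C": "II", "D": "II", "E": "II", "F": "III"}
        parts = [
            dm.call_differential_metabolites(
                normalized, worked_bundle.metadata, genotype, period_map,
                default_config, restrict_to=shared,
            )[0]
            for genotype in ("tolerant", "susceptible")
        ]
        table = pd.concat(parts, ignore_index=True)
        hits = table[table["is_dm"]]
        assert (hits["vip"] > default_config.vip_threshold).all()
        assert (hits["p_value"] < default_config.dm_p_threshold).all()
        misses = table[~table["is_dm"]]
        assert (
            (misses["vip"] <= default_config.vip_threshold)
            | (misses["p_value"] >= default_config.dm_p_threshold)
            | misses["vip"].isna()
        ).all()
        # every planted key metabolite is a DM in at least one genotype during
        # severe drought -- the property the key-metabolite criterion consumes
        planted = set(worked_bundle.truth.key_metabolites)
        severe = set(hits.loc[hits["period"] == "II", "metabolite_id"])
        assert planted <= severe
        # single-genotype metabolites never enter the shared comparison
        single = {
            m for m, det in metabolome.detection_flags(
                normalized, worked_bundle.metadata).iterrows()
            if not det.all()
        }
        assert not single & set(table["metabolite_id"])

    def test_sample_rescaling_invariance(self, worked_bundle, default_config):
        period_map = {"A": "I", "B": "I", "C": "II", "D": "II", "E": "II", "F": "III"}
        raw = worked_bundle.metabolites
        scaled_raw = raw.copy()
        scaled_raw.iloc[:, 0] *= 37.5   # global intensity drift in one sample
        outputs = []
        for t in (raw, scaled_raw):
            normalized = metabolome.normalize_sum_intensity(t)
            table, _ = dm.call_differential_metabolites(
                normalized, worked_bundle.metadata, "tolerant", period_map,
                default_config,
                restrict_to=metabolome.shared_metabolites(normalized, worked_bundle.metadata),
            )
            outputs.append(table)
        pd.testing.assert_frame_equal(outputs[0], outputs[1])

    @pytest.mark.parametrize("value,expected", [(12.4, 10.0), (-11.0, -10.0), (9.9, 9.9)])
    def test_metabolite_capping(self, value, expected):
        profile = pd.DataFrame({"I": [value]})
        assert dm.cap_metabolite_profile(profile).iloc[0, 0] == pytest.approx(expected)
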