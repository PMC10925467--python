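"""Soft-threshold selection, TOM, module detection, eigenlipids, module-trait stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from brainlipid.network import (
    NetworkConfig,
    build_tom,
    detect_modules,
    eigenlipids,
    feature_correlation,
    module_trait_assoc,
    pearson_with_student_p,
    pick_soft_threshold,
    remove_outlier_samples,
    signed_adjacency,
)
from tests.conftest import planted_blocks


def brute_force_diss_tom(cor, beta):
    """Triple-loop oracle for the signed min-overlap TOM dissimilarity."""
    p = cor.shape[0]
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=0) - 1.0
    tom = np.ones((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            overlap = sum(
                min(a[i, u], a[u, j]) for u in range(p) if u != i and u != j
            )
            tom[i, j] = (overlap + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    return diss


class TestSoftThreshold:
    def test_hub_structured_data_reaches_good_fit(self):
        """Data with power-law-ish hub connectivity fits scale-free topology."""
        rng = np.random.default_rng(0)
        n, p = 250, 150
        f = rng.standard_normal(n)
        loadings = (np.arange(1, p + 1) / p) ** 1.5  # heterogeneous hubness
        X = np.outer(f, loadings) + rng.standard_normal((n, p)) * 0.9
        data = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
        table, beta = pick_soft_threshold(data, range(1, 13))
        assert table.loc[table["power"] == beta, "r2"].iloc[0] >= 0.85

    def test_single_candidate_returned(self):
        data, _ = planted_blocks(1, n_modules=2, size=15, n=80)
        _, beta = pick_soft_threshold(data, [8])
        assert beta == 8

    def test_noise_data_still_returns_a_power(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.standard_normal((80, 40)))
        table, beta = pick_soft_threshold(data, range(1, 11))
        assert beta in set(table["power"])

    def test_too_few_features_rejected(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.standard_normal((30, 10)))
        with pytest.raises(ValueError):
            pick_soft_threshold(data)


class TestTom:
    def test_three_feature_hand_example(self):
        """cor = [[1,.5,0],[.5,1,0],[0,0,1]], beta 1: entries from the formula."""
        cor = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        rng = np.random.default_rng(4)
        # synthesize data with exactly this correlation via Cholesky on large n
        L = np.linalg.cholesky(cor + 1e-12 * np.eye(3))
        Z = rng.standard_normal((5000, 3))
        X = (Z - Z.mean(0)) / Z.std(0)
        data = pd.DataFrame(X @ L.T, columns=list("abc"))
        emp_cor = feature_correlation(data, NetworkConfig(power=1))
        expected = brute_force_diss_tom(emp_cor, 1)
        got = build_tom(data, NetworkConfig(power=1)).to_numpy()
        assert np.allclose(got, expected, atol=1e-10)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for beta in (1, 6):
            data = pd.DataFrame(rng.standard_normal((40, 15)))
            cor = np.clip(np.corrcoef(data.to_numpy(), rowvar=False), -1, 1)
            expected = brute_force_diss_tom(cor, beta)
            got = build_tom(data, NetworkConfig(power=beta)).to_numpy()
            assert np.allclose(got, expected, atol=1e-10)

    def test_identical_features_have_zero_dissimilarity(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        data = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)})
        diss = build_tom(data, NetworkConfig(power=6))
        assert diss.loc["a", "b"] == pytest.approx(0.0, abs=1e-8)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.standard_normal((50, 20)))
        diss = build_tom(data, NetworkConfig(power=6)).to_numpy()
        assert np.allclose(diss, diss.T)
        assert diss.min() >= 0.0 and diss.max() <= 1.0
        assert np.allclose(np.diag(diss), 0.0)

    def test_constant_feature_rejected(self):
        data = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            build_tom(data, NetworkConfig(power=2))

    def test_bicor_option_close_to_pearson_on_clean_data(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.standard_normal((200, 10)))
        c1 = feature_correlation(data, NetworkConfig(correlation="pearson"))
        c2 = feature_correlation(data, NetworkConfig(correlation="bicor"))
        assert np.abs(c1 - c2).max() < 0.15


class TestModuleDetection:
    def test_planted_blocks_recovered(self):
        data, truth = planted_blocks(0, n_modules=6, size=20, rho=0.7, n=300)
        cfg = NetworkConfig(power=8)
        labels = detect_modules(build_tom(data, cfg), cfg)
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_orthogonal_features_stay_unassigned(self):
        data, _ = planted_blocks(9, n_modules=0, size=0, n=300, n_noise=100)
        cfg = NetworkConfig(power=8)
        labels = detect_modules(build_tom(data, cfg), cfg)
        assert (labels == 0).mean() > 0.5

    def test_single_block_is_one_module(self):
        data, _ = planted_blocks(3, n_modules=1, size=30, n=300)
        cfg = NetworkConfig(power=8)
        labels = detect_modules(build_tom(data, cfg), cfg)
        assert labels.max() == 1 and (labels == 1).all()

    def test_label_invariance_to_feature_order(self):
        data, truth = planted_blocks(4, n_modules=4, size=15, n=200, n_noise=20)
        cfg = NetworkConfig(power=8)
        labels = detect_modules(build_tom(data, cfg), cfg)
        perm = np.random.default_rng(5).permutation(data.shape[1])
        labels_perm = detect_modules(build_tom(data.iloc[:, perm], cfg), cfg)
        assert adjusted_rand_score(
            labels.iloc[perm].to_numpy(), labels_perm.to_numpy()
        ) == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame(np.random.default_rng(0).uniform(size=(5, 5)))
        with pytest.raises(ValueError):
            detect_modules(bad, NetworkConfig())


class TestEigenlipids:
    def test_rank_one_module_has_full_variance_explained(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(80)
        data = pd.DataFrame({"a": x, "b": 2 * x + 5, "c": rng.standard_normal(80)})
        labels = pd.Series([1, 1, 2], index=["a", "b", "c"])
        ms = eigenlipids(data, labels)
        assert ms.variance_explained["M1"] == pytest.approx(1.0)

    def test_me_columns_unit_variance_and_sign_aligned(self):
        data, truth = planted_blocks(11, n_modules=3, size=10, n=150)
        labels = pd.Series(truth + 1, index=data.columns)
        ms = eigenlipids(data, labels)
        assert np.allclose(ms.eigenlipids.std(ddof=1), 1.0)
        for mid in (1, 2, 3):
            members = labels.index[labels == mid]
            mean_profile = data[members].mean(axis=1)
            r = np.corrcoef(ms.eigenlipids[f"M{mid}"], mean_profile)[0, 1]
            assert r > 0

    def test_own_module_kme_dominates(self):
        data, truth = planted_blocks(12, n_modules=5, size=15, n=250)
        labels = pd.Series(truth + 1, index=data.columns)
        ms = eigenlipids(data, labels)
        own_best = 0
        for f in data.columns:
            own = ms.kme.loc[f, f"M{labels[f]}"]
            own_best += own >= ms.kme.loc[f].max() - 1e-12
        assert own_best / len(data.columns) >= 0.95

    def test_hub_recovery_at_mm_threshold(self):
        """MM > 0.60 hubs of a planted module are exactly its strong members."""
        data, truth = planted_blocks(13, n_modules=2, size=20, rho=0.7, n=300)
        labels = pd.Series(truth + 1, index=data.columns)
        ms = eigenlipids(data, labels)
        hubs = set(ms.hubs(1, mm_threshold=0.60))
        members = set(labels.index[labels == 1])
        assert hubs <= members
        # sqrt(0.7) ~ 0.84 expected own-module kME: nearly all members are hubs
        assert len(hubs) >= 0.9 * len(members)

    def test_singleton_module_me_is_the_feature(self):
        rng = np.random.default_rng(14)
        data = pd.DataFrame({"a": rng.standard_normal(50), "b": rng.standard_normal(50)})
        labels = pd.Series([1, 2], index=["a", "b"])
        ms = eigenlipids(data, labels)
        r = np.corrcoef(ms.eigenlipids["M1"], data["a"])[0, 1]
        assert abs(r) == pytest.approx(1.0)


class TestModuleTrait:
    def test_zero_correlation_gives_p_one(self):
        r, p, n = pearson_with_student_p(
            np.array([1.0, -1.0, 1.0, -1.0]), np.array([1.0, 1.0, -1.0, -1.0])
        )
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_matches_published_order_of_magnitude(self):
        """r = -0.23 at n = 314 gives p ~ 4e-5 from t = r sqrt(n-2)/sqrt(1-r^2)."""
        rng = np.random.default_rng(15)
        n, r_target = 314, -0.23
        x = rng.standard_normal(n)
        y = r_target * x + np.sqrt(1 - r_target**2) * rng.standard_normal(n)
        # rescale to the exact empirical correlation
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        y_exact = r_target * (x - x.mean()) / x.std() + np.sqrt(1 - r_target**2) * (
            resid - resid.mean()
        ) / resid.std()
        r, p, n_out = pearson_with_student_p(x, y_exact)
        assert r == pytest.approx(r_target, abs=1e-10)
        t = r_target * np.sqrt(n - 2) / np.sqrt(1 - r_target**2)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-10)
        assert 1e-5 < p < 1e-4

    def test_constant_trait_returns_missing(self):
        me = pd.DataFrame({"M1": np.random.default_rng(0).standard_normal(20)})
        traits = pd.DataFrame({"flat": np.ones(20)}, index=me.index)
        res = module_trait_assoc(me, traits)
        assert np.isnan(res["r"].iloc[0])

    def test_pairwise_complete_handling(self):
        rng = np.random.default_rng(16)
        me = pd.DataFrame({"M1": rng.standard_normal(30)})
        y = me["M1"] * 0.9 + 0.3 * rng.standard_normal(30)
        y.iloc[:5] = np.nan
        res = module_trait_assoc(me, pd.DataFrame({"t": y}))
        assert res["n"].iloc[0] == 25
        assert res["p"].iloc[0] < 0.01

    def test_asymptotic_p_matches_permutation_p(self):
        """Student asymptotic p agrees with a permutation p within MC error."""
        rng = np.random.default_rng(17)
        n = 25
        x = rng.standard_normal(n)
        y = 0.45 * x + rng.standard_normal(n)
        r, p_asym, _ = pearson_with_student_p(x, y)
        B = 10_000
        perm_r = np.empty(B)
        for b in range(B):
            perm_r[b] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (1 + np.sum(np.abs(perm_r) >= abs(r))) / (B + 1)
        assert p_asym == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / B) + 1e-3)

    def test_null_calibration(self):
        rng = np.random.default_rng(18)
        ps = []
        for _ in range(300):
            r, p, _ = pearson_with_student_p(
                rng.standard_normal(40), rng.standard_normal(40)
            )
            ps.append(p)
        assert 0.02 <= np.mean(np.array(ps) < 0.05) <= 0.10


class TestOutlierRemoval:
    def test_shifted_sample_flagged(self):
        rng = np.random.default_rng(19)
        data = pd.DataFrame(rng.standard_normal((40, 30)))
        data.iloc[7] += 10.0
        retained, report = remove_outlier_samples(data, z_threshold=3.0)
        assert 7 not in retained
        assert report["outlier"].sum() >= 1

    def test_homogeneous_data_untouched(self):
        rng = np.random.default_rng(20)
        data = pd.DataFrame(rng.standard_normal((40, 30)))
        retained, _ = remove_outlier_samples(data, z_threshold=5.0)
        assert len(retained) == 40

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(21)
        data = pd.DataFrame(rng.standard_normal((15, 10)))
        retained, _ = remove_outlier_samples(data, z_threshold=np.inf)
        assert len(retained) == 15
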