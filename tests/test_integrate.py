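"""sPLS-DA, ROC/AUC, multiblock integration, relevance networks, set ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.cross_decomposition import PLSRegression

from brainlipid.integrate import (
    diablo_fit,
    geneset_ora,
    pairwise_assoc,
    per_feature_auc,
    relevance_network,
    roc_auc,
    splsda_fit,
    splsda_predict,
)


def _two_class(rng, n=40, p=12, sep=0.0):
    X = rng.standard_normal((n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "a", :3] += sep
    return pd.DataFrame(X), list(y)


class TestSplsda:
    def test_dense_fit_matches_pls_oracle(self):
        """keepX = all equals standard PLS on dummy Y (variate |r| >= 0.99)."""
        rng = np.random.default_rng(0)
        agree = 0
        for _ in range(50):
            X, y = _two_class(rng, n=30, p=10, sep=0.5)
            m = splsda_fit(X, y, ncomp=2)
            Y = np.column_stack([(np.array(y) == c).astype(float) for c in m.classes])
            pls = PLSRegression(n_components=2, scale=True).fit(X.to_numpy(), Y)
            r = abs(np.corrcoef(m.scores[:, 0], pls.x_scores_[:, 0])[0, 1])
            agree += r >= 0.99
        assert agree == 50

    def test_separable_classes_fully_recovered(self):
        rng = np.random.default_rng(1)
        X, y = _two_class(rng, sep=6.0)
        m = splsda_fit(X, y, ncomp=2)
        scores, labels = splsda_predict(m, X)
        assert (labels == np.array(y)).all()
        auc, _ = roc_auc(scores["a"].to_numpy(), (np.array(y) == "a").astype(int))
        assert auc == 1.0

    def test_sparsity_respected(self):
        rng = np.random.default_rng(2)
        X, y = _two_class(rng, p=20)
        m = splsda_fit(X, y, ncomp=2, keep_x=[5, 3])
        nz = (np.abs(m.loadings) > 1e-12).sum(axis=0)
        assert nz[0] <= 5 and nz[1] <= 3

    def test_keepx_exceeding_features_rejected(self):
        rng = np.random.default_rng(3)
        X, y = _two_class(rng, p=8)
        with pytest.raises(ValueError):
            splsda_fit(X, y, keep_x=[9])

    def test_permuted_labels_give_chance_level_auc(self):
        """Fit on permuted labels, evaluate on held-out permuted labels."""
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(20):
            X, y = _two_class(rng, n=60, p=10, sep=0.0)
            y = list(rng.permutation(y))
            m = splsda_fit(X.iloc[:40], y[:40], ncomp=2)
            scores, _ = splsda_predict(m, X.iloc[40:])
            auc, _ = roc_auc(scores["a"].to_numpy(), (np.array(y[40:]) == "a").astype(int))
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_prediction_partitions_the_plane(self):
        rng = np.random.default_rng(5)
        X, y = _two_class(rng, sep=2.0)
        m = splsda_fit(X, y, ncomp=2)
        grid = rng.standard_normal((200, X.shape[1]))
        for distance in ("centroid", "mahalanobis", "max_dist"):
            _, labels = splsda_predict(m, grid, distance=distance)
            assert set(labels) <= set(m.classes)
            assert len(labels) == 200

    def test_centroid_and_max_dist_agree_far_from_boundary(self):
        rng = np.random.default_rng(6)
        X, y = _two_class(rng, sep=8.0)
        m = splsda_fit(X, y, ncomp=2)
        _, l1 = splsda_predict(m, X, distance="centroid")
        _, l2 = splsda_predict(m, X, distance="max_dist")
        assert (l1 == l2).all()

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        X, y = _two_class(rng, p=8)
        m = splsda_fit(X, y)
        with pytest.raises(ValueError, match="feature mismatch"):
            splsda_predict(m, rng.standard_normal((5, 9)))


class TestRocAuc:
    def test_perfect_and_one_swap(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1])[0] == 1.0
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1])[0] == 0.75

    def test_equals_direct_u_counting(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            scores = rng.standard_normal(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_null_sampling_distribution(self):
        """Random scores: AUC mean ~0.5 with the closed-form null sd."""
        rng = np.random.default_rng(10)
        n1 = n0 = 50
        aucs = [
            roc_auc(rng.standard_normal(n1 + n0), [1] * n1 + [0] * n0)[0]
            for _ in range(300)
        ]
        sd_theory = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(np.mean(aucs) - 0.5) < 0.02
        assert np.std(aucs) == pytest.approx(sd_theory, rel=0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_per_feature_ranking_finds_planted_lyso_deficit(self, small_sim, small_log):
        groups = small_sim.cohort["diagnosis"].loc[small_log.index]
        keep = groups.isin(["SAD", "Control"])
        res = per_feature_auc(small_log.loc[keep.to_numpy()],
                              (groups[keep] == "SAD").astype(int).to_numpy())
        truth = set(small_sim.ground_truth.differential["feature"])
        top10 = set(res.head(10).index) | set(res.tail(10).index)
        assert len(top10 & truth) >= 5


class TestDiablo:
    def _shared_latent_blocks(self, rng, n=100):
        lat = rng.standard_normal(n)
        y = ["a" if v > 0 else "b" for v in lat]
        X1 = pd.DataFrame(np.outer(lat, rng.standard_normal(15)) + 0.7 * rng.standard_normal((n, 15)))
        X2 = pd.DataFrame(np.outer(lat, rng.standard_normal(12)) + 0.7 * rng.standard_normal((n, 12)))
        return {"b1": X1, "b2": X2}, y

    def test_shared_latent_recovered_in_component_one(self):
        rng = np.random.default_rng(11)
        blocks, y = self._shared_latent_blocks(rng)
        design = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["b1", "b2"], columns=["b1", "b2"])
        m = diablo_fit(blocks, y, design, ncomp=2)
        r1 = m.pair_correlations.query("component == 1")["r"].iloc[0]
        assert abs(r1) >= 0.8

    def test_zero_design_reduces_to_per_block_splsda(self):
        rng = np.random.default_rng(12)
        blocks, y = self._shared_latent_blocks(rng)
        design = pd.DataFrame(0.0, index=["b1", "b2"], columns=["b1", "b2"])
        m = diablo_fit(blocks, y, design, ncomp=1)
        for b in blocks:
            s = splsda_fit(blocks[b], y, ncomp=1)
            assert np.abs(np.abs(m.scores[b][:, 0]) - np.abs(s.scores[:, 0])).max() < 1e-6

    def test_dense_objective_monotone_within_component(self):
        rng = np.random.default_rng(13)
        blocks, y = self._shared_latent_blocks(rng)
        design = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["b1", "b2"], columns=["b1", "b2"])
        m = diablo_fit(blocks, y, design, ncomp=2)
        for trace in m.objective_trace:
            assert (np.diff(trace) >= -1e-8).all()

    def test_sample_mismatch_rejected_naming_block(self):
        rng = np.random.default_rng(14)
        blocks, y = self._shared_latent_blocks(rng)
        blocks["b2"] = blocks["b2"].iloc[:-3]
        with pytest.raises(ValueError, match="b2"):
            diablo_fit(blocks, y, ncomp=1)

    def test_invalid_design_rejected(self):
        rng = np.random.default_rng(15)
        blocks, y = self._shared_latent_blocks(rng)
        bad = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=["b1", "b2"], columns=["b1", "b2"])
        with pytest.raises(ValueError):
            diablo_fit(blocks, y, bad, ncomp=1)


class TestRelevanceNetwork:
    def test_duplicated_node_across_types_gives_unit_edge(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(50)
        a = pd.DataFrame({"m1": x})
        b = pd.DataFrame({"p1": x, "p2": rng.standard_normal(50)})
        net = relevance_network({"lipid": a, "protein": b}, cutoff=0.7)
        assert len(net.edges) == 1
        assert net.edges["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_nodes_give_empty_network(self):
        rng = np.random.default_rng(17)
        a = pd.DataFrame(rng.standard_normal((266, 4)), columns=list("abcd"))
        b = pd.DataFrame(rng.standard_normal((266, 5)), columns=list("vwxyz"))
        net = relevance_network({"lipid": a, "protein": b}, cutoff=0.7)
        assert net.edges.empty

    def test_edges_are_cross_type_and_deduplicated(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(60)
        a = pd.DataFrame({"m1": x, "m2": x + 0.01 * rng.standard_normal(60)})
        b = pd.DataFrame({"p1": x})
        net = relevance_network({"lipid": a, "protein": b}, cutoff=0.7)
        # m1-m2 are same-type: no edge between them even though |r| ~ 1
        pairs = set(zip(net.edges["source_type"], net.edges["target_type"]))
        assert pairs == {("lipid", "protein")}
        assert len(net.edges) == len(net.edges.drop_duplicates(["source", "target"]))

    def test_sample_mismatch_rejected(self):
        rng = np.random.default_rng(19)
        a = pd.DataFrame(rng.standard_normal((20, 2)))
        b = pd.DataFrame(rng.standard_normal((19, 2)))
        with pytest.raises(ValueError):
            relevance_network({"x": a, "y": b})


class TestPairwiseAssoc:
    def test_near_copy_retained_with_high_r(self):
        rng = np.random.default_rng(20)
        x = rng.standard_normal(80)
        lip = pd.DataFrame({"LPE 22:6": x})
        prot = pd.DataFrame({"EML4": x + 0.1 * rng.standard_normal(80),
                             "OTHER": rng.standard_normal(80)})
        edges = pairwise_assoc(lip, prot)
        assert list(edges["protein"]) == ["EML4"]
        assert edges["r"].iloc[0] > 0.95

    def test_null_retention_rate_matches_joint_threshold(self):
        """|r| > 0.5 at n = 30 has null probability ~0.005; retention is rare."""
        rng = np.random.default_rng(21)
        lip = pd.DataFrame(rng.standard_normal((30, 10)))
        lip.columns = [f"L{i}" for i in range(10)]
        prot = pd.DataFrame(rng.standard_normal((30, 40)))
        prot.columns = [f"P{i}" for i in range(40)]
        edges = pairwise_assoc(lip, prot, cor_cutoff=0.5, p_cutoff=0.05)
        assert len(edges) <= 0.05 * 400

    def test_coupled_community_recovered(self):
        rng = np.random.default_rng(22)
        x = rng.standard_normal(100)
        lip = pd.DataFrame({"LPE 22:6": x})
        cols = {f"P{i}": 0.8 * x + 0.6 * rng.standard_normal(100) for i in range(5)}
        cols.update({f"N{i}": rng.standard_normal(100) for i in range(20)})
        prot = pd.DataFrame(cols)
        edges = pairwise_assoc(lip, prot)
        assert set(edges["protein"]) >= {f"P{i}" for i in range(5)}


class TestGenesetOra:
    def test_exact_set_hit_closed_form(self):
        """Query equal to one set: p = 1/C(N, n) when K = n = k."""
        bg = [f"g{i}" for i in range(12)]
        sets = {"S": bg[:4]}
        res = geneset_ora(bg[:4], sets, bg)
        assert res["p"].iloc[0] == pytest.approx(1.0 / comb(12, 4), rel=1e-12)

    def test_disjoint_query_gives_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        sets = {"S1": bg[:5], "S2": bg[5:10]}
        res = geneset_ora(bg[15:], sets, bg)
        assert (res["p"] == 1.0).all()

    def test_bonferroni_vs_bh(self):
        rng = np.random.default_rng(23)
        bg = [f"g{i}" for i in range(50)]
        sets = {f"S{j}": list(rng.choice(bg, 8, replace=False)) for j in range(6)}
        q = list(rng.choice(bg, 10, replace=False))
        bonf = geneset_ora(q, sets, bg, correction="bonferroni").set_index("set")
        bh = geneset_ora(q, sets, bg, correction="bh").set_index("set")
        assert (bonf["p_adj"] >= bh["p_adj"] - 1e-12).all()

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            geneset_ora(["zz"], {"S": ["a"]}, ["a", "b"])

    def test_empty_query_gives_empty_result(self):
        assert geneset_ora([], {"S": ["a"]}, ["a", "b"]).empty
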