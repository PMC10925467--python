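"""Supervised classification and multiblock omics integration.

Sparse PLS-DA is fitted by NIPALS power iteration on the dummy-coded class
matrix with soft-thresholding of the X-loadings to ``keepX`` nonzero entries
per component. The multiblock (DIABLO-style) model alternates the same update
across omics blocks, maximizing

    sum_b cov(X_b w_b, Y u_b)  +  sum_{b<c} design_bc cov(X_b w_b, X_c w_c)

so that with an all-zero design it decouples exactly into per-block sPLS-DA
against the outcome. Relevance networks threshold direct Pearson correlations
between typed nodes (lipid-module eigenlipids, protein-module eigenvalues,
clinical traits); pairwise lipid-protein association uses the one-component
PLS correlation (Pearson for a univariate predictor) with the Student
asymptotic p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diff import bh_fdr
from .network import pearson_with_student_p


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold to the ``keep`` largest |w|; shrink survivors by the cut magnitude."""
    p = len(w)
    if keep >= p:
        return w.copy()
    absw = np.abs(w)
    lam = np.partition(absw, p - keep - 1)[p - keep - 1]
    out = np.sign(w) * np.maximum(absw - lam, 0.0)
    return out


def _dummy(y: Sequence) -> tuple[np.ndarray, list]:
    classes = sorted(set(y))
    Y = np.zeros((len(y), len(classes)))
    for i, lab in enumerate(y):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


@dataclass
class SplsdaModel:
    classes: list
    x_mean: np.ndarray
    x_scale: np.ndarray
    loadings: np.ndarray  # p x ncomp (sparse W)
    rotation: np.ndarray  # p x ncomp (W (P'W)^-1), projects new data
    scores: np.ndarray  # n x ncomp training variates
    y_loadings: np.ndarray  # K x ncomp
    centroids: np.ndarray  # K x ncomp
    explained_variance: np.ndarray
    keep_x: list
    feature_names: list
    within_cov: np.ndarray = field(default=None)


def splsda_fit(
    X,
    y: Sequence,
    ncomp: int = 2,
    keep_x: Optional[Sequence[int]] = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> SplsdaModel:
    """Sparse PLS discriminant analysis on dummy-coded class labels.

    ``keep_x`` gives the number of nonzero X-loadings per component (default:
    all features, i.e. dense PLS-DA). Deterministic: initialization is the
    dominant singular vector of X'Y.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    Ydum, classes = _dummy(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    keep_x = list(keep_x) if keep_x is not None else [p] * ncomp
    if len(keep_x) < ncomp:
        keep_x = keep_x + [keep_x[-1]] * (ncomp - len(keep_x))
    if any(k > p or k < 1 for k in keep_x):
        raise ValueError("keepX entries must lie in [1, n_features]")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    Xc = (X - x_mean) / x_scale
    Yc = Ydum - Ydum.mean(axis=0)
    total_var = (Xc**2).sum()

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    C = np.zeros((len(classes), ncomp))
    T = np.zeros((n, ncomp))
    ev = np.zeros(ncomp)
    Xd, Yd = Xc.copy(), Yc.copy()
    for h in range(ncomp):
        M = Xd.T @ Yd
        u_, s_, vt_ = np.linalg.svd(M, full_matrices=False)
        w = u_[:, 0]
        for _ in range(max_iter):
            q = M.T @ w
            nq = np.linalg.norm(q)
            if nq == 0:
                break
            q /= nq
            w_raw = M @ q
            w_new = _soft_threshold_keep(w_raw, keep_x[h])
            nw = np.linalg.norm(w_new)
            if nw == 0:
                w_new = w_raw
                nw = np.linalg.norm(w_new)
            w_new /= nw
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            break
        p_load = Xd.T @ t / tt
        c = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)
        W[:, h], P[:, h], C[:, h], T[:, h] = w, p_load, c, t
        ev[h] = tt * (p_load @ p_load) / total_var

    rotation = W @ np.linalg.pinv(P.T @ W)
    centroids = np.vstack([T[np.asarray(y) == lab].mean(axis=0) for lab in classes])
    resid = np.vstack([T[np.asarray(y) == lab] - centroids[i] for i, lab in enumerate(classes)])
    within_cov = np.cov(resid, rowvar=False) if ncomp > 1 else np.atleast_2d(resid.var(ddof=1))
    return SplsdaModel(
        classes=classes,
        x_mean=x_mean,
        x_scale=x_scale,
        loadings=W,
        rotation=rotation,
        scores=T,
        y_loadings=C,
        centroids=centroids,
        explained_variance=ev,
        keep_x=keep_x,
        feature_names=feature_names,
        within_cov=within_cov,
    )


def splsda_transform(model: SplsdaModel, X_new) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(model.x_mean):
        raise ValueError(
            f"feature mismatch: model has {len(model.x_mean)}, input has {X_new.shape[1]}"
        )
    return (X_new - model.x_mean) / model.x_scale @ model.rotation


def splsda_predict(
    model: SplsdaModel, X_new, distance: str = "centroid"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project new samples and assign classes by distance in variate space.

    ``distance``: 'centroid' (Euclidean to class centroids), 'mahalanobis'
    (pooled within-class covariance), or 'max_dist' (largest predicted dummy
    response). Returns (per-class continuous scores for ROC, predicted labels).
    """
    T = splsda_transform(model, X_new)
    K = len(model.classes)
    scores = np.zeros((T.shape[0], K))
    if distance in ("centroid", "mahalanobis"):
        if distance == "mahalanobis":
            cov = model.within_cov + 1e-10 * np.eye(model.within_cov.shape[0])
            icov = np.linalg.inv(cov)
        else:
            icov = np.eye(T.shape[1])
        for i in range(K):
            d = T - model.centroids[i]
            scores[:, i] = -np.sqrt(np.einsum("ij,jk,ik->i", d, icov, d))
    elif distance == "max_dist":
        scores = T @ model.y_loadings.T
    else:
        raise ValueError(f"unknown distance {distance!r}")
    labels = np.array([model.classes[i] for i in scores.argmax(axis=1)])
    out = pd.DataFrame(scores, columns=[str(c) for c in model.classes])
    return out, labels


def roc_auc(scores, labels) -> tuple[float, float]:
    """AUC as the Mann-Whitney U statistic, with the tie-corrected Wilcoxon p.

    ``labels`` are binary (positive class = the larger value).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = scores[labels == levels[1]]
    neg = scores[labels == levels[0]]
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = res.statistic / (len(pos) * len(neg))
    return float(auc), float(res.pvalue)


def per_feature_auc(log_table: pd.DataFrame, labels) -> pd.DataFrame:
    """roc_auc applied to each feature column, with a BH-adjusted column."""
    rows = []
    for feat in log_table.columns:
        auc, p = roc_auc(log_table[feat].to_numpy(), labels)
        rows.append({"feature": feat, "auc": auc, "p": p})
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("auc", ascending=False)


@dataclass
class MultiblockModel:
    block_names: list
    classes: list
    loadings: dict  # block -> p_b x ncomp
    scores: dict  # block -> n x ncomp
    y_scores: dict  # block -> n x ncomp (per-block outcome variates)
    design: pd.DataFrame
    pair_correlations: pd.DataFrame  # per component, per block pair
    objective_trace: list  # per component, the objective value per sweep
    consensus_scores: np.ndarray  # averaged block variates


def diablo_fit(
    blocks: dict,
    y: Sequence,
    design: Optional[pd.DataFrame] = None,
    ncomp: int = 2,
    keep_x: Optional[dict] = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> MultiblockModel:
    """Multiblock sparse discriminant integration across row-matched omics blocks.

    ``design`` is the symmetric, zero-diagonal block-coupling matrix in [0, 1];
    ``keep_x[block]`` is a per-component list of nonzero loading counts. The
    alternating updates keep the objective non-decreasing; per-pair variate
    correlations are reported per component.
    """
    names = list(blocks)
    mats = {}
    n_ref = None
    index_ref = None
    for b in names:
        Xb = blocks[b]
        if isinstance(Xb, pd.DataFrame):
            if index_ref is None:
                index_ref = Xb.index
            elif not Xb.index.equals(index_ref):
                raise ValueError(f"block {b!r} samples do not match the other blocks")
            Xb = Xb.to_numpy(dtype=float)
        Xb = np.asarray(Xb, dtype=float)
        if n_ref is None:
            n_ref = Xb.shape[0]
        elif Xb.shape[0] != n_ref:
            raise ValueError(f"block {b!r} has {Xb.shape[0]} samples, expected {n_ref}")
        mean, sd = Xb.mean(axis=0), Xb.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        mats[b] = (Xb - mean) / sd
    Ydum, classes = _dummy(y)
    Yc = Ydum - Ydum.mean(axis=0)
    if design is None:
        design = pd.DataFrame(1.0, index=names, columns=names)
        np.fill_diagonal(design.values, 0.0)
    else:
        design = design.loc[names, names]
        if not np.allclose(design.values, design.values.T) or np.any(np.diag(design.values) != 0):
            raise ValueError("design must be symmetric with zero diagonal")
    keep_x = keep_x or {}

    n = n_ref
    loadings = {b: np.zeros((mats[b].shape[1], ncomp)) for b in names}
    scores = {b: np.zeros((n, ncomp)) for b in names}
    y_scores = {b: np.zeros((n, ncomp)) for b in names}
    objective_trace: list = []
    Xd = {b: mats[b].copy() for b in names}
    pair_rows = []
    for h in range(ncomp):
        w = {}
        u = {}
        t = {}
        for b in names:
            M = Xd[b].T @ Yc
            sv = np.linalg.svd(M, full_matrices=False)
            w[b] = sv[0][:, 0]
            t[b] = Xd[b] @ w[b]
            uq = Yc.T @ t[b]
            u[b] = uq / (np.linalg.norm(uq) or 1.0)

        def objective():
            val = 0.0
            for i, b in enumerate(names):
                val += (t[b] @ (Yc @ u[b])) / (n - 1)
                for c in names[i + 1:]:
                    val += design.loc[b, c] * (t[b] @ t[c]) / (n - 1)
            return val

        comp_trace: list = []
        prev_obj = -np.inf
        for it in range(max_iter):
            for b in names:
                target = Yc @ u[b]
                for c in names:
                    if c != b:
                        target = target + design.loc[b, c] * t[c]
                w_raw = Xd[b].T @ target
                kb = keep_x.get(b)
                if kb is not None:
                    k_h = kb[h] if h < len(kb) else kb[-1]
                    w_new = _soft_threshold_keep(w_raw, int(k_h))
                else:
                    w_new = w_raw
                nw = np.linalg.norm(w_new)
                if nw == 0:
                    w_new, nw = w_raw, np.linalg.norm(w_raw)
                w[b] = w_new / nw
                t[b] = Xd[b] @ w[b]
                uq = Yc.T @ t[b]
                u[b] = uq / (np.linalg.norm(uq) or 1.0)
            obj = objective()
            comp_trace.append(obj)
            if abs(obj - prev_obj) < tol * max(1.0, abs(obj)):
                break
            prev_obj = obj
        objective_trace.append(comp_trace)
        for i, b in enumerate(names):
            loadings[b][:, h] = w[b]
            scores[b][:, h] = t[b]
            y_scores[b][:, h] = Yc @ u[b]
            for c in names[i + 1:]:
                r = np.corrcoef(t[b], t[c])[0, 1]
                pair_rows.append({"component": h + 1, "block_a": b, "block_b": c, "r": r})
            # deflate block by its own variate
            tt = t[b] @ t[b]
            if tt > 0:
                p_load = Xd[b].T @ t[b] / tt
                Xd[b] = Xd[b] - np.outer(t[b], p_load)
    consensus = np.mean([scores[b] for b in names], axis=0)
    return MultiblockModel(
        block_names=names,
        classes=classes,
        loadings=loadings,
        scores=scores,
        y_scores=y_scores,
        design=design,
        pair_correlations=pd.DataFrame(pair_rows),
        objective_trace=objective_trace,
        consensus_scores=consensus,
    )


@dataclass
class RelevanceNetwork:
    nodes: pd.DataFrame  # node, node_type
    edges: pd.DataFrame  # source, target, source_type, target_type, r
    cutoff: float


def relevance_network(node_tables: dict, cutoff: float = 0.7) -> RelevanceNetwork:
    """Correlation network between typed node sets on matched samples.

    ``node_tables`` maps a node type (e.g. 'lipid_module', 'protein_module',
    'clinical') to a samples x nodes DataFrame. Edges connect cross-type node
    pairs with |Pearson r| > cutoff; the edge list is symmetric-deduplicated.
    """
    types = list(node_tables)
    index = None
    for t in types:
        if index is None:
            index = node_tables[t].index
        elif not node_tables[t].index.equals(index):
            raise ValueError(f"samples of {t!r} do not match")
    node_rows = []
    for t in types:
        for col in node_tables[t].columns:
            node_rows.append({"node": col, "node_type": t})
    edge_rows = []
    for i, ta in enumerate(types):
        for tb in types[i + 1:]:
            A, B = node_tables[ta], node_tables[tb]
            for ca in A.columns:
                for cb in B.columns:
                    r, _, _ = pearson_with_student_p(
                        A[ca].to_numpy(dtype=float), B[cb].to_numpy(dtype=float)
                    )
                    if np.isfinite(r) and abs(r) > cutoff:
                        edge_rows.append(
                            {"source": ca, "target": cb, "source_type": ta,
                             "target_type": tb, "r": r}
                        )
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "source_type", "target_type", "r"])
    return RelevanceNetwork(pd.DataFrame(node_rows), edges, cutoff)


def pairwise_assoc(
    lipids: pd.DataFrame,
    proteins: pd.DataFrame,
    cor_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Pairwise lipid-protein association edges.

    The association of a single lipid with a protein via one-component PLS
    equals their Pearson correlation; edges are retained at |r| > cor_cutoff
    and Student asymptotic p < p_cutoff.
    """
    if not lipids.index.equals(proteins.index):
        raise ValueError("lipid and protein samples must match")
    rows = []
    for lip in lipids.columns:
        x = lipids[lip].to_numpy(dtype=float)
        for prot in proteins.columns:
            r, p, n = pearson_with_student_p(x, proteins[prot].to_numpy(dtype=float))
            if np.isfinite(r) and abs(r) > cor_cutoff and p < p_cutoff:
                rows.append({"lipid": lip, "protein": prot, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows, columns=["lipid", "protein", "r", "p", "n"])


def geneset_ora(
    query: Iterable[str],
    gene_sets: dict,
    background: Iterable[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in user-supplied sets.

    p is the upper-tail probability of observing at least the overlap;
    correction is 'bonferroni' or 'bh'; -log10 adjusted p is reported.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    bg = set(background)
    q = set(query)
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    if not q:
        return pd.DataFrame(columns=["set", "k", "n", "K", "N", "p", "p_adj", "neg_log10_p_adj"])
    N, n = len(bg), len(q)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & bg)
        if K == 0:
            continue
        k = len(set(members) & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "n": n, "K": K, "N": N, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    else:
        out["p_adj"] = bh_fdr(out["p"].to_numpy())
    out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out.sort_values("p").reset_index(drop=True)
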