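"""Signed weighted lipid co-expression network analysis.

Implements the weighted-network workflow: soft-threshold selection by
scale-free topology fit, signed adjacency a_ij = ((1 + cor_ij)/2)^beta,
topological overlap with component-wise minimum overlap, average-linkage
hierarchical module detection with a static tree cut plus recursive
branch splitting, module eigenlipids (first principal components), module
membership (kME), and Pearson module-trait association with the Student
asymptotic p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    correlation: str = "pearson"  # or "bicor"
    power: Optional[int] = None  # None: choose via pick_soft_threshold
    network_type: str = "signed"
    cut_height: float = 0.97
    deep_split: int = 3
    min_module_size: int = 2
    scale_free_target_r2: float = 0.9
    bicor_c: float = 9.0
    #: a cluster only becomes a module if its mean intra dissTOM is below this;
    #: rejects incohesive "clusters" that pure-noise data forms under the static cut
    module_cohesion: float = 0.75
    #: ... and if its mean dissimilarity to non-members exceeds its intra mean
    #: by this ratio; rejects the diffuse background blob that shares the
    #: topological baseline instead of genuine co-expression
    module_separation: float = 1.3
    #: soft-threshold fallback never selects powers whose mean connectivity
    #: drops below this (guards against degenerate argmax-R2 solutions)
    min_mean_connectivity: float = 2.0

    def __post_init__(self):
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be 0-4")


def _bicor(X: np.ndarray, c: float = 9.0) -> np.ndarray:
    """Biweight midcorrelation (Tukey biweight, tuning constant c)."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    mad[mad == 0] = 1e-12
    u = (X - med) / (c * mad)
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    xt = (X - med) * w
    norm = np.sqrt((xt**2).sum(axis=0))
    norm[norm == 0] = 1e-12
    xt = xt / norm
    return np.clip(xt.T @ xt, -1.0, 1.0)


def feature_correlation(data: pd.DataFrame, config: NetworkConfig) -> np.ndarray:
    X = data.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant features present")
    if config.correlation == "pearson":
        return np.clip(np.corrcoef(X, rowvar=False), -1.0, 1.0)
    if config.correlation == "bicor":
        return _bicor(X, config.bicor_c)
    raise ValueError(f"unknown correlation {config.correlation!r}")


def signed_adjacency(cor: np.ndarray, power: int) -> np.ndarray:
    a = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) against log10 k over connectivity bins."""
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.array(
        [k[(k >= edges[i]) & (k <= edges[i + 1])].mean() if counts[i] else np.nan
         for i in range(n_bins)]
    )
    ok = (counts > 0) & (centers > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins")
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts.sum())
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(r**2), float(slope)


def pick_soft_threshold(
    data: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    config: Optional[NetworkConfig] = None,
) -> tuple[pd.DataFrame, int]:
    """Scale-free fit index and mean connectivity per candidate power.

    Selects the smallest power whose fit R^2 (with a negative slope) reaches
    the target; falls back to the argmax R^2 with a warning.
    """
    config = config or NetworkConfig()
    if data.shape[1] < 20:
        raise ValueError("need at least 20 features for topology fitting")
    powers = list(powers)
    if len(powers) == 1:
        cor = feature_correlation(data, config)
        a = signed_adjacency(cor, powers[0])
        k = a.sum(axis=0) - 1
        try:
            r2, slope = scale_free_fit(k)
        except ValueError:
            r2, slope = np.nan, np.nan
        table = pd.DataFrame(
            {"power": powers, "r2": [r2], "slope": [slope], "mean_k": [k.mean()]}
        )
        return table, powers[0]
    cor = feature_correlation(data, config)
    rows = []
    for beta in powers:
        a = signed_adjacency(cor, beta)
        k = a.sum(axis=0) - 1
        r2, slope = scale_free_fit(k)
        rows.append({"power": beta, "r2": r2, "slope": slope, "mean_k": k.mean()})
    table = pd.DataFrame(rows)
    usable = table[(table["slope"] < 0) & (table["r2"] >= config.scale_free_target_r2)]
    if len(usable):
        selected = int(usable["power"].iloc[0])
    else:
        connected = table[table["mean_k"] >= config.min_mean_connectivity]
        pool = connected if len(connected) else table
        selected = int(pool.loc[pool["r2"].idxmax(), "power"])
        logger.warning(
            "no power reached scale-free R2 target %.2f; using argmax R2 among "
            "adequately connected powers (power %d)",
            config.scale_free_target_r2,
            selected,
        )
    return table, selected


def build_tom(data: pd.DataFrame, config: Optional[NetworkConfig] = None) -> pd.DataFrame:
    """Topological-overlap dissimilarity of the signed network.

    TOM_ij = (sum_u min(a_iu, a_uj) + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with the sum over u != i, j and k the intramodular connectivity; returns
    dissTOM = 1 - TOM with zero diagonal.
    """
    config = config or NetworkConfig()
    if data.isna().any().any():
        raise ValueError("missing values in the expression matrix")
    beta = config.power
    if beta is None:
        _, beta = pick_soft_threshold(data, config=config)
    cor = feature_correlation(data, config)
    a = signed_adjacency(cor, beta)
    p = a.shape[0]
    overlap = np.zeros_like(a)
    for u in range(p):
        col = a[:, u]
        overlap += np.minimum(col[:, None], col[None, :])
    # remove the u = i and u = j terms (each contributes min(1, a_ij) = a_ij)
    overlap -= 2 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum(k[:, None], k[None, :]) + 1.0 - a
    tom = (overlap + a) / denom
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    return pd.DataFrame(np.clip(diss, 0.0, 1.0), index=data.columns, columns=data.columns)


# deep_split -> minimum relative merge-height gap that justifies re-cutting a branch
_SPLIT_GAP = {0: np.inf, 1: 0.40, 2: 0.20, 3: 0.10, 4: 0.05}


def _gap_split(
    members: np.ndarray, diss: np.ndarray, gap_frac: float, min_size: int
) -> list[np.ndarray]:
    """Recursively re-cut a branch at its largest relative merge-height gap.

    Sorted merge heights of a homogeneous cluster rise smoothly; a relative
    gap of at least ``gap_frac`` marks the transition from within-module
    merges to bridge merges, and the branch is re-cut midway through the
    largest such gap. Parts are split recursively; over-splitting is healed
    later by the fragment-merge step.
    """
    if len(members) < max(3, min_size) or not np.isfinite(gap_frac):
        return [members]
    sub = diss[np.ix_(members, members)]
    Zs = linkage(squareform(sub, checks=False), method="average")
    h = np.sort(Zs[:, 2])
    gaps = np.diff(h)
    if len(gaps) == 0:
        return [members]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(h[1:] > 0, gaps / h[1:], 0.0)
    i = int(np.argmax(rel))
    if rel[i] < gap_frac:
        return [members]
    labels = fcluster(Zs, t=(h[i] + h[i + 1]) / 2.0, criterion="distance")
    parts = [members[labels == lab] for lab in np.unique(labels)]
    if len(parts) < 2:
        return [members]
    out = []
    for pt in parts:
        out.extend(_gap_split(pt, diss, gap_frac, min_size))
    return out


def _intra_diss(c: np.ndarray, diss: np.ndarray) -> float:
    if len(c) < 2:
        return 0.0
    sub = diss[np.ix_(c, c)]
    return float(sub[np.triu_indices(len(c), 1)].mean())


def _merge_modules(
    modules: list[np.ndarray], diss: np.ndarray, slack: float = 0.10
) -> list[np.ndarray]:
    """Merge accepted modules that are fragments of one another.

    Two modules merge when their mean cross-dissimilarity is within ``slack``
    of the looser one's intra mean — true for pieces of one split module,
    false for distinct modules whose cross-dissimilarity sits at the
    background level.
    """
    work = [c.copy() for c in modules]
    merged = True
    while merged and len(work) > 1:
        merged = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                cross = float(diss[np.ix_(work[i], work[j])].mean())
                if cross < max(_intra_diss(work[i], diss), _intra_diss(work[j], diss)) + slack:
                    work[i] = np.concatenate([work[i], work[j]])
                    del work[j]
                    merged = True
                    break
            if merged:
                break
    return work


def detect_modules(diss_tom: pd.DataFrame, config: Optional[NetworkConfig] = None) -> pd.Series:
    """Assign features to co-expression modules from the TOM dissimilarity.

    Average-linkage hierarchical clustering, static cut at ``cut_height``,
    then recursive splitting of branches whose top merge-height gap exceeds
    the ``deep_split`` granularity. Clusters below ``min_module_size`` are
    merged into the nearest module (mean dissTOM) when close enough, else
    left unassigned (module 0). Module ids are ordered by decreasing size.
    """
    config = config or NetworkConfig()
    D = diss_tom.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity must be square and symmetric")
    p = D.shape[0]
    Z = linkage(squareform(D, checks=False), method="average")
    initial = fcluster(Z, t=config.cut_height, criterion="distance")
    gap = _SPLIT_GAP[config.deep_split]
    clusters: list[np.ndarray] = []
    for lab in np.unique(initial):
        members = np.flatnonzero(initial == lab)
        if len(members) == 1 or config.deep_split == 0:
            clusters.append(members)
        else:
            clusters.extend(_gap_split(members, D, gap, config.min_module_size))

    def accept(c: np.ndarray) -> bool:
        if len(c) < config.min_module_size:
            return False
        intra = _intra_diss(c, D)
        if intra >= config.module_cohesion:
            return False
        rest = np.setdiff1d(np.arange(p), c)
        if len(rest) == 0:
            return True
        cross = float(D[np.ix_(c, rest)].mean())
        return cross >= config.module_separation * max(intra, 1e-12)

    modules = _merge_modules([c for c in clusters if accept(c)], D)
    rejected = [c for c in clusters if not accept(c)]
    labels = np.zeros(p, dtype=int)
    modules.sort(key=len, reverse=True)
    for mid, members in enumerate(modules, start=1):
        labels[members] = mid
    # attach leftovers only when they sit inside a module's own spread
    for c in rejected:
        if not modules:
            break
        cross = [float(D[np.ix_(c, m)].mean()) for m in modules]
        j = int(np.argmin(cross))
        if cross[j] < _intra_diss(modules[j], D) + 0.10:
            labels[c] = j + 1
    # re-rank ids by final size
    sizes = pd.Series(labels[labels > 0]).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = np.array([remap.get(l, 0) for l in labels])
    return pd.Series(labels, index=diss_tom.index, name="module")


@dataclass
class ModuleSet:
    labels: pd.Series  # feature -> module id (0 = unassigned)
    eigenlipids: pd.DataFrame  # samples x modules ("M1", ...), unit variance
    variance_explained: pd.Series
    kme: pd.DataFrame  # features x modules

    def module_members(self, module_id: int) -> list:
        return list(self.labels.index[self.labels == module_id])

    def hubs(self, module_id: int, mm_threshold: float = 0.60) -> list:
        """Hub lipids of a module: own-module membership kME above threshold."""
        col = f"M{module_id}"
        members = self.module_members(module_id)
        k = self.kme.loc[members, col]
        return list(k.index[k > mm_threshold])


def eigenlipids(data: pd.DataFrame, labels: pd.Series) -> ModuleSet:
    """Module eigenlipids: first principal component of each module's standardized profiles.

    ME columns are scaled to unit variance and sign-aligned so that their
    correlation with the module's mean standardized profile is positive.
    kME is the Pearson correlation of every feature with every ME.
    """
    labels = labels.loc[data.columns]
    X = data.to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    me_cols = {}
    ve = {}
    for mid in sorted(set(labels) - {0}):
        members = np.flatnonzero((labels == mid).to_numpy())
        sub = Xs[:, members]
        if len(members) == 1:
            scores = sub[:, 0]
            ve[f"M{mid}"] = 1.0
        else:
            u, s, vt = np.linalg.svd(sub - sub.mean(axis=0), full_matrices=False)
            scores = u[:, 0] * s[0]
            ve[f"M{mid}"] = float(s[0] ** 2 / (s**2).sum())
        if np.corrcoef(scores, sub.mean(axis=1))[0, 1] < 0:
            scores = -scores
        me_cols[f"M{mid}"] = scores / scores.std(ddof=1)
    me = pd.DataFrame(me_cols, index=data.index)
    if me.empty:
        raise ValueError("no assigned modules")
    kme = pd.DataFrame(
        np.corrcoef(Xs, me.to_numpy(), rowvar=False)[: Xs.shape[1], Xs.shape[1]:],
        index=data.columns,
        columns=me.columns,
    )
    return ModuleSet(labels, me, pd.Series(ve), kme)


def pearson_with_student_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with the Student asymptotic two-sided p."""
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0), n


def module_trait_assoc(me: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every module eigenlipid with every clinical trait."""
    traits = traits.loc[me.index]
    rows = []
    for mod in me.columns:
        for trait in traits.columns:
            r, p, n = pearson_with_student_p(
                me[mod].to_numpy(dtype=float), traits[trait].to_numpy(dtype=float)
            )
            rows.append({"module": mod, "trait": trait, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def remove_outlier_samples(
    data: pd.DataFrame, z_threshold: float = 3.0
) -> tuple[pd.Index, pd.DataFrame]:
    """Flag samples whose standardized Euclidean distance to the centroid is an outlier.

    Distances are converted to robust z-scores (median/MAD); samples above
    ``z_threshold`` are removed. Returns (retained index, report).
    """
    if data.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    d = np.sqrt((Xs**2).sum(axis=1))
    med = np.median(d)
    mad = np.median(np.abs(d - med)) * 1.4826
    z = (d - med) / mad if mad > 0 else np.zeros_like(d)
    flagged = z > z_threshold
    report = pd.DataFrame({"distance": d, "robust_z": z, "outlier": flagged}, index=data.index)
    return data.index[~flagged], report
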