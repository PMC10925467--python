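"""Feature filtering, QC-pool drift normalization, covariate screening, class aggregation.

The drift correction follows the QC-pool regression strategy of systematic-error
removal in large-run untargeted assays: for every lipid feature a random-forest
model is trained on the QC-pool injections to predict that feature's systematic
component from injection order plus the k most QC-correlated other features;
study samples are divided by the predicted component and rescaled to the
feature's QC median. When too few QC pools are available the correction falls
back to a LOESS fit of QC signal against injection order per batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from statsmodels.multivariate.manova import MANOVA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .chem import LipidParseError, parse_lipid_name

logger = logging.getLogger(__name__)

DEFAULT_GRADES = frozenset({"A", "B", "C"})


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with per-feature QC metrics and run metadata.

    ``abundance``: DataFrame indexed by sample_id, columns = feature names,
    non-negative, NaN = missing. ``feature_meta``: per-feature ``snr``,
    ``peak_quality``, ``id_grade``, ``is_internal_standard``. ``sample_meta``:
    per-sample ``is_qc_pool``, ``batch``, ``injection_order``.
    """

    abundance: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.abundance.index.equals(self.sample_meta.index):
            raise ValueError("abundance and sample_meta indices differ")
        if not self.abundance.columns.equals(pd.Index(self.feature_meta.index)):
            raise ValueError("abundance columns and feature_meta index differ")
        vals = self.abundance.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative abundances")
        for batch, grp in self.sample_meta.groupby("batch"):
            if grp["injection_order"].duplicated().any():
                raise ValueError(f"duplicate injection_order in batch {batch!r}")

    @property
    def qc_mask(self) -> pd.Series:
        return self.sample_meta["is_qc_pool"].astype(bool)

    def study_samples(self) -> pd.DataFrame:
        return self.abundance.loc[~self.qc_mask]

    def qc_samples(self) -> pd.DataFrame:
        return self.abundance.loc[self.qc_mask]

    def subset_features(self, features: Iterable[str]) -> "FeatureTable":
        features = list(features)
        return FeatureTable(
            self.abundance[features].copy(),
            self.feature_meta.loc[features].copy(),
            self.sample_meta.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.abundance.copy(), self.feature_meta.copy(), self.sample_meta.copy()
        )


@dataclass
class FilterResult:
    table: FeatureTable
    internal_standards: pd.DataFrame  # abundance of IS features (side table)
    n_input: int
    n_retained: int


def filter_features(
    table: FeatureTable,
    snr_min: float = 3.0,
    quality_min: float = 0.6,
    grades: frozenset = DEFAULT_GRADES,
) -> FilterResult:
    """Retain features with snr > snr_min, peak_quality > quality_min, grade in grades.

    Internal standards are excluded from the analysis set but returned in a
    side table. Strict inequalities, matching "greater than" thresholds.
    """
    if not np.isfinite(snr_min) or not np.isfinite(quality_min):
        raise ValueError("thresholds must be finite")
    meta = table.feature_meta
    keep = (
        (meta["snr"] > snr_min)
        & (meta["peak_quality"] > quality_min)
        & meta["id_grade"].isin(grades)
        & ~meta["is_internal_standard"].astype(bool)
    )
    standards = table.abundance.loc[:, meta["is_internal_standard"].astype(bool)].copy()
    retained = list(meta.index[keep])
    if not retained:
        logger.warning("feature filter retained no features")
    return FilterResult(
        table=table.subset_features(retained),
        internal_standards=standards,
        n_input=len(meta),
        n_retained=len(retained),
    )


def compute_rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sample sd / mean.

    Returns NaN with fewer than 2 non-missing values or zero mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return 100.0 * v.std(ddof=1) / m


def handle_missing(table: FeatureTable, max_missing: float = 0.20) -> FeatureTable:
    """Drop features with > max_missing fraction missing; impute the rest as half the feature minimum."""
    frac = table.abundance.isna().mean()
    keep = list(frac.index[frac <= max_missing])
    dropped = len(frac) - len(keep)
    if dropped:
        logger.info("dropped %d features exceeding %.0f%% missingness", dropped, 100 * max_missing)
    out = table.subset_features(keep)
    ab = out.abundance
    fill = ab.min() / 2.0
    out.abundance = ab.fillna(fill)
    return out


@dataclass
class DriftParams:
    n_predictors: int = 10
    n_trees: int = 100
    min_qc: int = 5
    seed: int = 0
    loess_frac: float = 0.75


@dataclass
class NormalizationReport:
    rsd_before: pd.Series
    rsd_after: pd.Series
    method: str
    params: dict

    @property
    def median_rsd_before(self) -> float:
        return float(np.nanmedian(self.rsd_before))

    @property
    def median_rsd_after(self) -> float:
        return float(np.nanmedian(self.rsd_after))

    def n_below(self, threshold: float = 50.0) -> tuple[int, int]:
        """Count of features with QC RSD below threshold, (before, after)."""
        return (
            int((self.rsd_before < threshold).sum()),
            int((self.rsd_after < threshold).sum()),
        )

    def to_dict(self) -> dict:
        before, after = self.n_below()
        return {
            "method": self.method,
            "params": self.params,
            "median_qc_rsd_before": self.median_rsd_before,
            "median_qc_rsd_after": self.median_rsd_after,
            "n_features_rsd_lt_50_before": before,
            "n_features_rsd_lt_50_after": after,
        }


def _rf_correct_batch(
    ab: pd.DataFrame, qc: np.ndarray, order: np.ndarray, params: DriftParams
) -> pd.DataFrame:
    """QC-regression correction of one batch; returns corrected abundances."""
    X = np.log2(ab.to_numpy(dtype=float) + 1e-12)
    n, p = X.shape
    qc_idx = np.flatnonzero(qc)
    corrected = np.empty_like(X)
    # correlations among features on QC pools select each feature's predictors
    Xq = X[qc_idx]
    Xq_c = Xq - Xq.mean(axis=0)
    sd = Xq_c.std(axis=0)
    sd[sd == 0] = 1.0
    corr = (Xq_c / sd).T @ (Xq_c / sd) / max(len(qc_idx) - 1, 1)
    rng = np.random.RandomState(params.seed)
    for j in range(p):
        c = np.abs(corr[j].copy())
        c[j] = -np.inf
        k = min(params.n_predictors, p - 1)
        top = np.argpartition(-c, k - 1)[:k] if k > 0 else np.array([], dtype=int)
        feats = np.column_stack([order.astype(float), X[:, top]])
        model = RandomForestRegressor(
            n_estimators=params.n_trees,
            random_state=rng.randint(0, 2**31 - 1),
            n_jobs=1,
        )
        model.fit(feats[qc_idx], X[qc_idx, j])
        pred = model.predict(feats)
        qc_med = np.median(X[qc_idx, j])
        corrected[:, j] = X[:, j] - pred + qc_med
    out = pd.DataFrame(2.0 ** corrected, index=ab.index, columns=ab.columns)
    return out


def _loess_correct_batch(
    ab: pd.DataFrame, qc: np.ndarray, order: np.ndarray, frac: float
) -> pd.DataFrame:
    X = np.log2(ab.to_numpy(dtype=float) + 1e-12)
    qc_idx = np.flatnonzero(qc)
    corrected = X.copy()
    for j in range(X.shape[1]):
        if len(qc_idx) >= 2:
            smoothed = lowess(X[qc_idx, j], order[qc_idx].astype(float), frac=frac)
            # interpolate the QC trend across the whole run (edges clamped)
            fit = np.interp(order.astype(float), smoothed[:, 0], smoothed[:, 1])
            qc_med = np.median(X[qc_idx, j])
            corrected[:, j] = X[:, j] - fit + qc_med
    return pd.DataFrame(2.0 ** corrected, index=ab.index, columns=ab.columns)


def qc_drift_correct(
    table: FeatureTable, params: Optional[DriftParams] = None
) -> tuple[FeatureTable, NormalizationReport]:
    """Remove injection-order and cross-feature systematic variation using QC pools.

    Per batch, each feature's systematic component is modelled on the QC pools
    (random forest on injection order + the k most-correlated other features)
    and divided out of every sample, rescaled to the feature's QC median; with
    fewer than ``min_qc`` QC pools the model falls back to LOESS on injection
    order. Batches are median-centered afterwards. Sample and feature counts
    are preserved and abundances stay non-negative.
    """
    params = params or DriftParams()
    if table.abundance.isna().any().any():
        raise ValueError("missing abundances; run handle_missing first")
    ab = table.abundance
    qc_all = table.qc_mask.to_numpy()
    if qc_all.sum() < 2:
        raise ValueError("need at least 2 QC pool injections")
    rsd_before = table.qc_samples().apply(compute_rsd)

    pieces = []
    method = "rf_qc_regression"
    for batch, meta in table.sample_meta.groupby("batch"):
        idx = meta.index
        sub = ab.loc[idx]
        qc = meta["is_qc_pool"].to_numpy(dtype=bool)
        order = meta["injection_order"].to_numpy()
        if qc.sum() >= params.min_qc:
            pieces.append(_rf_correct_batch(sub, qc, order, params))
        else:
            logger.warning(
                "batch %r has %d QC pools (<%d): LOESS fallback", batch, int(qc.sum()), params.min_qc
            )
            method = "loess_fallback"
            pieces.append(_loess_correct_batch(sub, qc, order, params.loess_frac))
    corrected = pd.concat(pieces).loc[ab.index]

    # median-center batches on the log scale so batch medians align globally
    if table.sample_meta["batch"].nunique() > 1:
        log = np.log2(corrected + 1e-12)
        global_med = log.median()
        for batch, meta in table.sample_meta.groupby("batch"):
            shift = global_med - log.loc[meta.index].median()
            log.loc[meta.index] = log.loc[meta.index] + shift
        corrected = 2.0 ** log

    out = FeatureTable(corrected, table.feature_meta.copy(), table.sample_meta.copy())
    rsd_after = out.qc_samples().apply(compute_rsd)
    report = NormalizationReport(
        rsd_before=rsd_before,
        rsd_after=rsd_after,
        method=method,
        params={
            "n_predictors": params.n_predictors,
            "n_trees": params.n_trees,
            "min_qc": params.min_qc,
            "seed": params.seed,
        },
    )
    return out, report


def log2_transform(table: FeatureTable, offset: float = 0.0) -> pd.DataFrame:
    """log2 abundance matrix of the study (non-QC) samples."""
    return np.log2(table.study_samples() + offset)


def covariate_screen(
    log_table: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    max_components: int = 10,
) -> pd.Series:
    """One-way MANOVA (Pillai's trace) of the feature matrix on each covariate.

    When features outnumber samples the matrix is reduced to its top principal
    components first. Returns a p-value per covariate; covariates below
    ``alpha`` are flagged in the log (screening only — nothing is regressed out
    here).
    """
    if not log_table.index.equals(covariates.index):
        covariates = covariates.loc[log_table.index]
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete for all samples")
    Y = log_table.to_numpy(dtype=float)
    n = Y.shape[0]
    if Y.shape[1] >= n - len(covariates.columns) - 2 or Y.shape[1] > max_components:
        Yc = Y - Y.mean(axis=0)
        _, _, vt = np.linalg.svd(Yc, full_matrices=False)
        ncomp = min(max_components, n - len(covariates.columns) - 2, Y.shape[1])
        Y = Yc @ vt[:ncomp].T
    pvals = {}
    for cov in covariates.columns:
        x = covariates[cov]
        if x.nunique() < 2:
            raise ValueError(f"covariate {cov!r} has a single level")
        if x.dtype == object or str(x.dtype) == "category":
            exog = pd.get_dummies(x, drop_first=True).to_numpy(dtype=float)
        else:
            exog = x.to_numpy(dtype=float)[:, None]
        exog = np.column_stack([np.ones(len(x)), exog])
        mv = MANOVA(endog=Y, exog=exog)
        ncols = exog.shape[1] - 1
        contrast = np.zeros((ncols, exog.shape[1]))
        contrast[:, 1:] = np.eye(ncols)
        res = mv.mv_test(hypotheses=[(cov, contrast)])
        stat = res.results[cov]["stat"]
        pvals[cov] = float(stat.loc["Pillai's trace", "Pr > F"])
        if pvals[cov] < alpha:
            logger.info("covariate %r associated with lipidome (p=%.3g)", cov, pvals[cov])
    return pd.Series(pvals, name="manova_p")


RATIO_PAIRS = [("LPE", "PE"), ("LPC", "PC"), ("PC", "PE")]


@dataclass
class ClassAggregate:
    class_log2: pd.DataFrame  # samples x lipid classes, log2 of summed linear abundance
    ratios_log2: pd.DataFrame  # samples x ratio names, log2(numerator/denominator)
    composition_pct: pd.Series  # mean linear share per class, sums to 100


def aggregate_classes_and_ratios(
    log_table: pd.DataFrame, ratio_pairs=None
) -> ClassAggregate:
    """Aggregate species to lipid-class totals (linear-scale sum, then log2) and class ratios.

    Ratios (default LPE/PE, LPC/PC, PC/PE) are per-sample log2 differences of
    class totals; a missing denominator class yields a missing ratio.
    """
    ratio_pairs = ratio_pairs or RATIO_PAIRS
    classes: dict[str, list[str]] = {}
    for name in log_table.columns:
        try:
            cls = parse_lipid_name(name).lipid_class
        except LipidParseError:
            logger.warning("skipping unparseable species %r", name)
            continue
        classes.setdefault(cls, []).append(name)
    linear = 2.0 ** log_table
    class_linear = pd.DataFrame(
        {cls: linear[cols].sum(axis=1) for cls, cols in classes.items()}
    )
    class_log2 = np.log2(class_linear)
    ratios = {}
    for num, den in ratio_pairs:
        label = f"{num}/{den}"
        if num in class_log2 and den in class_log2:
            ratios[label] = class_log2[num] - class_log2[den]
        else:
            logger.warning("ratio %s skipped: class missing", label)
            ratios[label] = pd.Series(np.nan, index=class_log2.index)
    total = class_linear.sum(axis=1)
    composition = (class_linear.div(total, axis=0).mean() * 100.0).rename("pct")
    return ClassAggregate(class_log2, pd.DataFrame(ratios), composition)
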