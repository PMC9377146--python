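"""Untargeted LC-MS metabolomics preprocessing and analysis.

Processing order is fixed: prevalence filter -> KNN imputation -> IQR
filter -> log transform -> quantile normalization -> batch standardization.
Downstream: per-feature covariate linear models, the cholate:deoxycholate
log ratio, bile-acid 7a-dehydroxylation (bai) pathway aggregation from a
predicted-metagenome KO table, and microbe-metabolite residual Spearman
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import (DesignMatrix, TestResult, bh_adjust, residual_spearman,
                    wilcoxon_rank_sum)

logger = logging.getLogger(__name__)

#: KEGG orthologies of the bile-acid 7a-dehydroxylation (bai) operon
BAI_KOS = ("K15868", "K15869", "K15870", "K15871", "K15872", "K07007")


@dataclass
class MetaboliteTable:
    """Feature x sample intensity matrix with feature and sample annotations.

    ``intensities``: features (rows) x samples (columns); NaN marks missing.
    ``features``: per-feature mz (Th), rt (min), mode in {pos, neg}.
    ``batches``: per-sample batch label (optional).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame | None = None
    batches: pd.Series | None = None

    def __post_init__(self) -> None:
        # raw intensities are non-negative, but processed (log-scale)
        # tables reuse this container, so positivity is checked at the
        # transform steps rather than here
        if not self.intensities.index.is_unique:
            raise ValueError("feature ids must be unique")

    def _with(self, intensities: pd.DataFrame) -> "MetaboliteTable":
        feats = self.features.loc[intensities.index] if self.features is not None else None
        return MetaboliteTable(intensities, feats, self.batches)


def feature_prevalence_filter(
    m: MetaboliteTable, min_prevalence: float = 0.10
) -> MetaboliteTable:
    """Keep features observed in strictly more than ``min_prevalence`` of samples."""
    if not 0 < min_prevalence < 1:
        raise ValueError("min_prevalence must be in (0, 1)")
    prev = m.intensities.notna().mean(axis=1)
    keep = prev.index[prev > min_prevalence]
    if len(keep) == 0:
        raise ValueError("prevalence filter removed every feature")
    return m._with(m.intensities.loc[keep])


def knn_impute(m: MetaboliteTable, k: int = 10) -> MetaboliteTable:
    """Impute missing intensities from the k nearest features.

    A missing value of feature f in sample s becomes the unweighted mean, at
    s, of the k features closest to f by Euclidean distance over the samples
    where both features are observed; only features observed at s qualify as
    donors.  If fewer than k qualify those available are used; with no donor
    the feature's own observed mean is substituted (logged).
    """
    X = m.intensities.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if np.isnan(X).all(axis=1).any():
        bad = m.intensities.index[np.isnan(X).all(axis=1)].tolist()
        raise ValueError(f"features entirely missing: {bad[:5]}")
    obs = ~np.isnan(X)
    feat_means = np.nanmean(X, axis=1)
    out = X.copy()
    missing_rows = np.where(~obs.all(axis=1))[0]
    fallbacks = 0
    for i in missing_rows:
        # distances from feature i to all others over mutually observed samples
        shared = obs[i] & obs
        diffs = np.where(shared, X[i] - np.where(np.isnan(X), 0.0, X), np.nan)
        with np.errstate(invalid="ignore"):
            d2 = np.nansum(diffs**2, axis=1)
        n_shared = shared.sum(axis=1)
        dist = np.where(n_shared > 0, np.sqrt(d2), np.inf)
        dist[i] = np.inf
        for s in np.where(~obs[i])[0]:
            candidates = np.where(obs[:, s] & np.isfinite(dist))[0]
            if len(candidates) == 0:
                out[i, s] = feat_means[i]
                fallbacks += 1
                continue
            nearest = candidates[np.argsort(dist[candidates], kind="stable")[:k]]
            out[i, s] = X[nearest, s].mean()
    if fallbacks:
        logger.info("knn_impute: %d cells fell back to the feature mean", fallbacks)
    return m._with(pd.DataFrame(out, index=m.intensities.index,
                                columns=m.intensities.columns))


def iqr_filter(
    m: MetaboliteTable,
    keep_fraction: float | None = None,
    min_features_to_filter: int = 250,
    default_drop: float = 0.10,
) -> MetaboliteTable:
    """Drop the lowest-interquartile-range tail of features.

    Default rule: when more than ``min_features_to_filter`` features are
    present, the bottom ``default_drop`` fraction by IQR is removed;
    ``keep_fraction`` overrides the rule explicitly.
    """
    X = m.intensities
    if X.isna().any().any():
        raise ValueError("iqr_filter expects a complete (imputed) table")
    iqr = X.quantile(0.75, axis=1) - X.quantile(0.25, axis=1)
    if keep_fraction is None:
        keep_fraction = 1.0 - default_drop if X.shape[0] > min_features_to_filter else 1.0
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n_keep = max(int(np.ceil(keep_fraction * X.shape[0])), 1)
    keep = iqr.sort_values(ascending=False, kind="stable").index[:n_keep]
    keep = [f for f in X.index if f in set(keep)]  # preserve input order
    return m._with(X.loc[keep])


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (column) quantile normalization to the mean sorted profile.

    Ties receive the average of the tied reference quantiles; the operation
    is idempotent.
    """
    L = df.to_numpy(dtype=float)
    mean_profile = np.sort(L, axis=0).mean(axis=1)
    out = np.empty_like(L)
    for j in range(L.shape[1]):
        ranks = sps.rankdata(L[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, L.shape[0] + 1), mean_profile)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def log_quantile_normalize(m: MetaboliteTable) -> MetaboliteTable:
    """Natural-log transform then per-sample quantile normalization."""
    X = m.intensities.to_numpy(dtype=float)
    if np.isnan(X).any() or (X <= 0).any():
        bad = np.argwhere(~(X > 0))[0]
        raise ValueError(
            f"nonpositive or missing intensity at feature "
            f"{m.intensities.index[bad[0]]!r}, sample {m.intensities.columns[bad[1]]!r}"
        )
    normed = quantile_normalize(np.log(m.intensities))
    return m._with(normed)


def batch_standardize(m: MetaboliteTable, batches: pd.Series | None = None) -> MetaboliteTable:
    """Location-scale batch correction.

    Per feature, each batch is centered to the feature's grand mean and its
    standard deviation rescaled to the pooled (all-sample) value.  This is a
    deliberately simple standardization, not an empirical-Bayes method.
    """
    batches = batches if batches is not None else m.batches
    if batches is None:
        raise ValueError("no batch labels supplied")
    batches = batches.loc[m.intensities.columns]
    sizes = batches.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"batches with a single sample: {sizes.index[sizes < 2].tolist()}")
    X = m.intensities
    grand_mean = X.mean(axis=1)
    pooled_sd = X.std(axis=1, ddof=1)
    out = X.copy()
    for b in sizes.index:
        cols = batches.index[batches == b]
        sub = X[cols]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
        scaled = (sub.sub(mu, axis=0)).div(sd, axis=0).mul(pooled_sd, axis=0)
        out[cols] = scaled.add(grand_mean, axis=0).fillna(
            pd.DataFrame(np.tile(grand_mean.to_numpy()[:, None], (1, len(cols))),
                         index=X.index, columns=cols)
        )
    return m._with(out)


def preprocess(
    m: MetaboliteTable,
    min_prevalence: float = 0.10,
    k: int = 10,
    keep_fraction: float | None = None,
    correct_batch: bool = True,
) -> MetaboliteTable:
    """The full processing chain in its fixed order."""
    m = feature_prevalence_filter(m, min_prevalence)
    m = knn_impute(m, k=k)
    m = iqr_filter(m, keep_fraction=keep_fraction)
    m = log_quantile_normalize(m)
    if correct_batch and m.batches is not None and m.batches.nunique() > 1:
        m = batch_standardize(m)
    return m


def per_feature_models(
    m: MetaboliteTable, design: DesignMatrix, term: str
) -> pd.DataFrame:
    """Per-feature least-squares fits with a t-test on ``term`` and BH q.

    Vectorized across features: one design pseudo-inverse serves every fit.
    """
    term_cols = design.columns_for(term)
    if len(term_cols) != 1:
        raise ValueError("per_feature_models expects a single-column term")
    X = design.matrix.loc[m.intensities.columns].to_numpy(dtype=float)
    Y = m.intensities.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    j = list(design.matrix.columns).index(term_cols[0])
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[j] / se, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {"estimate": beta[j], "t": t, "p": pvals, "q": bh_adjust(pvals)},
        index=m.intensities.index,
    )


@dataclass
class BileRatioResult:
    log_ratio: pd.Series
    group_test: TestResult
    cd_mean: float
    control_mean: float


def bile_log_ratio(
    m: MetaboliteTable,
    cholate_id: str,
    deoxycholate_id: str,
    groups: pd.Series | None = None,
    cd_label: str = "CD",
    control_label: str = "nonIBD",
) -> BileRatioResult | pd.Series:
    """Per-sample ln(cholate / deoxycholate) with a CD-vs-control rank test.

    Uses the table as given (raw pre-normalization intensities by default,
    since the ratio is a within-sample quantity); pass a processed table to
    use normalized values instead.
    """
    for fid in (cholate_id, deoxycholate_id):
        if fid not in m.intensities.index:
            raise ValueError(f"feature {fid!r} not present in the table")
    ca = m.intensities.loc[cholate_id]
    dca = m.intensities.loc[deoxycholate_id]
    ok = ca.notna() & dca.notna()
    if (~ok).any():
        logger.info("bile_log_ratio: dropping %d samples with a missing bile feature",
                    int((~ok).sum()))
    ca, dca = ca[ok], dca[ok]
    if (ca <= 0).any() or (dca <= 0).any():
        raise ValueError("bile feature intensities must be positive")
    ratio = np.log(ca / dca).rename("log_cholate_deoxycholate")
    if groups is None:
        return ratio
    g = groups.loc[ratio.index]
    cd = ratio[g == cd_label].to_numpy()
    ctrl = ratio[g == control_label].to_numpy()
    test = wilcoxon_rank_sum(cd, ctrl)
    return BileRatioResult(
        log_ratio=ratio, group_test=test,
        cd_mean=float(cd.mean()), control_mean=float(ctrl.mean()),
    )


def aggregate_bai(ko: pd.DataFrame) -> pd.Series:
    """Per-sample summed relative abundance of the six bai-operon KOs.

    ``ko`` is KO x sample relative abundances.  KOs absent from the table
    contribute zero (logged); if none of the six is present this is an error.
    """
    present = [k for k in BAI_KOS if k in ko.index]
    if not present:
        raise ValueError(f"none of the bai KOs {BAI_KOS} present in the table")
    absent = sorted(set(BAI_KOS) - set(present))
    if absent:
        logger.info("aggregate_bai: KOs absent (contribute 0): %s", absent)
    return ko.loc[present].sum(axis=0).rename("bai_pathway")


def microbe_metabolite_correlations(
    microbe_residuals: pd.DataFrame,   # taxa x samples (NB deviance residuals)
    metabolite_residuals: pd.DataFrame,  # features x samples (OLS residuals)
    taxa: list | None = None,
    metabolites: list | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Spearman correlations of residuals with BH q-values.

    Returns a long-format frame (taxon, metabolite, rho, p, q, significant).
    Pairs with constant residuals are excluded (flagged upstream).
    """
    shared = [s for s in microbe_residuals.columns if s in metabolite_residuals.columns]
    if not shared:
        raise ValueError("no shared samples between the residual tables")
    taxa = list(taxa) if taxa is not None else list(microbe_residuals.index)
    metabolites = (list(metabolites) if metabolites is not None
                   else list(metabolite_residuals.index))
    rows = []
    for t in taxa:
        rt = microbe_residuals.loc[t, shared].to_numpy(dtype=float)
        for f in metabolites:
            rf = metabolite_residuals.loc[f, shared].to_numpy(dtype=float)
            if np.allclose(rt, rt[0]) or np.allclose(rf, rf[0]):
                continue
            rho, p = sps.spearmanr(rt, rf)
            rows.append((t, f, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["taxon", "metabolite", "rho", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < q_threshold
    return out
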