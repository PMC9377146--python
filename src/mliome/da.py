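"""Negative-binomial differential abundance and the dysbiosis index.

The workflow mirrors the standard count-based RNA-seq style analysis applied
to ASV tables: prevalence filtering, median-of-ratios size factors,
per-taxon negative-binomial dispersion estimation with shrinkage toward a
parametric mean-dispersion trend, Wald tests on log-linear model
coefficients, q-value significance filtering, and finally a per-sample
dysbiosis index (log ratio of summed relative abundances of
disease-enriched over disease-depleted taxa).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from scipy import stats as sps

from .diversity import CountTable
from .stats import DesignMatrix, storey_qvalues

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class DAResult:
    """Per-taxon differential-abundance results for one tested term."""

    table: pd.DataFrame  # log2fc, p, q, mean_norm_rel_abund, dispersion, converged
    term: str
    design_columns: list[str]

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["converged"]]


@dataclass
class TaxonSets:
    enriched: set
    depleted: set
    contrast: str = ""

    def __post_init__(self) -> None:
        overlap = self.enriched & self.depleted
        if overlap:
            raise ValueError(f"enriched and depleted overlap: {sorted(overlap)[:5]}")

    def swapped(self) -> "TaxonSets":
        return TaxonSets(enriched=set(self.depleted), depleted=set(self.enriched),
                         contrast=self.contrast + "-swapped")


@dataclass
class DysbiosisResult:
    values: pd.Series       # per-sample index, natural-log units
    sets: TaxonSets
    pseudocount: float


def prevalence_filter(table: CountTable, min_prevalence: float = 0.25) -> CountTable:
    """Keep taxa with nonzero counts in at least ``min_prevalence`` of samples.

    The boundary is inclusive: a taxon present in exactly the threshold
    fraction is retained ("present in less than 25%" is removed).
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    prev = (table.counts > 0).mean(axis=1)
    keep = prev.index[prev >= min_prevalence]
    if len(keep) == 0:
        raise ValueError("prevalence filter removed every taxon")
    return CountTable(table.counts.loc[keep], table.samples)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-taxon geometric mean over samples, computed on
    taxa with all-positive counts; if no such taxon exists the geometric
    means use positive entries only (logged fallback).
    """
    X = counts.to_numpy(dtype=float)
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        ref = X[all_pos]
        log_gm = np.log(ref).mean(axis=1)
        log_ratios = np.log(ref) - log_gm[:, None]
    else:
        logger.info("size_factors: no all-positive taxon; using positive entries only")
        with np.errstate(divide="ignore"):
            logX = np.where(X > 0, np.log(X), np.nan)
        log_gm = np.nanmean(logX, axis=1)
        log_ratios = logX - log_gm[:, None]
    log_sf = np.nanmedian(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _nb_negloglik(alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    """Negative log-likelihood of NB(mu, alpha) with Var = mu + alpha*mu^2."""
    r = 1.0 / alpha
    ll = (
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    )
    return -float(ll.sum())


def _fit_taxon_mu(y: np.ndarray, X: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Fitted means from a Poisson GLM (consistent for the NB mean)."""
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit()
    return np.maximum(res.mu, 1e-8)


def _mle_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        lambda la: _nb_negloglik(np.exp(la), y, mu),
        bounds=(np.log(1e-8), np.log(50.0)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def fit_dispersions(
    counts: pd.DataFrame,
    design: DesignMatrix,
    sf: pd.Series,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-taxon NB dispersions with shrinkage toward a parametric trend.

    Per taxon, the dispersion is the maximum-likelihood estimate given
    Poisson-fitted means; a trend alpha(mu) = a0/mu + a1 is then fitted
    across taxa by least squares on the gene-wise estimates, and the final
    value is the geometric combination
    exp((1-w) log alpha_mle + w log alpha_trend) with w=``shrinkage_weight``.
    Taxa whose likelihood fit fails take the trend value and are flagged.
    """
    if not 0 <= shrinkage_weight <= 1:
        raise ValueError("shrinkage_weight must be in [0, 1]")
    X = design.matrix.loc[counts.columns].to_numpy(dtype=float)
    if counts.shape[1] <= X.shape[1]:
        raise ValueError("need more samples than design columns")
    offset = np.log(sf.loc[counts.columns].to_numpy(dtype=float))
    rows = []
    for taxon in counts.index:
        y = counts.loc[taxon].to_numpy(dtype=float)
        ok = True
        try:
            mu = _fit_taxon_mu(y, X, offset)
            alpha = _mle_dispersion(y, mu)
            mean_mu = float(mu.mean())
        except Exception:  # noqa: BLE001 - any numerical failure flags the taxon
            ok, alpha, mean_mu = False, np.nan, float(max(y.mean(), 1e-8))
        rows.append((taxon, alpha, mean_mu, ok))
    df = pd.DataFrame(rows, columns=["taxon", "alpha_mle", "mean_mu", "fit_ok"]).set_index("taxon")

    fit_df = df[df["fit_ok"] & (df["alpha_mle"] > 10 * DISPERSION_FLOOR)]
    if len(fit_df) >= 3:
        A = np.column_stack([1.0 / fit_df["mean_mu"], np.ones(len(fit_df))])
        coef, _ = optimize.nnls(A, fit_df["alpha_mle"].to_numpy())
        a0, a1 = coef
    else:
        a0, a1 = 0.0, float(np.nanmedian(df["alpha_mle"])) if df["fit_ok"].any() else 0.1
    trend = np.maximum(a0 / df["mean_mu"] + a1, DISPERSION_FLOOR)
    mle = np.maximum(df["alpha_mle"].fillna(trend), DISPERSION_FLOOR)
    w = shrinkage_weight
    final = np.exp((1 - w) * np.log(mle) + w * np.log(trend))
    df["alpha_trend"] = trend
    df["dispersion"] = np.maximum(final, DISPERSION_FLOOR)
    df.loc[~df["fit_ok"], "dispersion"] = trend[~df["fit_ok"]]
    return df


def mean_normalized_relative_abundance(counts: pd.DataFrame, sf: pd.Series) -> pd.Series:
    """Mean over samples of size-factor-normalized relative abundances."""
    norm = counts / sf.loc[counts.columns]
    rel = norm / norm.sum(axis=0)
    return rel.mean(axis=1)


def nb_wald_test(
    counts: pd.DataFrame,
    design: DesignMatrix,
    term: str,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    shrinkage_weight: float = 0.5,
) -> DAResult:
    """Per-taxon NB Wald test of ``term`` with log size-factor offset.

    Returns log2 fold changes (term coefficient / ln 2), two-sided Wald p,
    Storey q-values over converged taxa, mean normalized relative abundance,
    and the dispersion used.  Non-converged taxa are excluded from the
    q-value computation and flagged.
    """
    term_cols = design.columns_for(term)
    if len(term_cols) != 1:
        raise ValueError("nb_wald_test expects a single-column (binary or continuous) term")
    X_df = design.matrix.loc[counts.columns]
    if X_df[term_cols[0]].nunique() < 2:
        raise ValueError(f"term {term!r} is constant across samples")
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = fit_dispersions(counts, design, sf, shrinkage_weight)["dispersion"]
    X = X_df.to_numpy(dtype=float)
    offset = np.log(sf.loc[counts.columns].to_numpy(dtype=float))
    j = list(design.matrix.columns).index(term_cols[0])
    rows = []
    for taxon in counts.index:
        y = counts.loc[taxon].to_numpy(dtype=float)
        alpha = float(dispersions.loc[taxon])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-8)),
                    offset=offset,
                )
                res = model.fit(maxiter=100)
            beta = res.params[j]
            se = res.bse[j]
            converged = bool(res.converged) and np.isfinite(beta) and np.isfinite(se) and se > 0
        except Exception:  # noqa: BLE001
            beta, se, converged = np.nan, np.nan, False
        if converged:
            z = beta / se
            p = 2.0 * sps.norm.sf(abs(z))
            l2fc = beta / np.log(2.0)
        else:
            p, l2fc = np.nan, np.nan
        rows.append((taxon, l2fc, p, alpha, converged))
    out = pd.DataFrame(
        rows, columns=["taxon", "log2fc", "p", "dispersion", "converged"]
    ).set_index("taxon")
    out["mean_norm_rel_abund"] = mean_normalized_relative_abundance(counts, sf)
    out["q"] = np.nan
    ok = out["converged"]
    if ok.sum() == 0:
        raise ValueError("no taxon converged in the NB fit")
    if (~ok).any():
        logger.info("nb_wald_test: %d taxa failed to converge and are excluded from q",
                    int((~ok).sum()))
    out.loc[ok, "q"] = storey_qvalues(out.loc[ok, "p"].to_numpy())
    return DAResult(table=out, term=term, design_columns=list(design.matrix.columns))


def significant_sets(
    da: DAResult, q_threshold: float = 0.05, abund_threshold: float = 1e-5,
    contrast: str = "",
) -> TaxonSets:
    """Split significant taxa into enriched/depleted by fold-change sign.

    Significance: q below threshold AND mean normalized relative abundance
    strictly above the abundance threshold (independent filtering applied
    after the q computation).
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0, 1)")
    t = da.tested
    sig = t[(t["q"] < q_threshold) & (t["mean_norm_rel_abund"] > abund_threshold)]
    enriched = set(sig.index[sig["log2fc"] > 0])
    depleted = set(sig.index[sig["log2fc"] < 0])
    if not enriched and not depleted:
        logger.info("significant_sets: no significant taxa for %s", contrast or da.term)
    return TaxonSets(enriched=enriched, depleted=depleted, contrast=contrast or da.term)


def dysbiosis_index(
    table: CountTable | pd.DataFrame,
    sets: TaxonSets,
    pseudocount: float = 1e-6,
) -> DysbiosisResult:
    """Per-sample ln of (enriched relative abundance sum / depleted sum).

    A small pseudocount keeps the index finite when one side's taxa are
    absent from a sample.  Accepts a CountTable or a relative-abundance
    DataFrame (taxa x samples).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not sets.enriched and not sets.depleted:
        raise ValueError("both taxon sets are empty")
    rel = table.relative_abundance() if isinstance(table, CountTable) else table
    enr = [t for t in sets.enriched if t in rel.index]
    dep = [t for t in sets.depleted if t in rel.index]
    num = rel.loc[enr].sum(axis=0) if enr else pd.Series(0.0, index=rel.columns)
    den = rel.loc[dep].sum(axis=0) if dep else pd.Series(0.0, index=rel.columns)
    values = np.log((num + pseudocount) / (den + pseudocount))
    return DysbiosisResult(values=values.rename("dysbiosis_index"), sets=sets,
                           pseudocount=pseudocount)


def nb_deviance_residuals(
    counts: pd.DataFrame,
    design: DesignMatrix,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Deviance residuals of per-taxon NB fits (for residual correlations)."""
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = fit_dispersions(counts, design, sf)["dispersion"]
    X = design.matrix.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(sf.loc[counts.columns].to_numpy(dtype=float))
    out = {}
    for taxon in counts.index:
        y = counts.loc[taxon].to_numpy(dtype=float)
        alpha = float(max(dispersions.loc[taxon], 1e-8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(maxiter=100)
        out[taxon] = res.resid_deviance
    return pd.DataFrame(out, index=counts.columns).T
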