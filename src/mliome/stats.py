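"""Shared statistical primitives.

Covariate-adjusted linear-model tests, rank tests with post-hoc procedures,
multiple-testing correction (Benjamini-Hochberg and Storey q-values), and
residual Spearman correlations.  Every analysis stage builds on these.

Conventions fixed here and relied on throughout the package:

* Linear-model hypothesis tests use sequential (Type-I) sums of squares with
  the covariates entered first and the term of interest entered **last**, so
  the reported F tests the term after adjustment for everything before it.
* Categorical covariates are reference-coded with fixed reference levels:
  ``dx=nonIBD``, ``gender=female``, ``bmi_cat=lt25``, ``behavior=B1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: reference level per known categorical covariate (dropped during encoding)
REFERENCE_LEVELS = {
    "dx": "nonIBD",
    "gender": "female",
    "bmi_cat": "lt25",
    "behavior": "B1",
    "site": "cecum",
    "progression": "nonprogressor",
}


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable design matrices."""


@dataclass
class TestResult:
    """A single hypothesis-test outcome."""

    statistic: float
    p_value: float
    effect_estimate: float | None = None
    df: tuple | int | None = None
    term: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class DesignMatrix:
    """Encoded design with bookkeeping of which columns belong to which term.

    ``matrix`` holds an intercept column plus reference-coded covariates in
    the order the terms were supplied; ``term_columns`` maps each term name
    to its column labels.
    """

    matrix: pd.DataFrame
    term_columns: dict[str, list[str]] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def columns_for(self, term: str) -> list[str]:
        if term not in self.term_columns:
            raise DesignError(f"term {term!r} not in design ({list(self.term_columns)})")
        return self.term_columns[term]


def build_design(
    metadata: pd.DataFrame,
    terms: list[str],
    continuous: set[str] | frozenset[str] = frozenset({"age", "grs"}),
    reference_levels: dict[str, str] | None = None,
) -> DesignMatrix:
    """Encode metadata columns into a full-rank design matrix.

    Terms are encoded in the given order (put the term of interest last for
    sequential testing).  Categorical terms are reference-coded; continuous
    terms enter as a single column.
    """
    refs = dict(REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(metadata))}
    term_columns: dict[str, list[str]] = {}
    for term in terms:
        if term not in metadata.columns:
            raise DesignError(f"metadata has no column {term!r}")
        values = metadata[term]
        if term in continuous or pd.api.types.is_numeric_dtype(values):
            arr = values.to_numpy(dtype=float)
            if np.isnan(arr).any():
                raise DesignError(f"term {term!r} has missing values")
            cols[term] = arr
            term_columns[term] = [term]
        else:
            levels = sorted(values.astype(str).unique())
            ref = refs.get(term, levels[0])
            if ref not in levels:
                ref = levels[0]
            labels = []
            for lev in levels:
                if lev == ref:
                    continue
                lab = f"{term}[{lev}]"
                cols[lab] = (values.astype(str) == lev).to_numpy(dtype=float)
                labels.append(lab)
            if not labels:
                raise DesignError(f"term {term!r} is constant across rows")
            term_columns[term] = labels
    X = pd.DataFrame(cols, index=metadata.index)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns): "
            f"{list(X.columns)}"
        )
    return DesignMatrix(matrix=X, term_columns=term_columns)


def build_design_robust(
    metadata: pd.DataFrame,
    covariates: list[str],
    term: str,
    **kw,
) -> DesignMatrix:
    """Like :func:`build_design` but drops covariates that would make the
    design rank-deficient or are constant (logged), keeping the term."""
    usable: list[str] = []
    for cov in covariates:
        if metadata[cov].nunique() < 2:
            logger.info("build_design_robust: dropping constant covariate %r", cov)
            continue
        try:
            build_design(metadata, usable + [cov, term], **kw)
        except DesignError:
            logger.info("build_design_robust: dropping collinear covariate %r", cov)
            continue
        usable.append(cov)
    return build_design(metadata, usable + [term], **kw)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of the least-squares fit and its model rank."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def anova_with_covariates(
    response: np.ndarray | pd.Series, design: DesignMatrix, term: str
) -> TestResult:
    """Sequential (Type-I) F-test for ``term`` entered last.

    Covariates (all design columns other than the term's) are fitted first;
    the F statistic measures the additional variance explained by the term.
    A constant response returns F=0, p=1.
    """
    y = np.asarray(response, dtype=float)
    term_cols = design.columns_for(term)
    X_full = design.values
    keep = [c for c in design.matrix.columns if c not in term_cols]
    X_red = design.matrix[keep].to_numpy(dtype=float)
    if len(y) <= X_full.shape[1]:
        raise DesignError("fewer observations than design columns")
    if np.allclose(y, y[0]):
        return TestResult(statistic=0.0, p_value=1.0, term=term, df=(len(term_cols), 0))
    rss_red, _ = _rss(y, X_red)
    rss_full, rank_full = _rss(y, X_full)
    df_term = len(term_cols)
    df_resid = len(y) - rank_full
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")
    num = max(rss_red - rss_full, 0.0) / df_term
    den = rss_full / df_resid
    if den <= 0:
        # saturated fit: term explains everything that was left
        return TestResult(statistic=np.inf, p_value=0.0, term=term, df=(df_term, df_resid))
    F = num / den
    p = float(sps.f.sf(F, df_term, df_resid))
    # effect estimate: coefficient of the term's first column in the full fit
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    est = float(beta[list(design.matrix.columns).index(term_cols[0])])
    return TestResult(statistic=float(F), p_value=p, effect_estimate=est,
                      df=(df_term, df_resid), term=term)


def tukey_hsd(response: np.ndarray, group: np.ndarray) -> list[TestResult]:
    """All pairwise group comparisons with studentized-range adjusted p."""
    y = np.asarray(response, dtype=float)
    g = np.asarray(group)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("tukey_hsd requires at least two groups")
    samples = [y[g == lev] for lev in levels]
    for lev, s in zip(levels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")
    res = sps.tukey_hsd(*samples)
    out = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            out.append(
                TestResult(
                    statistic=float(res.statistic[i, j]),
                    p_value=float(min(res.pvalue[i, j], 1.0)),
                    effect_estimate=float(np.mean(samples[i]) - np.mean(samples[j])),
                    term=f"{levels[i]}-{levels[j]}",
                )
            )
    return out


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration when the combined sample is small (n <= 20) and free of
    ties; otherwise the normal approximation with midranks and tie-corrected
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    exact = len(combined) <= 20 and len(np.unique(combined)) == len(combined)
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        effect_estimate=float(np.median(x) - np.median(y)),
        note="exact" if exact else "normal-approximation",
    )


def kruskal_dunn(
    response: np.ndarray, group: np.ndarray
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis omnibus test with Dunn post-hoc z tests (BH adjusted)."""
    y = np.asarray(response, dtype=float)
    g = np.asarray(group)
    levels = list(pd.unique(g))
    samples = [y[g == lev] for lev in levels]
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if np.allclose(y, y[0]):
        omnibus = TestResult(statistic=0.0, p_value=1.0, term="kruskal")
    else:
        H, p = sps.kruskal(*samples)
        omnibus = TestResult(statistic=float(H), p_value=float(p), term="kruskal")

    # Dunn's z statistics on midranks with tie correction
    N = len(y)
    ranks = sps.rankdata(y)
    mean_ranks = {lev: ranks[g == lev].mean() for lev in levels}
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    pairs, raw_p, zs, diffs = [], [], [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            na, nb = (g == a).sum(), (g == b).sum()
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
            pairs.append(f"{a}-{b}")
            zs.append(z)
            diffs.append(mean_ranks[a] - mean_ranks[b])
            raw_p.append(2.0 * sps.norm.sf(abs(z)))
    adj = bh_adjust(np.array(raw_p)) if raw_p else np.array([])
    posthoc = [
        TestResult(statistic=float(z), p_value=float(q), effect_estimate=float(d), term=pair,
                   note=f"raw_p={p:.6g}")
        for pair, z, d, p, q in zip(pairs, zs, diffs, raw_p, adj)
    ]
    return omnibus, posthoc


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 as the median of pi0(lambda) over a grid."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    ests = [(p > lam).mean() / (1.0 - lam) for lam in lambdas]
    pi0 = float(np.median(ests))
    return min(max(pi0, 1.0 / len(p)), 1.0)


def storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values: pi0-scaled BH adjusted p-values.

    With fewer than 50 p-values the pi0 estimate is unstable, so the function
    falls back to plain BH (pi0 = 1) with a logged notice.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 50:
        logger.info("storey_qvalues: %d p-values < 50; falling back to BH (pi0=1)", p.size)
        warnings.warn("fewer than 50 p-values; using BH without pi0 estimation",
                      stacklevel=2)
        return bh_adjust(p)
    pi0 = storey_pi0(p)
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def ols_residuals(y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    X = design.values
    beta, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return np.asarray(y, dtype=float) - X @ beta


def residual_spearman(x: np.ndarray, y: np.ndarray, design: DesignMatrix) -> TestResult:
    """Spearman correlation of the OLS residuals of x and y on the design.

    With an intercept-only design this reduces to the ordinary Spearman
    correlation.  Constant residuals yield an undefined correlation which is
    returned flagged (NaN statistic, p=1) so callers can exclude it.
    """
    rx = ols_residuals(x, design)
    ry = ols_residuals(y, design)
    if np.allclose(rx, rx[0]) or np.allclose(ry, ry[0]):
        return TestResult(statistic=np.nan, p_value=1.0, note="constant-residuals")
    rho = float(sps.spearmanr(rx, ry).statistic)
    # the covariate fit absorbs degrees of freedom, so the p-value uses
    # df = n - g - 2 with g non-intercept design columns (partial-correlation
    # convention); scipy's own p would be anticonservative here
    n = len(rx)
    g = design.matrix.shape[1] - 1
    df = n - g - 2
    if df <= 0:
        return TestResult(statistic=rho, p_value=1.0, note="insufficient-df")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=rho, p_value=p, effect_estimate=rho)


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Serialize a list of results to the package's standard TSV layout."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "estimate": [r.effect_estimate for r in results],
        }
    )
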