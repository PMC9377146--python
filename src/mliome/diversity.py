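"""Alpha/beta diversity and biogeography.

Rarefaction, Chao1 and Shannon alpha diversity, Bray-Curtis dissimilarity,
principal coordinates analysis, covariate-adjusted PERMANOVA (adonis-style
sequential partitioning), and the paired cecum-sigmoid contrasts.

Alpha diversity is computed on rarefied counts; beta diversity defaults to
raw counts (both are supported, the choice is the caller's).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .stats import DesignMatrix, TestResult, build_design, kruskal_dunn, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Taxon x sample integer count matrix with per-sample annotations.

    ``counts`` is taxa (rows) x samples (columns); ``samples`` is indexed by
    sample id and must carry ``subject_id`` and ``site`` columns plus any
    metadata used downstream (dx, gender, age, bmi_cat, behavior, ...).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing annotations: {sorted(missing)[:5]}")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"zero-total samples: {bad}")
        return self.counts / totals

    def subset_samples(self, sample_ids) -> "CountTable":
        ids = list(sample_ids)
        return CountTable(self.counts[ids], self.samples.loc[ids])

    def metadata_for_samples(self) -> pd.DataFrame:
        return self.samples.loc[self.counts.columns]


@dataclass
class Ordination:
    coordinates: pd.DataFrame          # samples x axes, centered
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues


@dataclass
class PermanovaResult:
    terms: list[str]
    pseudo_f: dict[str, float]
    r_squared: dict[str, float]
    p_value: float                     # for the term of interest (last term)
    term_of_interest: str
    n_permutations: int


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (and logged),
    matching the convention of excluding under-sequenced samples before
    alpha-diversity analysis.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= depth]
    dropped = sorted(set(table.counts.columns) - set(keep))
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if len(keep) == 0:
        raise ValueError(f"rarefaction depth {depth} drops every sample")
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy(dtype=np.int64)
        out[s] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=table.counts.index)
    return CountTable(rarefied, table.samples.loc[list(keep)])


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        warnings.warn("all-zero count vector; Chao1 = 0", stacklevel=2)
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy in nats over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("count vector sums to zero")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Chao1 and Shannon per sample."""
    vals = {
        s: (chao1(table.counts[s].to_numpy()), shannon(table.counts[s].to_numpy()))
        for s in table.sample_ids
    }
    return pd.DataFrame(vals, index=["chao1", "shannon"]).T


def bray_curtis(table: CountTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix: 1 - 2*sum(min) / sum(totals)."""
    X = table.counts.to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = [table.sample_ids[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"zero-total samples: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(distance: pd.DataFrame, k: int | None = None) -> Ordination:
    """Classical scaling: eigendecompose the Gower-centered matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for **positive**
    eigenvalues only; negative eigenvalues are reported, not corrected.
    """
    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    G = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    n_pos = int(pos.sum())
    if k is None:
        k = n_pos
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    prop = eigvals[:n_pos] / eigvals[:n_pos].sum() if n_pos else np.array([])
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=distance.index, columns=[f"PCo{i+1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova(
    distance: pd.DataFrame,
    metadata: pd.DataFrame,
    term: str,
    covariates: list[str] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Covariate-adjusted PERMANOVA by sequential partitioning.

    The Gower-centered inner-product matrix of the distances is partitioned
    by the ordered model terms (covariates first, term of interest last).
    The pseudo-F of the term is compared against free row permutations;
    p = (1 + #{F* >= F}) / (1 + n_permutations).
    """
    covariates = list(covariates or [])
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    meta = metadata.loc[distance.index]
    for col in covariates + [term]:
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
        if meta[col].nunique() < 2:
            raise ValueError(f"term {col!r} is constant across samples")
    design = build_design(meta, covariates + [term])
    G = _gower_center(distance.to_numpy(dtype=float))
    n = G.shape[0]
    ss_total = float(np.trace(G))

    terms = covariates + [term]
    # cumulative hat matrices: intercept, then +term1, +term2, ...
    cum_cols: list[list[str]] = [["Intercept"]]
    for t in terms:
        cum_cols.append(cum_cols[-1] + design.columns_for(t))
    hats = [_hat(design.matrix[c].to_numpy(dtype=float)) for c in cum_cols]

    ss_terms, dfs = {}, {}
    for i, t in enumerate(terms):
        ss_terms[t] = float(np.sum(hats[i + 1] * G)) - float(np.sum(hats[i] * G))
        dfs[t] = len(design.columns_for(t))
    ss_resid = ss_total - float(np.sum(hats[-1] * G))
    df_resid = n - 1 - sum(dfs.values())
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def f_for_interest(Gmat: np.ndarray) -> float:
        ss_t = float(np.sum(hats[-1] * Gmat)) - float(np.sum(hats[-2] * Gmat))
        ss_r = float(np.trace(Gmat)) - float(np.sum(hats[-1] * Gmat))
        return (ss_t / dfs[term]) / (ss_r / df_resid) if ss_r > 0 else np.inf

    f_obs = f_for_interest(G)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if f_for_interest(G[np.ix_(perm, perm)]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    pseudo_f = {t: (ss_terms[t] / dfs[t]) / (ss_resid / df_resid) for t in terms}
    r2 = {t: ss_terms[t] / ss_total for t in terms}
    r2["Residual"] = ss_resid / ss_total
    return PermanovaResult(
        terms=terms, pseudo_f=pseudo_f, r_squared=r2, p_value=p,
        term_of_interest=term, n_permutations=n_permutations,
    )


@dataclass
class PairedContrast:
    per_subject: pd.DataFrame          # subject_id, value, group
    group_test: TestResult | tuple
    metric: str
    excluded_subjects: list = field(default_factory=list)


def paired_site_contrast(
    table: CountTable,
    metric: str = "bray_curtis",
    alpha_values: pd.Series | None = None,
    group_column: str = "dx",
    groups: tuple[str, str] | None = ("CD", "nonIBD"),
    alternative: str = "two-sided",
) -> PairedContrast:
    """Per-subject cecum-vs-sigmoid contrasts with a group comparison.

    ``metric='bray_curtis'`` yields the paired Bray-Curtis dissimilarity
    between a subject's cecum and sigmoid samples; passing ``alpha_values``
    (indexed by sample id) yields the difference cecum - sigmoid.  Subjects
    missing a site are excluded and logged.  With two groups the comparison
    is a Wilcoxon rank-sum test; with more, Kruskal-Wallis + Dunn.
    """
    meta = table.metadata_for_samples()
    rows, excluded = [], []
    for subject, sub in meta.groupby("subject_id"):
        sites = sub.groupby("site").groups
        if "cecum" not in sites or "sigmoid" not in sites or any(
            len(v) != 1 for v in sites.values()
        ):
            excluded.append(subject)
            continue
        cec = list(sites["cecum"])[0]
        sig = list(sites["sigmoid"])[0]
        if alpha_values is not None:
            value = float(alpha_values[cec] - alpha_values[sig])
        else:
            pair = table.subset_samples([cec, sig])
            value = float(bray_curtis(pair).iloc[0, 1])
        rows.append((subject, value, sub[group_column].iloc[0]))
    if excluded:
        logger.info("paired_site_contrast: excluded subjects missing a site: %s", excluded)
    per_subject = pd.DataFrame(rows, columns=["subject_id", "value", "group"])
    if per_subject["group"].nunique() < 2:
        test = None
    elif groups is not None:
        a = per_subject.loc[per_subject["group"] == groups[0], "value"].to_numpy()
        b = per_subject.loc[per_subject["group"] == groups[1], "value"].to_numpy()
        test = wilcoxon_rank_sum(a, b, alternative=alternative)
    else:
        test = kruskal_dunn(per_subject["value"].to_numpy(), per_subject["group"].to_numpy())
    return PairedContrast(
        per_subject=per_subject,
        group_test=test,
        metric=metric if alpha_values is None else "alpha-difference",
        excluded_subjects=excluded,
    )
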