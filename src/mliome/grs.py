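"""Polygenic risk score and its microbiome associations.

The genetic risk score of a subject is the weighted sum of risk-allele
dosages, GRS = sum_i beta_i * G_i, with G_i in {0, 1, 2} and beta_i the
per-variant log odds ratio.  Association analyses test the (continuous)
score against alpha diversity, the dysbiosis index, community composition
(PERMANOVA) and per-taxon abundance, and quantify the overlap between
score-associated taxa and disease-associated taxa with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import da as _da
from .diversity import CountTable, permanova
from .stats import (DesignMatrix, TestResult, anova_with_covariates,
                    build_design, build_design_robust)

logger = logging.getLogger(__name__)


def compute_grs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    missing_policy: str = "error",
) -> pd.Series:
    """Per-subject weighted sum of risk-allele dosages.

    ``dosages`` is subjects x SNPs with entries in {0, 1, 2}; ``weights``
    has columns (snp_id, beta).  The join is on SNP id and order-insensitive.
    Missing dosage entries raise by default; ``missing_policy='mean'``
    imputes 2 x allele frequency estimated from the observed column.
    """
    w = weights.set_index("snp_id")["beta"] if "snp_id" in weights.columns else weights["beta"]
    missing_snps = set(w.index) - set(dosages.columns)
    if missing_snps:
        raise ValueError(f"SNPs in weights absent from dosages: {sorted(missing_snps)[:10]}")
    D = dosages[list(w.index)].astype(float)
    vals = D.to_numpy()
    if not np.isin(vals[~np.isnan(vals)], [0, 1, 2]).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    if D.isna().any().any():
        if missing_policy == "mean":
            freq = D.mean(axis=0) / 2.0
            D = D.fillna(2.0 * freq)
            logger.info("compute_grs: mean-imputed missing dosages (2 x allele frequency)")
        else:
            bad = D.columns[D.isna().any()].tolist()
            raise ValueError(f"missing dosages for SNPs {bad[:10]}; set missing_policy='mean'")
    return pd.Series(D.to_numpy() @ w.to_numpy(), index=dosages.index, name="grs")


@dataclass
class GrsAssociationReport:
    stratum: str
    scalar_tests: dict[str, TestResult] = field(default_factory=dict)
    composition: object | None = None          # PermanovaResult
    per_taxon: object | None = None            # DAResult
    overlap: dict | None = None                # Fisher contingency + p


def fisher_overlap(
    hits_a: set, hits_b: set, universe: set
) -> dict:
    """Fisher's exact test for overlap of two hit sets within a universe."""
    a, b = hits_a & universe, hits_b & universe
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(universe) - both - only_a - only_b
    table = [[both, only_a], [only_b, neither]]
    odds, p = sps.fisher_exact(table, alternative="greater")
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p),
            "universe_size": len(universe)}


def grs_associations(
    grs: pd.Series,
    subjects: pd.DataFrame,
    stratum: str,
    counts: CountTable | None = None,
    alpha: pd.DataFrame | None = None,
    dysbiosis: pd.Series | None = None,
    distance: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
    cd_sets: _da.TaxonSets | None = None,
    q_threshold: float = 0.1,
    n_permutations: int = 999,
    seed: int = 0,
) -> GrsAssociationReport:
    """Associations of the risk score within one disease stratum.

    Scalar targets (alpha diversity, dysbiosis index, subject-level) are
    tested by covariate-adjusted sequential ANOVA with the continuous score
    entered last; composition by covariate-adjusted PERMANOVA; per-taxon
    effects by the NB Wald test at the (laxer) score q-threshold; and the
    overlap of score-associated with disease-associated taxa by a one-sided
    Fisher exact test over the post-filter taxon universe.
    """
    covariates = list(covariates or [])
    sub = subjects.loc[subjects["dx"] == stratum] if stratum in ("CD", "nonIBD") else subjects
    ids = [s for s in sub.index if s in grs.index]
    if len(ids) < len(covariates) + 3:
        raise ValueError(f"stratum {stratum!r} too small for adjusted analysis")
    g = grs.loc[ids]
    if float(np.var(g)) == 0:
        raise ValueError("GRS has zero variance in this stratum")
    meta = sub.loc[ids].copy()
    meta["grs"] = g

    usable_cov = [c for c in covariates if meta[c].nunique() > 1]
    design = build_design_robust(meta, usable_cov, "grs")
    report = GrsAssociationReport(stratum=stratum)

    def _scalar(name: str, values: pd.Series) -> None:
        aligned = values.reindex(ids)
        if aligned.isna().any():
            raise ValueError(f"{name}: missing values for some subjects")
        report.scalar_tests[name] = anova_with_covariates(aligned.to_numpy(), design, "grs")

    if alpha is not None:
        for col in alpha.columns:
            _scalar(f"alpha_{col}", alpha[col])
    if dysbiosis is not None:
        _scalar("dysbiosis_index", dysbiosis)
    if distance is not None:
        keep = [s for s in distance.index if s in ids]
        report.composition = permanova(
            distance.loc[keep, keep], meta, "grs", covariates=usable_cov,
            n_permutations=n_permutations, seed=seed,
        )
    if counts is not None:
        sample_ids = [s for s in counts.sample_ids if counts.samples.loc[s, "subject_id"] in ids]
        sub_counts = counts.subset_samples(sample_ids)
        smeta = sub_counts.metadata_for_samples().copy()
        smeta["grs"] = [g[smeta.loc[s, "subject_id"]] for s in smeta.index]
        s_cov = [c for c in covariates if smeta[c].nunique() > 1]
        sdesign = build_design_robust(smeta, s_cov, "grs")
        result = _da.nb_wald_test(sub_counts.counts, sdesign, "grs")
        report.per_taxon = result
        grs_sets = _da.significant_sets(result, q_threshold=q_threshold, contrast="grs")
        if cd_sets is not None:
            universe = set(result.tested.index)
            report.overlap = fisher_overlap(
                grs_sets.enriched | grs_sets.depleted,
                (cd_sets.enriched | cd_sets.depleted),
                universe,
            )
    return report
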