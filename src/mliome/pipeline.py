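"""End-to-end orchestration of the full analysis on one cohort.

Runs, per colonic site: rarefied alpha diversity with covariate-adjusted
tests, Bray-Curtis / PCoA / PERMANOVA, NB differential abundance and the
dysbiosis index, genetic-risk-score associations per disease stratum,
two-stage random-forest classifiers (disease state, behavior, progression),
and the metabolome stages through the cholate:deoxycholate log ratio and
bai-pathway aggregation.  Every stage logs its seed, thresholds, and
row/column counts, and the run writes a machine-readable JSON summary plus
a plain-text report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _cl
from . import da as _da
from . import diversity as _dv
from . import grs as _grs
from . import metabolome as _mb
from .stats import anova_with_covariates, build_design, build_design_robust
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and sizes of one pipeline run (defaults = study values)."""

    rarefaction_depth: int = 10_000
    prevalence_min: float = 0.25
    metabolite_prevalence_min: float = 0.10
    q_threshold: float = 0.05
    q_threshold_grs: float = 0.10
    abundance_threshold: float = 1e-5
    importance_cut: float = 2.0
    n_permutations: int = 9_999
    n_permutations_paper: int = 100_000
    paper_mode: bool = False
    n_boot: int = 2000
    train_fraction: float = 0.6
    mtry: int = 2
    n_trees: int = 1001
    covariates: tuple = ("gender", "bmi_cat")
    seed: int = 0

    @property
    def nperm(self) -> int:
        return self.n_permutations_paper if self.paper_mode else self.n_permutations


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_sanitize(v) for v in sorted(obj) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, set) else [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (pd.Series,)):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    return obj


def classify_from_counts(
    counts: _dv.CountTable,
    target: str,
    labels: pd.Series,
    run: RunConfig,
    covariates: list[str] | None = None,
    seed: int = 0,
) -> _cl.ClassifierReport:
    """DA-gated two-stage RF on one site's counts for a subject-level target.

    Feature pre-selection (taxa significant for the target) is recomputed on
    the training split only, so the held-out samples never influence the
    feature list.
    """
    meta = counts.metadata_for_samples().copy()
    meta = meta[meta["subject_id"].isin(labels.index)]
    meta["target"] = [labels[s] for s in meta["subject_id"]]
    table = counts.subset_samples(list(meta.index))
    train_ids, test_ids = _cl.stratified_split(meta["target"], run.train_fraction, seed)

    train = table.subset_samples(train_ids)
    train_meta = meta.loc[train_ids]
    design = build_design_robust(train_meta, list(covariates or []), "target",
                                 reference_levels={"target": sorted(set(labels))[0]})
    filtered = _da.prevalence_filter(train, run.prevalence_min)
    result = _da.nb_wald_test(filtered.counts, design, "target")
    sets = _da.significant_sets(result, run.q_threshold, run.abundance_threshold)
    selected = sorted(sets.enriched | sets.depleted)
    if not selected:
        # fall back to the lowest-p taxa so the classifier remains defined
        selected = list(result.tested.sort_values("p").index[:10])
        logger.warning("classify[%s]: no significant taxa; using 10 lowest-p taxa", target)
    sf_train = _da.size_factors(train.counts)
    feats_train = _cl.log_relative_features(train.counts, sf_train)[selected]
    test = table.subset_samples(test_ids)
    sf_test = _da.size_factors(test.counts)
    feats_test = _cl.log_relative_features(test.counts, sf_test)[selected]
    return _cl.train_two_stage_rf(
        feats_train, meta.loc[train_ids, "target"],
        feats_test, meta.loc[test_ids, "target"],
        mtry=run.mtry, n_trees=run.n_trees, importance_cut=run.importance_cut,
        n_boot=run.n_boot, seed=seed,
    )


def run_pipeline(
    cohort: SyntheticCohort | None = None,
    run: RunConfig | None = None,
    out_dir: str | Path | None = None,
    cohort_config: CohortConfig | None = None,
) -> dict:
    """Execute every stage on a cohort (simulated if not supplied).

    Returns the summary dict; if ``out_dir`` is given, also writes
    ``summary.json`` and ``report.txt`` plus per-stage TSVs.
    """
    run = run or RunConfig()
    if cohort is None:
        cohort = simulate_cohort(cohort_config or CohortConfig(seed=run.seed))
    summary: dict = {"seed": run.seed, "stages": {}}
    counts, subjects = cohort.counts, cohort.subjects
    covs = list(run.covariates)
    required = {"subject_id", "site", "dx"} | set(covs)
    missing_cols = required - set(counts.samples.columns)
    if missing_cols:
        raise ValueError(f"sample metadata missing columns: {sorted(missing_cols)}")
    failures: list[str] = []

    per_site: dict[str, dict] = {}
    for site in ("cecum", "sigmoid"):
        stage: dict = {}
        site_ids = [s for s in counts.sample_ids
                    if counts.samples.loc[s, "site"] == site]
        site_table = counts.subset_samples(site_ids)
        logger.info("site %s: %d samples x %d taxa", site, len(site_ids),
                    site_table.counts.shape[0])
        try:
            depth = min(run.rarefaction_depth,
                        int(site_table.counts.sum(axis=0).min()))
            rare = _dv.rarefy(site_table, depth, seed=run.seed)
            alpha = _dv.alpha_diversity(rare)
            meta = rare.metadata_for_samples()
            design = build_design_robust(meta, covs + ["age"], "dx")
            stage["alpha"] = {
                m: vars(anova_with_covariates(alpha[m].to_numpy(), design, "dx"))
                for m in ("chao1", "shannon")
            }
            dist = _dv.bray_curtis(site_table)
            ord_ = _dv.pcoa(dist, k=2)
            stage["pcoa_prop_explained"] = ord_.proportion_explained[:2].tolist()
            perma = _dv.permanova(dist, site_table.metadata_for_samples(), "dx",
                                  covariates=covs, n_permutations=run.nperm,
                                  seed=run.seed)
            stage["permanova_dx"] = {"p": perma.p_value,
                                     "r2": perma.r_squared["dx"],
                                     "n_perm": perma.n_permutations}

            filtered = _da.prevalence_filter(site_table, run.prevalence_min)
            design_s = build_design_robust(filtered.metadata_for_samples(), covs, "dx")
            da_res = _da.nb_wald_test(filtered.counts, design_s, "dx")
            sets = _da.significant_sets(da_res, run.q_threshold,
                                        run.abundance_threshold,
                                        contrast=f"dx-{site}")
            dys = _da.dysbiosis_index(site_table, sets) if (
                sets.enriched or sets.depleted) else None
            stage["da_dx"] = {"n_tested": int(da_res.tested.shape[0]),
                              "n_enriched": len(sets.enriched),
                              "n_depleted": len(sets.depleted)}
            if dys is not None:
                meta_all = site_table.metadata_for_samples()
                cd_vals = dys.values[meta_all["dx"] == "CD"]
                ctrl_vals = dys.values[meta_all["dx"] == "nonIBD"]
                from .stats import wilcoxon_rank_sum
                t = wilcoxon_rank_sum(cd_vals.to_numpy(), ctrl_vals.to_numpy())
                stage["dysbiosis"] = {"cd_mean": float(cd_vals.mean()),
                                      "control_mean": float(ctrl_vals.mean()),
                                      "wilcoxon_p": t.p_value}
            per_site[site] = {"table": site_table, "dist": dist, "sets": sets,
                              "dys": dys, "filtered": filtered}
        except Exception as exc:  # noqa: BLE001 - stage isolation
            failures.append(f"{site}: {exc}")
            logger.exception("site stage %s failed", site)
        summary["stages"][site] = stage

    # GRS associations per stratum (cecum)
    try:
        grs = cohort.truth.grs if cohort.truth.grs is not None else subjects["grs"]
        cec = per_site["cecum"]
        dys = cec["dys"]
        grs_stage = {}
        for stratum in ("CD", "nonIBD"):
            kw = {}
            if dys is not None:
                subj_dys = dys.values.groupby(
                    cec["table"].samples.loc[dys.values.index, "subject_id"]).mean()
                kw["dysbiosis"] = subj_dys
            strat_covs = covs + (["behavior"] if stratum == "CD" else [])
            rep = _grs.grs_associations(
                grs, subjects, stratum, counts=cec["filtered"],
                covariates=strat_covs, cd_sets=cec["sets"],
                q_threshold=run.q_threshold_grs, seed=run.seed, **kw,
            )
            grs_stage[stratum] = {
                "scalar": {k: {"p": v.p_value, "F": v.statistic}
                           for k, v in rep.scalar_tests.items()},
                "overlap_p": rep.overlap["p_value"] if rep.overlap else None,
            }
        summary["stages"]["grs"] = grs_stage
    except Exception as exc:  # noqa: BLE001
        failures.append(f"grs: {exc}")
        logger.exception("grs stage failed")

    # classifiers (cecum site, per target)
    clf_stage = {}
    targets = {
        "dx": subjects["dx"],
        "behavior": subjects.loc[subjects["dx"] == "CD", "behavior"],
        "progression": subjects.loc[subjects["progression"].isin(
            ["progressor", "nonprogressor"]), "progression"],
    }
    for name, labels in targets.items():
        try:
            rep = classify_from_counts(per_site["cecum"]["table"], name, labels,
                                       run, covariates=covs, seed=run.seed)
            clf_stage[name] = {
                "auc": rep.auc, "ci": list(rep.ci),
                "n_preliminary": len(rep.preliminary_features),
                "n_refined": len(rep.refined_features),
            }
        except Exception as exc:  # noqa: BLE001
            failures.append(f"classifier {name}: {exc}")
            logger.exception("classifier %s failed", name)
    summary["stages"]["classifiers"] = clf_stage

    # metabolome
    try:
        mt = cohort.metabolites
        processed = _mb.preprocess(mt, run.metabolite_prevalence_min)
        meta = counts.samples.loc[[s for s in processed.intensities.columns
                                   if s in counts.samples.index]]
        design = build_design(meta, covs + ["dx"])
        proc_sub = processed._with(processed.intensities[meta.index])
        models = _mb.per_feature_models(proc_sub, design, "dx")
        imputed = _mb.knn_impute(_mb.feature_prevalence_filter(
            mt, run.metabolite_prevalence_min))
        bile = _mb.bile_log_ratio(
            imputed, cohort.truth.cholate_feature, cohort.truth.deoxycholate_feature,
            groups=counts.samples["dx"],
        )
        bai = _mb.aggregate_bai(cohort.ko_table)
        dxmap = counts.samples["dx"]
        from .stats import wilcoxon_rank_sum
        bai_test = wilcoxon_rank_sum(
            bai[dxmap.loc[bai.index] == "CD"].to_numpy(),
            bai[dxmap.loc[bai.index] == "nonIBD"].to_numpy(),
        )
        summary["stages"]["metabolome"] = {
            "n_features_processed": int(processed.intensities.shape[0]),
            "n_significant_dx": int((models["q"] < run.q_threshold).sum()),
            "bile_log_ratio": {
                "cd_mean": bile.cd_mean, "control_mean": bile.control_mean,
                "wilcoxon_p": bile.group_test.p_value,
            },
            "bai": {"cd_mean": float(bai[dxmap.loc[bai.index] == "CD"].mean()),
                    "control_mean": float(bai[dxmap.loc[bai.index] == "nonIBD"].mean()),
                    "wilcoxon_p": bai_test.p_value},
        }
    except Exception as exc:  # noqa: BLE001
        failures.append(f"metabolome: {exc}")
        logger.exception("metabolome stage failed")

    summary["failures"] = failures
    summary = _sanitize(summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (out / "report.txt").write_text(_render_report(summary))
    if failures:
        raise PipelineError(summary, failures)
    return summary


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained on the summary."""

    def __init__(self, summary: dict, failures: list[str]):
        super().__init__("; ".join(failures))
        self.summary = summary
        self.failures = failures


def _render_report(summary: dict) -> str:
    lines = [f"mliome pipeline run (seed {summary.get('seed')})", "=" * 40]
    for site in ("cecum", "sigmoid"):
        st = summary["stages"].get(site, {})
        if not st:
            continue
        lines.append(f"\n[{site}]")
        if "alpha" in st:
            for m, r in st["alpha"].items():
                lines.append(f"  alpha {m}: F={r['statistic']:.2f} p={r['p_value']:.3g}")
        if "permanova_dx" in st:
            p = st["permanova_dx"]
            lines.append(f"  PERMANOVA dx: R2={p['r2']:.3f} p={p['p']:.3g} "
                         f"({p['n_perm']} permutations)")
        if "da_dx" in st:
            d = st["da_dx"]
            lines.append(f"  DA dx: {d['n_enriched']} enriched / {d['n_depleted']} "
                         f"depleted of {d['n_tested']} tested")
        if "dysbiosis" in st:
            d = st["dysbiosis"]
            lines.append(f"  dysbiosis index: CD {d['cd_mean']:.2f} vs control "
                         f"{d['control_mean']:.2f} (p={d['wilcoxon_p']:.3g})")
    clf = summary["stages"].get("classifiers", {})
    for name, r in clf.items():
        lines.append(f"\nclassifier {name}: AUC {r['auc']:.3f} "
                     f"(95% CI {r['ci'][0]:.3f}-{r['ci'][1]:.3f}), "
                     f"{r['n_refined']}/{r['n_preliminary']} features after refinement")
    mb = summary["stages"].get("metabolome")
    if mb:
        b = mb["bile_log_ratio"]
        lines.append(f"\nmetabolome: {mb['n_significant_dx']} features at q<0.05; "
                     f"cholate:deoxycholate log ratio CD {b['cd_mean']:.2f} vs "
                     f"control {b['control_mean']:.2f} (p={b['wilcoxon_p']:.3g})")
        a = mb["bai"]
        lines.append(f"bai pathway: CD {a['cd_mean']:.2e} vs control "
                     f"{a['control_mean']:.2e} (p={a['wilcoxon_p']:.3g})")
    if summary.get("failures"):
        lines.append("\nFAILED stages: " + "; ".join(summary["failures"]))
    return "\n".join(lines) + "\n"
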