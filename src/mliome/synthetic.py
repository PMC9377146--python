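"""Synthetic study generator with known ground truth.

Emulates the structure of a paired-site colonic lavage cohort: subject
metadata (disease status, gender, age, BMI category, behavior,
progression), paired cecum/sigmoid ASV count tables with planted disease /
obesity / genetic-risk / site / progression effects, biallelic SNP dosages
with log-odds-ratio weights, log-normal LC-MS metabolite intensities with
intensity-dependent missingness and planted cholate/deoxycholate shifts,
and a predicted-metagenome KO table carrying the bai operon.

Counts are drawn by a gamma-multinomial scheme: per-taxon latent log
abundances (baseline + planted effects + subject and site random effects)
are softmax-normalized, perturbed by per-taxon gamma noise whose shape is
the inverse negative-binomial dispersion, and the library total is
distributed multinomially.  Marginal taxon counts are therefore
approximately negative-binomial while per-sample totals equal the library
size exactly.  Planted fold changes are approximate after renormalization
(compositional coupling), which downstream tests tolerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from .diversity import CountTable
from .metabolome import BAI_KOS, MetaboliteTable

LN2 = np.log(2.0)


class ConfigError(ValueError):
    pass


def _default_effect_sets() -> dict:
    """Planted effects: taxon index -> log2 fold change (or slope for GRS).

    cd_enriched/cd_depleted define the disease contrast; obesity overlaps
    them with weaker same-direction effects (so obese controls sit between
    lean controls and CD on the dysbiosis index); grs_coupled is a subset of
    the CD-enriched taxa; progression plants depletion of one
    Parasutterella-like taxon (index 25) plus a few companions.
    """
    return {
        "cd_enriched": {i: 2.5 for i in range(0, 10)},
        "cd_depleted": {i: -2.5 for i in range(10, 25)},
        "obesity": {**{i: 1.0 for i in range(0, 5)}, **{i: -1.0 for i in range(10, 18)}},
        "grs_coupled": {i: 1.0 for i in range(0, 6)},
        "site": {i: 1.0 for i in range(30, 34)},
        "progression": {25: -2.0, 26: -1.5, 27: 1.5},
    }


@dataclass
class CohortConfig:
    """All knobs of the synthetic study; the defaults are the study conditions."""

    n_cd: int = 50
    n_control: int = 50
    n_taxa: int = 150
    n_snps: int = 186
    n_metabolites: int = 300
    library_size_log_mean: float = float(np.log(5e4))
    library_size_log_sd: float = 0.25
    baseline_abundance_log_mean: float = 0.0
    baseline_abundance_log_sd: float = 1.5
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.25
    effect_sets: dict = field(default_factory=_default_effect_sets)
    site_divergence_sd_cd: float = 0.8
    site_divergence_sd_control: float = 0.2
    subject_effect_sd: float = 0.5
    grs_effect_slope: float = 1.0       # log2 fold change per GRS unit (grs_coupled taxa)
    grs_cd_offset: float = 0.45         # planted CD-vs-control mean GRS difference
    weight_log_or_mean: float = 0.15
    weight_log_or_sd: float = 0.08
    maf_range: tuple = (0.05, 0.5)
    behavior_b1_prob: float = 0.34
    progression_labeled_fraction: float = 0.8
    progressor_prob: float = 0.44
    missingness_intercept: float = 8.8
    missingness_slope: float = 1.5
    bile_shift_log2: float = 1.0
    metabolite_log_mean: float = 7.0
    metabolite_log_sd: float = 1.0
    bile_feature_log_mean: float = 9.0
    n_batches: int = 2
    batch_shift: float = 0.3
    batch_scale: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_control", "n_taxa", "n_snps", "n_metabolites"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_cd < 0:
            raise ConfigError("n_cd must be >= 0")
        if self.n_metabolites < 2:
            raise ConfigError("n_metabolites must be >= 2")
        for contrast, eff in self.effect_sets.items():
            for idx, fc in eff.items():
                if not 0 <= int(idx) < self.n_taxa:
                    raise ConfigError(
                        f"effect_sets[{contrast!r}] index {idx} outside [0, {self.n_taxa})"
                    )
                if not np.isfinite(fc):
                    raise ConfigError(f"effect_sets[{contrast!r}] fold change not finite")
        for name in ("dispersion_shape", "dispersion_mean", "subject_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything planted, recoverable by index/id."""

    effect_sets: dict
    taxon_log2fc: dict                     # contrast -> {taxon_id: log2fc}
    grs: pd.Series | None = None           # per-subject latent score
    cholate_feature: str = "feat_cholate"
    deoxycholate_feature: str = "feat_deoxycholate"
    ko_incidence: pd.DataFrame | None = None
    dispersions: np.ndarray | None = None

    def taxon_ids(self, contrast: str, sign: int | None = None) -> set:
        eff = self.taxon_log2fc.get(contrast, {})
        if sign is None:
            return set(eff)
        return {t for t, fc in eff.items() if np.sign(fc) == sign}


def _taxon_id(i: int) -> str:
    return f"ASV{i:04d}"


def simulate_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per subject: dx, gender, age, bmi_cat, behavior, progression.

    Age and BMI-category distributions differ by arm (CD subjects younger
    and leaner, controls skewed overweight/obese, as in screening-colonoscopy
    cohorts).  Behavior (B1 vs B2B3) exists only for CD; progression labels
    exist for a configurable subset of CD subjects.
    """
    config.validate()
    n = config.n_cd + config.n_control
    ids = [f"subj{i:04d}" for i in range(n)]
    dx = np.array(["CD"] * config.n_cd + ["nonIBD"] * config.n_control)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    age = np.where(
        dx == "CD",
        rng.normal(41, 12, n),
        rng.normal(64, 10, n),
    ).clip(18, 90).round(1)
    bmi_probs_cd = [0.60, 0.25, 0.15]
    bmi_probs_ctrl = [0.40, 0.35, 0.25]
    cats = np.array(["lt25", "25to30", "gt30"])
    bmi = np.array([
        rng.choice(cats, p=bmi_probs_cd if d == "CD" else bmi_probs_ctrl) for d in dx
    ])
    behavior = np.where(
        dx == "CD",
        np.where(rng.random(n) < config.behavior_b1_prob, "B1", "B2B3"),
        "",
    )
    progression = np.full(n, "", dtype=object)
    cd_idx = np.where(dx == "CD")[0]
    n_labeled = int(round(config.progression_labeled_fraction * len(cd_idx)))
    labeled = rng.choice(cd_idx, size=n_labeled, replace=False) if n_labeled else []
    for i in labeled:
        progression[i] = (
            "progressor" if rng.random() < config.progressor_prob else "nonprogressor"
        )
    return pd.DataFrame(
        {
            "dx": dx, "gender": gender, "age": age, "bmi_cat": bmi,
            "behavior": behavior, "progression": progression,
        },
        index=pd.Index(ids, name="subject_id"),
    )


def simulate_genotypes(
    config: CohortConfig, subjects: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic dosages in {0,1,2} and per-SNP log-odds-ratio weights.

    CD subjects' allele frequencies are tilted along the weight vector so
    their expected score exceeds controls by ``grs_cd_offset`` (solved
    numerically); ``grs_cd_offset=0`` leaves both arms exchangeable.
    """
    config.validate()
    snps = [f"rs{i:06d}" for i in range(config.n_snps)]
    beta = np.abs(rng.normal(config.weight_log_or_mean, config.weight_log_or_sd,
                             config.n_snps))
    maf = rng.uniform(*config.maf_range, config.n_snps)
    weights = pd.DataFrame({"snp_id": snps, "beta": beta})

    def tilted_maf(c: float) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return special.expit(special.logit(maf) + c * beta)

    offset = config.grs_cd_offset
    if offset != 0 and beta.sum() > 0 and maf.sum() > 0:
        def gap(c: float) -> float:
            return float(2.0 * (beta * (tilted_maf(c) - maf)).sum()) - offset
        c_star = optimize.brentq(gap, 0.0 if offset > 0 else -50.0,
                                 50.0 if offset > 0 else 0.0)
        maf_cd = tilted_maf(c_star)
    else:
        maf_cd = maf
    rows = {}
    for subj in subjects.index:
        p = maf_cd if subjects.loc[subj, "dx"] == "CD" else maf
        rows[subj] = rng.binomial(2, p)
    dosages = pd.DataFrame.from_dict(rows, orient="index", columns=snps)
    dosages.index.name = "subject_id"
    return dosages, weights


def _obesity_level(bmi_cat: str) -> float:
    return {"lt25": 0.0, "25to30": 0.5, "gt30": 1.0}[bmi_cat]


def simulate_counts(
    config: CohortConfig,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
    grs: pd.Series | None = None,
) -> tuple[CountTable, GroundTruth]:
    """Paired cecum/sigmoid counts with planted effects.

    Latent per-sample log abundance of taxon t =
    baseline_t + ln2 * (CD + obesity + GRS + progression effects)
    + subject random effect + site effect, where the per-subject site effect
    is drawn with a larger standard deviation for CD subjects (planting
    paired cecum-sigmoid divergence).  Counts follow the gamma-multinomial
    scheme described in the module docstring.
    """
    config.validate()
    if len(subjects) == 0:
        raise ConfigError("subjects table is empty")
    n_taxa = config.n_taxa
    baseline = rng.normal(config.baseline_abundance_log_mean,
                          config.baseline_abundance_log_sd, n_taxa)
    if config.dispersion_shape > 0:
        disp = rng.gamma(config.dispersion_shape,
                         config.dispersion_mean / config.dispersion_shape, n_taxa)
    else:
        disp = np.full(n_taxa, config.dispersion_mean)
    disp = np.maximum(disp, 1e-6)

    eff = {k: np.zeros(n_taxa) for k in
           ("cd", "obesity", "grs", "progression", "site")}
    mapping = {"cd_enriched": "cd", "cd_depleted": "cd", "obesity": "obesity",
               "grs_coupled": "grs", "site": "site", "progression": "progression"}
    for contrast, vec in config.effect_sets.items():
        key = mapping.get(contrast)
        if key is None:
            continue
        for idx, fc in vec.items():
            eff[key][int(idx)] += fc

    taxa = [_taxon_id(i) for i in range(n_taxa)]
    counts = {}
    meta_rows = []
    for s_i, subj in enumerate(subjects.index):
        row = subjects.loc[subj]
        is_cd = row["dx"] == "CD"
        u = rng.normal(0.0, config.subject_effect_sd, n_taxa)
        site_sd = config.site_divergence_sd_cd if is_cd else config.site_divergence_sd_control
        site_delta = rng.normal(0.0, site_sd, n_taxa)
        grs_val = float(grs.loc[subj]) if grs is not None else 0.0
        base = baseline + u + LN2 * (
            eff["cd"] * is_cd
            + eff["obesity"] * _obesity_level(row["bmi_cat"])
            + eff["grs"] * config.grs_effect_slope * grs_val
            + eff["progression"] * (row.get("progression") == "progressor")
        )
        for site in ("cecum", "sigmoid"):
            lam = base.copy()
            if site == "sigmoid":
                lam = lam + LN2 * eff["site"] + site_delta
            p = np.exp(lam - lam.max())
            p = p / p.sum()
            library = int(np.round(np.exp(rng.normal(
                config.library_size_log_mean, config.library_size_log_sd))))
            library = max(library, 1)
            shape = 1.0 / disp
            gam = rng.gamma(shape, p * disp * library)
            total = gam.sum()
            probs = gam / total if total > 0 else p
            sample_id = f"{subj}_{site}"
            counts[sample_id] = rng.multinomial(library, probs)
            meta_rows.append(
                (sample_id, subj, site, row["dx"], row["gender"], row["age"],
                 row["bmi_cat"], row["behavior"], row["progression"],
                 f"batch{s_i % config.n_batches + 1}")
            )
    count_df = pd.DataFrame(counts, index=taxa)
    sample_meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "subject_id", "site", "dx", "gender", "age",
                 "bmi_cat", "behavior", "progression", "batch"],
    ).set_index("sample_id")
    truth = GroundTruth(
        effect_sets=config.effect_sets,
        taxon_log2fc={
            contrast: {_taxon_id(int(i)): fc for i, fc in vec.items()}
            for contrast, vec in config.effect_sets.items()
        },
        grs=grs,
        dispersions=disp,
    )
    return CountTable(count_df, sample_meta), truth


def simulate_metabolome(
    config: CohortConfig, subjects: pd.DataFrame, rng: np.random.Generator
) -> tuple[MetaboliteTable, GroundTruth]:
    """Log-normal intensities with MNAR missingness and planted bile shifts.

    Two designated features play cholate (+shift in CD) and deoxycholate
    (-shift); the probability that an entry is missing follows
    logistic(intercept - slope * log intensity), so low-intensity ions
    vanish preferentially.  Samples carry a planted location/scale batch
    effect on the log scale.
    """
    config.validate()
    n_feat = config.n_metabolites
    feat_ids = ["feat_cholate", "feat_deoxycholate"] + [
        f"feat{i:05d}" for i in range(2, n_feat)
    ]
    mz = np.round(rng.uniform(50, 1200, n_feat), 4)
    mz[0], mz[1] = 407.2802, 391.2853  # [M-H]- cholate / deoxycholate
    rt = np.round(rng.uniform(0.5, 13.0, n_feat), 2)
    mode = rng.choice(["pos", "neg"], n_feat)
    mode[0] = mode[1] = "neg"
    features = pd.DataFrame({"mz": mz, "rt": rt, "mode": mode},
                            index=pd.Index(feat_ids, name="feature_id"))

    feat_mean = rng.normal(config.metabolite_log_mean, 1.0, n_feat)
    feat_mean[0] = feat_mean[1] = config.bile_feature_log_mean
    feat_sd = np.abs(rng.normal(0.5, 0.2, n_feat)) + 0.2

    sample_ids, batches, cols = [], [], {}
    for s_i, subj in enumerate(subjects.index):
        is_cd = subjects.loc[subj, "dx"] == "CD"
        for site in ("cecum", "sigmoid"):
            sid = f"{subj}_{site}"
            mu = feat_mean.copy()
            if is_cd:
                mu[0] += config.bile_shift_log2 * LN2
                mu[1] -= config.bile_shift_log2 * LN2
            noise = rng.normal(0.0, feat_sd)
            batch = s_i % config.n_batches
            # batch effect perturbs location and noise scale, not the
            # planted structural means, so planted contrasts stay exact
            if batch > 0:
                logI = mu + noise * config.batch_scale + config.batch_shift
            else:
                logI = mu + noise
            p_miss = special.expit(
                config.missingness_intercept - config.missingness_slope * logI
            )
            vals = np.exp(logI)
            vals[rng.random(n_feat) < p_miss] = np.nan
            cols[sid] = vals
            sample_ids.append(sid)
            batches.append(f"batch{batch + 1}")
    intensities = pd.DataFrame(cols, index=features.index)
    table = MetaboliteTable(
        intensities=intensities, features=features,
        batches=pd.Series(batches, index=sample_ids, name="batch"),
    )
    truth = GroundTruth(effect_sets=config.effect_sets, taxon_log2fc={})
    return table, truth


def simulate_ko_table(
    config: CohortConfig,
    counts: CountTable,
    truth: GroundTruth,
    rng: np.random.Generator,
    n_background_kos: int = 24,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KO x sample relative abundances from a taxon->KO incidence matrix.

    The six bai-operon KOs are carried exclusively by a subset of the
    CD-depleted taxa (so the pathway is depleted in CD); background KOs get
    random carriers.  KO abundance is the incidence-weighted sum of taxon
    relative abundances, renormalized per sample.  Returns (ko_table,
    incidence).
    """
    taxa = list(counts.taxa)
    depleted = sorted(truth.taxon_ids("cd_depleted"))
    carriers = [t for t in depleted if t in taxa][:6]
    if not carriers:
        raise ValueError("no CD-depleted taxa available to carry the bai operon")
    kos = list(BAI_KOS) + [f"K{90000 + i:05d}" for i in range(n_background_kos)]
    incidence = pd.DataFrame(0.0, index=taxa, columns=kos)
    for j, ko in enumerate(BAI_KOS):
        for t_i, t in enumerate(carriers):
            if (t_i + j) % 2 == 0 or len(carriers) == 1:
                incidence.loc[t, ko] = 1.0
    for ko in kos[len(BAI_KOS):]:
        chosen = rng.choice(len(taxa), size=max(2, len(taxa) // 10), replace=False)
        incidence.iloc[chosen, incidence.columns.get_loc(ko)] = 1.0
    rel = counts.relative_abundance()
    if list(rel.index) != list(incidence.index):
        raise ValueError("taxon sets of counts and incidence differ")
    raw = incidence.T.to_numpy() @ rel.to_numpy()
    ko_df = pd.DataFrame(raw, index=kos, columns=rel.columns)
    totals = ko_df.sum(axis=0).replace(0.0, np.nan)
    ko_df = (ko_df / totals).fillna(0.0)
    truth.ko_incidence = incidence
    return ko_df, incidence


@dataclass
class SyntheticCohort:
    config: CohortConfig
    subjects: pd.DataFrame
    counts: CountTable
    dosages: pd.DataFrame
    weights: pd.DataFrame
    metabolites: MetaboliteTable
    ko_table: pd.DataFrame
    truth: GroundTruth


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate the full study deterministically from ``config.seed``."""
    config = config or CohortConfig()
    if seed is not None:
        config = CohortConfig(**{**asdict(config), "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = simulate_metadata(config, rng)
    dosages, weights = simulate_genotypes(config, subjects, rng)
    from .grs import compute_grs

    grs = compute_grs(dosages, weights)
    grs_centered = grs - grs.mean()
    counts, truth = simulate_counts(config, subjects, rng, grs=grs_centered)
    metabolites, _ = simulate_metabolome(config, subjects, rng)
    ko_table, _ = simulate_ko_table(config, counts, truth, rng)
    truth.grs = grs
    subjects = subjects.copy()
    subjects["grs"] = grs
    return SyntheticCohort(
        config=config, subjects=subjects, counts=counts, dosages=dosages,
        weights=weights, metabolites=metabolites, ko_table=ko_table, truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write the cohort as plain TSVs plus a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.counts.counts.rename_axis("taxon_id").to_csv(out / "counts.tsv", sep="\t")
    cohort.counts.samples.rename_axis("sample_id").to_csv(out / "metadata.tsv", sep="\t")
    cohort.subjects.rename_axis("subject_id").to_csv(out / "subjects.tsv", sep="\t")
    cohort.dosages.rename_axis("subject_id").to_csv(out / "dosages.tsv", sep="\t")
    cohort.weights.to_csv(out / "weights.tsv", sep="\t", index=False)
    mt = cohort.metabolites
    feat = mt.features.join(mt.intensities)
    feat.rename_axis("feature_id").to_csv(out / "metabolites.tsv", sep="\t")
    cohort.ko_table.rename_axis("ko_id").to_csv(out / "ko_table.tsv", sep="\t")
    truth = {
        "taxon_log2fc": cohort.truth.taxon_log2fc,
        "cholate_feature": cohort.truth.cholate_feature,
        "deoxycholate_feature": cohort.truth.deoxycholate_feature,
        "grs": ({} if cohort.truth.grs is None
                else {k: float(v) for k, v in cohort.truth.grs.items()}),
        "bai_carriers": [
            t for t in cohort.truth.ko_incidence.index
            if cohort.truth.ko_incidence.loc[t, list(BAI_KOS)].sum() > 0
        ] if cohort.truth.ko_incidence is not None else [],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
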