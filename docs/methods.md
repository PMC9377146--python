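# Methods

This note documents the models, conventions and design choices behind
`mliome`, in the spirit of the methods documentation of statsmodels or
msprime: what each stage assumes, which knobs matter, and what the bundled
synthetic cohort does and does not emulate.

## Statistical conventions (stats module)

**Sequential ANOVA.** All covariate-adjusted scalar tests use sequential
(Type-I) sums of squares with covariates entered first and the variable of
interest last, i.e. the F statistic measures the variance explained by the
term *after* the covariates. Term order is therefore part of the contract;
helper functions always place the term of interest last. Categorical
covariates are reference-coded with fixed references (`dx=nonIBD`,
`gender=female`, `bmi_cat=lt25`, `behavior=B1`) so coefficients are
comparable across runs.

**Rank tests.** The Wilcoxon rank-sum test enumerates the exact null when
the pooled sample has ≤20 observations and no ties, otherwise it uses the
normal approximation with midranks and tie-corrected variance. Dunn's
post-hoc z tests share the Kruskal-Wallis tie correction and are BH
adjusted.

**Multiple testing.** BH is the step-up procedure. Storey q-values
estimate π₀ as the median of π₀(λ) = #{p>λ}/(n(1−λ)) over
λ ∈ {0.05, …, 0.95} (capped to (0,1]) and scale the BH values; below 50
p-values the estimate is too unstable and the function falls back to BH
with a warning.

**Residual Spearman correlations.** Both variables are residualized on the
design by least squares, then rank-correlated. The p-value uses
df = n − g − 2 with g non-intercept design columns (the partial-correlation
convention); using scipy's df = n − 2 on residualized data is measurably
anticonservative at n ≈ 30, which the calibration test in the acceptance
suite would catch.

## Diversity and biogeography

Alpha diversity (bias-corrected Chao1; Shannon in natural-log units — the
base is a convention, nats chosen and documented) is computed on counts
rarefied without replacement to a fixed depth; samples below depth are
dropped and logged. Beta diversity (Bray-Curtis) is computed on raw counts
by default — whether to rarefy first is exposed to the caller, since
practice varies and the choice is not decidable from first principles.

PCoA is classical scaling of the Gower-centered −½d² matrix. Coordinates
are returned for positive eigenvalues only; negative eigenvalues are
reported unmodified (no Lingoes/Cailliez correction), matching common
plotting usage.

PERMANOVA partitions the Gower-centered inner-product matrix sequentially
by the ordered model terms (covariates first), giving per-term pseudo-F and
R²; significance of the final term comes from free row/column permutations
of the centered matrix, p = (1 + #{F* ≥ F}) / (1 + n_perm). No restricted
permutation blocks are implemented. Per-term statistics were verified
against `vegan::adonis2(by="terms")` on a frozen instance. Default
permutations: 9,999 (a "paper mode" switch raises it to 100,000).

The paired biogeography contrast computes, per subject, either the
difference cecum − sigmoid of an alpha metric or the Bray-Curtis
dissimilarity between the subject's two samples, and compares these
per-subject values between groups with rank tests. Subjects lacking one
site are excluded and logged.

## Negative-binomial differential abundance

The count model is a DESeq2-style workflow authored here:

1. **Prevalence filter**: keep taxa with nonzero counts in ≥25% of samples
   (the boundary is inclusive: exactly-25% is kept).
2. **Size factors**: median-of-ratios against per-taxon geometric means
   over all-positive taxa, then rescaled so the factors' geometric mean
   is 1. When no taxon is everywhere-positive, geometric means use positive
   entries only (logged). Exact invariance to adding a constant-count taxon
   does *not* hold for a median-based estimator (the inserted ratio moves
   the median element); tests assert robustness, not identity.
3. **Dispersions**: per taxon, the NB dispersion (Var = μ + αμ²) is
   estimated by profile maximum likelihood given Poisson-fitted means; a
   trend α(μ) = a₀/μ + a₁ is fitted across taxa by non-negative least
   squares, and the final value is the log-scale weighted combination
   exp((1−w)·log α̂ + w·log α_trend) with default w = 0.5, floored at 1e-8.
   This is a deliberately simplified empirical-Bayes shrinkage: the
   contract is calibration and recovery (verified by simulation), not
   numerical identity with the Cox–Reid adjusted-profile machinery of the
   reference implementations (a cross-check against pydeseq2 fold changes
   runs in the test suite).
4. **Wald tests**: per-taxon NB log-linear regression with log size-factor
   offset; z = β̂/SE, two-sided p, log2 fold change = β̂/ln 2. Taxa that
   fail to converge are excluded from the q-value computation and flagged.
   Storey q-values are computed over converged taxa; the independent
   abundance filter (mean normalized relative abundance > 10⁻⁵) is applied
   *after* q computation.

**Dysbiosis index.** Per sample,
ln((Σ enriched rel. abund. + ε)/(Σ depleted rel. abund. + ε)) with
pseudocount ε = 10⁻⁶; the raw ratio is undefined whenever a sample carries
none of the depleted taxa, and the natural log is a documented choice.
Site-specific enriched/depleted sets are the default (cecal and sigmoid
indices are computed from their own contrasts); pooled sets are a caller
choice.

## Genetic risk

GRS = Σᵢ βᵢGᵢ exactly, joined on SNP id (order-insensitive). Missing
dosages are an error by default; an opt-in policy mean-imputes with
2×allele-frequency. The score is used unstandardized. Associations per
disease stratum: sequential ANOVA for scalar targets (GRS last, behavior
among the covariates in the CD stratum), PERMANOVA for composition,
NB Wald tests at the laxer q < 0.1 for per-taxon effects, and a one-sided
Fisher exact test for the overlap between score-associated and
disease-associated taxa with the post-filter tested-taxon universe as
background — the only defensible universe, since untested taxa could never
enter either set.

## Two-stage random forest

Features are log10 size-factor-normalized relative abundances with
pseudocount 10⁻⁶ (the transform is a documented choice, configurable).
Candidate features are taxa significant for the trait of interest; by
default this pre-selection is recomputed on the training split only, so the
held-out samples never influence the feature list (an information-flow test
asserts that permuting test labels leaves the trained model and its test
scores unchanged). Stage 1 fits a forest with mtry=2 and 1001 trees;
feature importance is the permutation mean-decrease-accuracy divided by its
standard error over repeats (a z-score — the scale on which a "greater
than 2" cut is meaningful); stage 2 refits on features with z > 2, falling
back to all features with a warning if none qualifies. Accuracy is the
Mann-Whitney AUC (ties counted half) on the 40% test split, with a
stratified-bootstrap percentile CI (degenerate single-class resamples are
redrawn and counted). With strongly redundant informative features the
permutation z-scores can all be small (permuting one feature is compensated
by its correlates) and the fallback path triggers; this is inherent to
permutation importance, not a defect of the cut.

## Metabolomics

Processing order is fixed and logged: prevalence filter (strictly >10% of
samples observed) → KNN imputation → IQR filter → natural-log transform →
quantile normalization → batch standardization.

* **KNN imputation** (k=10) is feature-wise: a missing value of feature f
  in sample s is the unweighted mean, at s, of the k features nearest to f
  by Euclidean distance over mutually observed samples, restricted to
  features observed at s; with no qualifying donor the feature's observed
  mean is used (logged). Feature-neighborhood imputation is the standard
  choice for LC-MS missingness, which is missing-not-at-random in
  intensity.
* **IQR filter**: features ranked by interquartile range; by default the
  bottom 10% is dropped only when more than 250 features are present, and
  the retained fraction is fully configurable — the rule is explicit rather
  than an emulation claim of any particular tool version.
* **Quantile normalization** maps every sample onto the mean sorted
  profile; ties get the average of the tied reference quantiles, making the
  operation idempotent.
* **Batch standardization** is a location/scale correction (center each
  batch to the feature's grand mean, rescale to the pooled SD). It is a
  deliberately simple standardization, not an empirical-Bayes method, and
  is validated by a planted-shift removal test.
* **Per-feature models** are ordinary least squares with a t-test on the
  term and BH correction. No variance moderation is applied; the null
  calibration test guards validity at the sample sizes used here.
* **Bile-acid ratio**: per sample ln(cholate/deoxycholate) on raw
  (pre-normalization) intensities by default, since the ratio is a
  within-sample quantity; samples missing either feature are dropped with a
  log note, and a processed table can be passed instead. The bai pathway
  (KOs K15868, K15869, K15870, K15871, K15872, K07007) is the per-sample
  sum of those KO relative abundances; absent KOs contribute zero.
* **Microbe–metabolite correlations** use NB deviance residuals for taxa
  and OLS residuals for metabolites, rank-correlated pairwise with BH q.

## The synthetic cohort

The generator's defaults are the study conditions for every test: 50 CD +
50 control subjects, two samples each (cecum, sigmoid), 150 taxa, 186
SNPs, 300 metabolite features.

Counts follow a **gamma-multinomial** scheme: per-taxon latent log
abundances (log-normal baseline, SD 1.5) receive planted effects in log2
units — CD enrichment +2.5 on 10 taxa, CD depletion −2.5 on 15, weaker
overlapping obesity effects (±1 on subsets of the CD taxa, half-strength
for the overweight category), a genetic-risk slope of +1 log2FC per
centered-GRS unit on 6 CD-enriched taxa, fixed site effects on 4 taxa, and
progression effects including a depleted "Parasutterella-like" taxon —
plus a per-subject random effect (SD 0.5, shared between the subject's two
samples) and a per-subject per-taxon sigmoid-site effect whose SD is larger
in CD (0.8) than controls (0.2), planting paired-site divergence. The
softmax-normalized abundances are perturbed by per-taxon gamma noise with
shape 1/α (α ~ Gamma, mean 0.25) and the library total (log-normal, median
5×10⁴ — a desk-scale depth; real studies run deeper but the extra depth
adds nothing to testability) is distributed multinomially. Marginal counts
are approximately negative-binomial while per-sample totals equal the
library size exactly. Because effects are planted before renormalization,
realized fold changes are approximate (compositional coupling) — tests
tolerate this, and planted effect *sizes* were chosen for testability; the
underlying study reports no per-taxon effect magnitudes to copy.

Genotypes are binomial(2, maf) with maf ~ U(0.05, 0.5) and positive
log-odds-ratio weights |N(0.15, 0.08)|; CD subjects' allele frequencies are
tilted along the weight vector (solved numerically) so their expected score
exceeds controls by 0.45, matching the direction and rough size of reported
risk-score gaps. No linkage disequilibrium is modeled.

Metabolite log intensities are normal per feature (mean ~N(7,1), feature
SD ~0.5); two designated features act as cholate (+shift·ln2 in CD) and
deoxycholate (−shift·ln2), with default shift 1 log2 unit and high baseline
intensity so the planted ratio difference of 2·shift·ln2 survives
missingness almost exactly. Entries go missing with probability
logistic(intercept − slope·log intensity) (defaults 8.8, 1.5 → ~15%
missingness, low-intensity ions preferentially lost). A two-batch
location/scale effect perturbs the noise and location but not the planted
structural means, so planted contrasts remain exact under batch effects.
The KO table is the incidence-weighted sum of taxon relative abundances,
renormalized per sample; the six bai KOs are carried exclusively by
CD-depleted taxa, so the pathway is depleted in CD by construction.

**What the generator does not emulate:** phylogenetic correlation between
taxa, taxon-specific PCR/extraction bias, overdispersion heterogeneity
beyond the gamma draw, chimeras/contaminants, LD between SNPs, retention
time drift or adduct structure in the metabolome. Passing tests therefore
demonstrate that the statistical machinery recovers effects under a
realistic but idealized data-generating process, not that it is robust to
every artifact of real MLI data.

## Problem sizes and numerical choices

Calibration tests use ≥200 replicates (or ≥300 independent features) per
procedure at n = 24–50 samples with 499 permutations for PERMANOVA;
recovery tests use the generator defaults (n = 50/group, |log2FC| = 2.5)
over 20–50 replicates. These sizes give the binomial acceptance intervals
stated in each test while keeping the full suite in the minutes range.
Dispersion floors (1e-8), the dysbiosis pseudocount (1e-6), and the
classifier's feature pseudocount (1e-6) guard logs and divisions;
degenerate inputs (constant terms, single-member classes, zero-variance
scores, all-missing features) raise named errors rather than propagating
NaNs, except where a documented fallback exists (dispersion trend values,
all-feature refinement, feature-mean imputation).
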