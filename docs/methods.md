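# Methods

## Scoring model

Each trait group k contributes a weighted polygenic score
`raw_ik = sum_j X_ij beta_jk` over its variants, with `X_ij` the
effect-allele dosage in [0, 2] and `beta_jk` the per-allele GWAS effect
size. The group score is then rescaled to a locus-count scale,
`scaled_ik = raw_ik / (sum_j beta_jk) * m_k`, where `m_k` counts the
variant records actually scored in the group (after alignment exclusions —
the harmonisation report states both the nominal and the aligned count).
Properties that follow and are enforced by tests: a constant dosage `c`
maps to exactly `c*m_k`; rescaling all of a group's effect sizes by a
positive constant leaves the scaled score unchanged; the score lies in
`[0, 2 m_k]`.

The divisor `sum_j beta_jk` is only meaningful when all weights are
positive, so harmonisation flips any negative-weight record to its other
allele (beta -> -beta, dosage read as 2 - dosage), the usual
trait-increasing-allele convention in published PRS work. With that
convention a signed and an absolute-value divisor coincide. A variant may
appear in two trait groups with different weights and even opposite
trait-increasing alleles; the scorer re-orients the stored dosage column
per weight record through its allele annotation.

Variant matching runs by identifier first, then by chromosome:position with
order-insensitive allele-pair agreement. Strand-ambiguous variants (A/T,
C/G) never match positionally — the allele pair cannot distinguish strands
— and can be dropped entirely with `drop_ambiguous`. Missing dosages are
kept missing in the genotype container (I/O is lossless) and mean-imputed
per variant at scoring time, computed on the scored cohort, which keeps the
`sum(beta)` denominator constant across individuals.

## Ancestry principal components

PCA standardises each variant by `(x - mean)/sqrt(2 p (1-p))` with
`p = mean/2`, sets missing values to 0 after standardisation, and takes the
singular decomposition. Monomorphic variants are excluded and listed. Each
component's sign is fixed so its largest-magnitude loading is positive,
making fits reproducible. Projection of a new cohort always uses the
*model's* means and scales (never the target cohort's); model variants
absent from the target contribute 0, and projection refuses to run below a
configurable 50% variant overlap. Downstream models use PC1 only by
default — in the motivating application it captures the east/west European
ancestry axis — with the component count configurable.

## The joint risk model

A maximum-likelihood logistic regression of one binary outcome on the ten
scaled wPRS, PC1, sex, age at diabetes onset (years) and diabetes duration
(years): 15 coefficients with the intercept, kept on natural units by
default (an option standardises predictors for contribution comparisons).
Perfect separation is detected and aborts the fit with a named error. The
multiPRS score used for all downstream ranking is the predicted
probability — monotone-equivalent to the linear predictor, and directly
interpretable in decile/event-rate displays.

Out-of-sample prediction uses tenfold cross-validation, stratified by
outcome (plain shuffled folds when a class is rarer than the fold count,
e.g. leave-one-out); every individual gets exactly one out-of-fold
probability and pooled predictions feed the AUC (per-fold averaging is
available behind a flag-level choice in the evaluation helpers).
Discrimination is the rank-based Mann-Whitney AUC with tie correction; its
CI is a seeded case-resampling bootstrap, percentile method, 2,000
resamples by default. Calibration is the Hosmer-Lemeshow statistic
`sum_g (O_g - E_g)^2 / (E_g (1 - pbar_g))` over equal-count bins of
predicted risk (10 by default), referred to chi-square with `bins - 2`
degrees of freedom; the p-value is exposed as `pi` (closer to 1 = better
fit). The continuous net reclassification improvement compares two scores:
`P(new>old|event) - P(new<old|event)` plus the mirrored non-event term,
ties contributing zero.

## Stratification

Quantile groups (deciles, thirds) are assigned by rank with stable
tie-breaking; group sizes differ by at most one. Top-k% thresholds take the
top `ceil(n*k)` individuals by score. The "frequency ratio" — outcome
frequency in the high-risk set over the remainder — is reported alongside a
conventional odds ratio to avoid ambiguity between the two. PPV/NPV are
prevalence-adjusted through Bayes' rule from sensitivity and specificity;
the prevalence defaults to in-sample and is user-overridable, since the
adjustment's source population is an analysis choice. The 3×3 genomic ×
age-at-onset grid computes empirical tertiles by default and accepts fixed
age cut points (published displays used bands such as <55 / 55–63 / >63).
The trend test is a logistic regression on the stratum index as a numeric
covariate with a Wald test — a parametric trend test within formal
regression.

## Treatment-response analysis

Within thirds of a risk score, any contrast of the 2×2 factorial design
(blood-pressure factor, glucose factor, or the extreme combined cells
intensive/active vs standard/placebo) is summarised by: a Cox
partial-likelihood hazard ratio (Breslow ties by default, Efron optional;
implemented via statsmodels PHReg) with Wald CI, a logrank test, and risks
at fixed horizons (defaults 4.5 y trial and 9.5 y trial-plus-extension)
taken from Kaplan-Meier cumulative incidence — assumption-light and
matching a frequency-of-events presentation. Follow-up is truncated at the
requested horizon so an "HR at 4.5 years" uses in-trial data only.
NNT = 1/ARR at the horizon, reported both real-valued and as the ceiling
integer; ARR <= 0 flags `harm_or_null` and leaves the NNT undefined. The
significance of the ARR is a seeded case-resampling bootstrap (two-sided
percentile), a convention of this package since no standard method is
implied by the quantity itself. A monotone partial likelihood (all events
in one arm) yields a degenerate 0/inf hazard ratio rather than an error.

## Risk-profile clustering

Each individual's profile is the vector of predicted risks from several
outcome models (six in the motivating display: myocardial infarction,
stroke, heart failure, major macrovascular events, cardiovascular and
all-cause death). Columns are z-scored before clustering so no single
outcome dominates the Euclidean metric (the source display shows z-scores;
whether clustering ran on raw or standardised risks was open, and
standardised is this package's choice). Complete-linkage agglomeration on
Euclidean distances is cut into k = 3 flat clusters (height-based cutting
available), relabelled L/M/H by ascending mean predicted risk —
deterministic given the partition and invariant to row order. Constant
profile columns cannot be standardised; they are kept raw and flagged.
High-vs-low cluster contrasts use a two-proportion z test for binary
variables and the Wilcoxon rank-sum test for continuous ones.

## Synthetic cohort generator

The generator emulates the data structure of a large type 2 diabetes
outcome trial with a 2×2 factorial design and ~4.5 years of trial plus ~5
years of extension follow-up. It is the test bed for every stage, with all
generative parameters recorded as ground truth.

* **Scoring file** — ten groups with per-group counts summing to 598 by
  default; effect sizes drawn half-normal with scale 0.08 (GWAS-scale
  log-odds magnitudes); random non-degenerate allele pairs.
* **Genotypes** — two subpopulations (balanced), Balding–Nichols
  allele-frequency divergence (beta-distributed subpopulation frequencies
  around a shared ancestral frequency, single Fst-like parameter, default
  0.01), Hardy-Weinberg within subpopulation, ancestral MAF uniform on
  [0.05, 0.5]. A separate null panel (default 2,000 variants) serves
  ancestry PCA, standing in at desk scale for a pruned genome-wide panel.
  No linkage disequilibrium — variants are independent by construction.
* **Covariates** — sex ~ Bernoulli(0.58), age at onset ~ Normal(58, 9²)
  clipped to [25, 90], duration ~ Normal(8, 6²) clipped to [0, 40].
* **Outcomes** — true effects are specified per SD of each predictor and
  resolved to natural units against the cohort's own predictor SDs;
  the resolved coefficients are recorded in `GroundTruth`. Binary outcomes
  follow `logit(P) = alpha + gamma'z` with the intercept calibrated by
  bisection to the target prevalence (±0.5 percentage points at n = 50,000
  by test). Survival outcomes (cardiovascular death, all-cause death, ESRD)
  follow an exponential model with rate `lambda0 * exp(gamma'z)` times
  arm- and risk-third-specific hazard-ratio multipliers, `lambda0`
  calibrated so the expected in-trial event fraction hits the target;
  their binary indicator is the in-trial event. Default prevalences follow
  the published period-prevalence spectrum (4–41%), and default effect
  magnitudes put oracle AUCs in the published 0.64–0.72 range, with the
  cardiovascular-death profile at ~0.72 / prevalence 0.07.
* **Treatment** — independent fair randomisation per factor. Default
  hazard-ratio multipliers concentrate the benefit of intensive therapy in
  the high-risk third (combined ~0.6 there vs ~1.0 in the low third for
  cardiovascular death), mirroring the effect pattern the analysis is meant
  to detect.
* **Censoring** — administrative at trial+extension; random exponential
  censoring off by default (so calibration targets are exact) and
  configurable.
* **Oracle AUC** — the Monte-Carlo AUC of the true linear predictor on a
  fresh cohort drawn from the same generative parameters (stored
  subpopulation frequencies, canonical PC model for projection, recorded
  coefficients and intercepts). It is the reference that cross-validated
  AUCs are compared to (recovery within ±0.02 at n = 20,000 by test).

Everything is deterministic given the config seed: fixed-tag child
generators per stage make weights, genotypes, phenotypes and all CLI
outputs byte-identical across reruns.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and genotyping error,
realistic genome coordinates, age-dependent (non-exponential) hazards,
competing risks, informative censoring, unmeasured confounding of
treatment response, and real multi-modal risk-profile structure (the
hierarchical clustering of smooth unimodal synthetic risk profiles yields
more imbalanced cluster sizes than published displays of real cohorts).

## Numerical choices and degenerate inputs

* Quantile-group ties break by stable input order; high-risk sets take
  exactly `ceil(n*fraction)` members.
* Bisection for intercept/baseline-rate calibration uses Brent's method on
  a bracketing interval; an unreachable prevalence raises a named error.
* Logistic fits run Newton iterations (statsmodels) to 200 iterations;
  non-finite coefficients or uniformly degenerate fitted probabilities are
  reported as separation.
* Hosmer-Lemeshow bins are equal-count splits of the rank-ordered
  predictions; degrees of freedom follow the realised bin count.
* PCA excludes zero-variance variants and reports them; projection refuses
  below 50% variant overlap.
* A trait group losing all variants at alignment is a hard error (the
  scaling rule is undefined at `m_k = 0`).
* Problem sizes in the test-suite simulations (e.g. n = 20,000 for
  discrimination recovery, n = 50,000 × 20 seeds for coefficient recovery,
  200 replicates of n = 2,000 for calibration type-I error) are chosen as
  the smallest scales at which the targeted sampling error is negligible
  relative to the tested tolerances.

## Known limitations

* LD pruning, kinship correction and genotype QC/imputation are out of
  scope; inputs are assumed harmonised biallelic SNPs.
* Clinical comparator scores enter reclassification as externally supplied
  probability columns; no coefficient sets for published clinical scores
  are bundled.
* Cumulative-hazard displays are stratified, not covariate-adjusted.
* The bootstrap NNT significance is a package convention, not a canonical
  method.
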