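# multiprs

Trait-grouped weighted polygenic risk scores (wPRS) and a joint **multiPRS**
logistic model for predicting the cardiovascular and renal complications of
type 2 diabetes, stratifying patients by genetic risk, and asking whether
intensive treatment helps the genetically high-risk most.

The package is aimed at statistical geneticists and trial biostatisticians
who want a tested, reusable implementation of this modelling pipeline — plus
a synthetic trial-cohort generator with full ground truth, so every stage
can be validated end to end without access to individual-level trial data.

## The model

Variants associated with ten groups of risk factors and outcomes
(diabetes, obesity, blood pressure, albuminuria, GFR, biomarkers, lipids,
stroke, CVD, low birthweight) enter one weighted PRS per group:

    wPRS_ik = sum_j X_ij * beta_jk

with `X_ij` the effect-allele dosage in [0, 2] and `beta_jk` the per-allele
effect size from the source GWAS. Because groups differ in locus count and
effect-size units, each group score is scaled by its summed effect sizes and
multiplied by its locus count `m_k`:

    scaled_ik = wPRS_ik / sum_j beta_jk * m_k

so every group lives on a locus-count scale (a constant dosage `c` maps to
exactly `c * m_k`). The **multiPRS** is the predicted probability of a
logistic regression of an outcome on the ten scaled wPRS, the first
ancestry principal component (PC1), sex, age at diabetes onset and diabetes
duration (15 coefficients with the intercept). It drives:

* **discrimination** — stratified tenfold cross-validation, Mann-Whitney
  AUC with case-resampling percentile-bootstrap CIs, AUC decomposition over
  predictor subsets;
* **calibration** — Hosmer–Lemeshow chi-square over deciles of predicted
  risk (p-value reported as `pi`);
* **reclassification** — continuous net reclassification improvement against
  an external comparator score;
* **stratification** — decile event-rate profiles, top-30%/top-10% high-risk
  thresholds with frequency ratios and prevalence-adjusted PPV/NPV, 3×3
  genomic-risk × age-at-onset grids with a regression trend test;
* **risk clustering** — complete-linkage hierarchical clustering of
  z-scored predicted-risk profiles into low/medium/high strata;
* **treatment response** — Kaplan–Meier curves, Cox hazard ratios (Breslow
  or Efron ties), logrank tests and the number needed to treat at a fixed
  horizon, within multiPRS thirds and for any contrast of a 2×2 factorial
  trial design.

## Worked example

```python
import multiprs as mp

cfg = mp.default_config(seed=7, n_individuals=8000)   # trial-like synthetic study
study = mp.simulate_study(cfg)

oof = mp.crossval_predict(study.scores, study.cohort, "cardiovascular_death",
                          folds=10, seed=1)
y = study.cohort.outcome_vector("cardiovascular_death")
disc = mp.auc_with_ci(oof["prob"].to_numpy(), y, n_boot=500, seed=2)
print(disc.auc, mp.oracle_auc(cfg, "cardiovascular_death", 50_000, seed=3))
```

prints `0.697` and `0.709`: the cross-validated multiPRS comes within a
hair of the oracle AUC of the true generative predictor. Continuing with
risk stratification (`examples/03_stratify.py`):

```text
event rate (%) by multiPRS decile:
  1.1   3.0   3.1   5.0   4.2   7.1   6.4   8.8   8.2  20.1
top 30% threshold: freq_ratio=2.89, PPV=12%, NPV=96% (prevalence 6.7%)
top 10% threshold: freq_ratio=3.85, PPV=20%, NPV=95% (prevalence 6.7%)
```

Event rates rise sharply in the last deciles and the top-30% of the score
holds ~3-fold enriched risk. The treatment analysis
(`examples/04_treatment_response.py`, n = 12,000) recovers the planted
benefit concentrated in the genetically high-risk third:

```text
stratum      HR           95% CI  logrank p     ARR   NNT
low        0.94 [ 0.58,  1.54]      0.817   0.002   575
medium     1.03 [ 0.70,  1.53]      0.873  -0.002     -
high       0.56 [ 0.42,  0.73]      0.000   0.061    17
```

Treating the high-risk third prevents one cardiovascular death per 17
treated; in the low-risk third the effect is indistinguishable from null.
The `examples/` directory has one short narrative script per capability;
each prints the numbers it computes and a line on what they mean.

A thin CLI mirrors the pipeline stages
(`multiprs simulate | score | fit | evaluate | stratify | treat | cluster`);
given the same `--seed`, reruns are byte-identical.

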