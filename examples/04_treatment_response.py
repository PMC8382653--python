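"""Treatment response by genetic risk stratum: Cox HR, logrank and NNT.

The simulated trial plants a survival benefit of combined intensive
therapy that is concentrated in the high-risk third. The analysis
stratifies the cohort into thirds of the multiPRS score and contrasts the
extreme cells of the 2x2 factorial design (intensive glucose + active BP
vs standard + placebo) within each third.
"""

import multiprs as mp

cfg = mp.default_config(seed=7, n_individuals=12_000)
study = mp.simulate_study(cfg)
outcome = "cardiovascular_death"

oof = mp.crossval_predict(study.scores, study.cohort, outcome, folds=10, seed=1)
times, events = study.cohort.survival_arrays(outcome)
tab = mp.stratified_treatment_table(
    times, events,
    study.cohort.table["arm_bp"].to_numpy(),
    study.cohort.table["arm_glucose"].to_numpy(),
    oof["prob"].to_numpy(),
    which="combined", horizons=(4.5,), n_boot=300, seed=2,
)

print(f"{'stratum':<8} {'HR':>6} {'95% CI':>16} {'logrank p':>10} "
      f"{'ARR':>7} {'NNT':>5}")
for _, r in tab.iterrows():
    nnt = str(r["nnt_int"]) if r["nnt_int"] > 0 else "-"
    print(f"{r['stratum']:<8} {r['hr']:6.2f} "
          f"[{r['hr_ci_low']:5.2f}, {r['hr_ci_high']:5.2f}] "
          f"{r['logrank_p']:10.3f} {r['arr']:7.3f} {nnt:>5}")

print("\nthe hazard ratio falls and the NNT shrinks in the high-risk third:")
print("treating the genetically high-risk prevents one death with far fewer")
print("treated individuals than treating the low-risk third.")
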