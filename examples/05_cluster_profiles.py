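"""Cluster individuals by their predicted-risk profile across outcomes.

Six outcome models (myocardial infarction, stroke, heart failure, major
macrovascular events, cardiovascular and all-cause death) give each
individual a six-dimensional risk profile; complete-linkage hierarchical
clustering on the z-scored profiles partitions the cohort into low/medium/
high strata, and the mortality contrast between the extreme clusters is
tested.
"""

import multiprs as mp

cfg = mp.default_config(seed=7, n_individuals=3000)
study = mp.simulate_study(cfg)

outcomes = ["myocardial_infarction", "stroke", "heart_failure",
            "major_macro", "cardiovascular_death", "all_cause_death"]
models = [mp.fit_multiprs(study.scores, study.cohort, o) for o in outcomes]
matrix = mp.build_profile_matrix(models, study.scores, study.cohort)
result = mp.cluster_profiles(matrix, k=3)

print("cluster sizes:", result.sizes)
print("fractions:", {k: f"{100*v:.1f}%" for k, v in result.fractions.items()})
print("\nmean predicted risk per outcome (rows = clusters L/M/H):")
print(result.mean_risk.round(3).to_string())

comp = mp.compare_clusters(result, study.cohort, "all_cause_death")
print(f"\nall-cause death: {100*comp.value_high:.1f}% in the high cluster vs "
      f"{100*comp.value_low:.1f}% in the low cluster (p = {comp.p_value:.2e})")
print("the unsupervised strata separate observed mortality, mirroring the")
print("supervised top-30% threshold's enrichment.")
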