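"""Trajectory-stratified survival and determinant models.

Per-year dominant clusters become a time-updating covariate in a flexible
parametric (log cumulative hazard spline) model; crude survival per
trajectory is summarised by Kaplan-Meier restricted mean survival time,
which also fixes the cluster labelling (label 1 = longest survival).
"""

import numpy as np

import mmtraj as mt

result = mt.run(mt.PipelineConfig(
    synthetic=dict(n_patients=600, k_true=3, hazard_ratios=(1.0, 2.5, 5.0)),
    k=3, n_restarts=8, max_iter=250, tol=1e-4,
    bootstrap_B=0, run_bootstrap=False, spline_df=4,
    out_dir="mmtraj_example_out", seed=8,
))

print("restricted mean survival time per trajectory (years):")
print(result.tables["rmst"].round(2).to_string(index=False))
print("\nlabels are ordered by RMST, so trajectory 1 survives longest; the "
      "planted per-cluster hazard ratios (1, 2.5, 5) should reappear as a "
      "decreasing RMST gradient.")

print("\nhazard ratios vs trajectory 1 (time-updating dominant cluster):")
print(result.tables["survival_hr"].round(3).to_string(index=False))

mn = result.tables["multinomial"]
age = mn[mn["term"] == "age_at_index"].round(3)
print("\nmultinomial determinants: relative risk ratio per year of baseline age")
print(age[["outcome_cluster", "rrr", "ci_low", "ci_high"]].to_string(index=False))
print("\n(the generator assigns older patients to clusters with worse "
      "survival, which relabelling puts at higher trajectory numbers, so "
      "RRRs above 1 recover that planted effect; the age_in_year term, "
      "conditional on baseline age, instead captures time on study)")
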