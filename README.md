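# mmtraj

Multimorbidity disease-trajectory modelling from longitudinal diagnosis
records.

People who survive a major index event such as a myocardial infarction go on
to accrue further acute and chronic conditions, and the *pattern* of that
accrual — not just its amount — predicts survival. `mmtraj` implements a
complete pipeline for discovering and validating such patterns in
person-level diagnosis histories:

1. **Person-time disease matrix.** Long-format diagnosis events are turned
   into a sparse binary matrix `A` (`u` person-year rows × `v` conditions).
   Each patient contributes one row per year of follow-up from their own
   index date. Chronic (long-term) conditions are carried forward from the
   year of diagnosis (including diagnoses before the index date); acute
   conditions mark only the year of occurrence, and pre-index acute events
   are ignored. All conditions are weighted equally.
2. **Non-negative matrix factorisation.** `A ≈ W·H` with `W ≥ 0` (`u × k`)
   and `H ≥ 0` (`k × v`), fitted by Lee–Seung multiplicative updates on the
   Frobenius objective with many random restarts. The rows of `H` are
   *disease clusters* (weighted groups of co-occurring conditions); each row
   of `W` gives a person-year's expression of every cluster. A rank scan
   reports MSE, generalised Kullback–Leibler divergence and the cophenetic
   correlation of the condition co-assignment consensus for each candidate
   `k`; the final rank is a user decision.
3. **Trajectories.** A person-year's dominant cluster is the argmax of its
   `W` row; a patient's *predominant multimorbidity trajectory* is the
   cluster with the greatest area under their cluster-expression–time
   curve. Clusters are relabelled by decreasing restricted mean survival
   time, so trajectory 1 always survives longest.
4. **Bootstrap stability.** The full procedure is repeated on bootstrap
   resamples; replicate clusters are matched to the originals by optimal
   assignment on cosine similarity of `H` rows, and per-cluster Jaccard
   indices of patient membership are summarised with percentile 95% CIs
   (mean JI > 0.75 ⇒ highly stable, < 0.5 ⇒ unstable).
5. **Outcome models.** Kaplan–Meier survival and RMST per trajectory; a
   Royston–Parmar flexible parametric model
   `ln H(t|x) = s(ln t; γ) + x'β` (restricted cubic spline in log time,
   default 6 df) fitted on left-truncated person-year episodes so the
   dominant cluster acts as a *time-updating* covariate, with age splines,
   hazard ratios, delta-method standardised survival curves, and optional
   non-proportional cluster effects; multinomial logistic regression for
   sociodemographic determinants of per-year cluster membership.

A synthetic EHR cohort generator with planted cluster structure,
trajectory-dependent exponential mortality and demographic assignment
effects provides a recoverable ground truth for every stage.

## Worked example

```python
import mmtraj as mt

result = mt.run(mt.PipelineConfig(
    synthetic=dict(n_patients=600, k_true=3, hazard_ratios=(1.0, 2.5, 5.0)),
    k=3, n_restarts=8, bootstrap_B=0, run_bootstrap=False,
    spline_df=4, out_dir="out", seed=8,
))
print(result.tables["rmst"].round(2))
print(result.tables["survival_hr"].round(3))
```

prints

```
 cluster  rmst  tau   n
       1 10.78 15.0 201
       2  6.86 15.0 165
       3  3.90 15.0 234

        term  person_years  hr_unadjusted  ...  hr_adjusted  a_ci_low  a_ci_high
cluster[ref]      2136.331          1.000  ...        1.000       NaN        NaN
  cluster[2]      1138.765          2.619  ...        2.751     2.118      3.573
  cluster[3]       935.465          5.359  ...        5.612     4.372      7.203
```

Trajectory 1 (longest restricted mean survival, 10.8 years over a 15-year
horizon) is the reference; the adjusted hazard ratios 2.8 and 5.6 recover
the planted per-cluster mortality ratios 2.5 and 5 from yearly-updated
cluster memberships. The `examples/` directory walks through each stage
(`01_cohort_and_matrix.py` … `04_survival_and_determinants.py`), and a thin
CLI (`mmtraj simulate | build-matrix | scan-k | run-all`) wraps the same
pipeline for shell use.

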