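# Methods

This note records the models implemented in `mmtraj`, their assumptions,
the defaults and why, and the design decisions taken where the methodology
left genuine choices open.

## Person-time disease matrix

Follow-up is discretised into anniversary years from each patient's own
index date (365.25-day years). A follow-up of `f` years yields
`max(ceil(f), 1)` rows: a final partial year contributes a full-weight row,
because the indicators are binary and "presence during the period" is the
semantics — there is no fractional-year weighting to apply. A death
mid-year therefore still emits that year's row; person-time *for the
survival models* is handled separately and exactly (see episodes below).

Encoding rules:

- A chronic condition diagnosed at any time up to the end of year `t` sets
  the indicator for years `max(0, t)` through the last row. Pre-index
  chronic diagnoses (unrestricted look-back) set the indicator from year 0.
- An acute condition sets only the year containing the event; acute events
  before the index date are ignored.
- Duplicate events within a year collapse to a single 1; conditions are
  weighted equally — no frequency or inverse-frequency weighting, which
  keeps common and rare conditions on the same footing.

The chronic carry-forward makes each patient's chronic indicators
monotonically non-decreasing over their rows, which is asserted as an
invariant in the tests.

## Factorisation

`A ≈ W·H` is fitted by multiplicative updates on the squared Frobenius
objective. The method literature plots both MSE and generalised KL
divergence as fit measures without fixing the minimised objective; we
minimise Frobenius (standard, fast, and matched by widely used library
implementations, which serve as a cross-check in the tests) and report KL
as a diagnostic. Because `A` is sparse, the objective is evaluated in
factored form, `‖A−WH‖² = nnz(A) − 2⟨WᵀA, H⟩ + ⟨WᵀW, HHᵀ⟩`, so an
iteration costs `O(nnz·k + (u+v)k²)` and the dense `u×v` product is never
formed.

Numerical choices: an elementwise floor of 1e-12 on `W` and `H` prevents
division by zero; restart `r` of a factorisation uses seed `seed + r`, so
runs are bit-identical; the best restart is the one with the lowest final
loss, ties to the lowest restart id; convergence is declared when the
relative loss change drops below `tol` (default 1e-5, cap 500 iterations —
the defaults are logged since published analyses rarely state them).
Headline factorisations default to 100 restarts.

Rank selection: the scan (default 10 runs per candidate `k`) records
best-run MSE and KL plus the cophenetic correlation of the condition
co-assignment consensus (a condition's cluster is the argmax of its `H`
column; consensus is computed over conditions, not person-years, because
`v` is a few hundred while `u` is large, and the condition-side consensus
is sample-size-free). The elbow suggestion is the maximal second difference
of the fit curve, but the final `k` is deliberately left to the analyst:
fit, parsimony, stability and interpretability all weigh in, and the
cophenetic coefficient in particular is advisory only — it is known to be
noisy across runs.

## Trajectories

`W` rows are used raw (unnormalised): argmax and area ranks are all that
downstream stages consume, and both are invariant to the uniform positive
rescaling that row-normalisation would apply. Areas under the
cluster-expression–time curve use unit-width rectangular integration —
person-time is already discretised to years. All ties break to the lowest
cluster label. An all-zero expression row receives the sentinel label 0
("none") and is excluded from cluster membership sets.

Final labels are assigned in *decreasing* order of per-trajectory RMST
(label 1 = longest survival), and the permutation is applied consistently
to `H` rows, `W` columns, memberships and every downstream table.

## Bootstrap stability

Each replicate draws `n` patients with replacement, rebuilds the matrix
(duplicated patients contribute duplicated row blocks, preserving the
bootstrap weighting), refactorises at the chosen `k`, and assigns
predominant trajectories. Replicate clusters are matched one-to-one to the
original clusters by maximising total cosine similarity between `H` rows
(a linear assignment problem); matching on `H` rather than on patient sets
keeps the criterion invariant to resampling. The exact matching rule of the
cited bootstrap-validation literature is not spelled out there, so this
rule is our declared choice. Jaccard indices compare the original and
matched replicate membership sets, restricted to patients present in the
replicate, counting a twice-drawn patient once (its first drawn block
decides its replicate trajectory). CIs are percentile (2.5/97.5 order
statistics) because JI is bounded. Replicate `r` is a pure function of
`(seed, r)`. Within-replicate restarts default to 20 (reduced from the
headline 100 to keep `B = 1000` tractable; configurable and logged).

## Survival and determinants

**Episodes.** Each person-year becomes one left-truncated episode
`[y, min(y+1, f))` carrying that year's dominant cluster; the death
indicator sits on the final episode. Because year boundaries are integers
and the final stop equals the follow-up value itself, summed durations
telescope to the exact follow-up in floating point — conservation is
asserted with equality, not a tolerance.

**Flexible parametric model.** `ln H(t|x) = s(ln t; γ) + x'β`, with `s` a
restricted cubic spline: `spline_df` basis terms, interior knots at equally
spaced centiles of the uncensored log event times, boundary knots at their
extremes, cubic terms scaled by the squared boundary span for conditioning
(`spline_df = 1` is Weibull). Default 6 df. Each episode contributes
`d·ln h(stop) + ln S(stop) − ln S(start)`; the likelihood is maximised by
BFGS with an analytic gradient, started from the exponential-model solution.
Coefficient covariance is the inverse observed information (finite
differences of the analytic gradient). The fit refuses to return a model
whose cumulative hazard is non-monotone anywhere on the observed time range
for any fitted covariate pattern. BIC uses the number of events as the
sample size. Splitting a subject into yearly episodes leaves the likelihood
(and hence the estimates) unchanged — tested — which is what justifies the
time-updating covariate construction. An independent cross-check against R's
`flexsurv` spline model on identical data agrees on coefficients and
log-likelihood to ~1e-3.

Age enters through its own restricted cubic spline. The source methodology
states 3 df in one place and 5 df in another; the default is 3 and the
value is configurable. Deprivation quintile and rurality enter as indicator
variables; the reference cluster is label 1 (longest RMST).

Non-proportional cluster effects are available as cluster × log-time-spline
interactions with a separate small spline (default 2 df), off by default —
the exact interaction specification is not fixed by the methodology, and
the proportional model is the primary object.

**RMST.** Area under the KM step function to `tau`, extending flat past the
last observation; `tau` defaults to the maximum observed follow-up. The
"continuity correction" sometimes attached to KM-based RMST is not defined
precisely in the sources we follow, so the default is the plain step-function
area with an optional trapezoid (half-step) variant exposed.

**Unadjusted vs adjusted hazard ratios.** Both use the time-updating
cluster covariate by default (whether published unadjusted estimates fix
the predominant trajectory instead is not stated; fixing it is a one-line
change on the episode table).

**Multinomial model.** Softmax regression of per-year dominant cluster on
age in the given year, baseline age, sex, index year, deprivation and
rurality, reference = cluster 1, fitted by Newton MLE. The unit of analysis
is the person-year and within-person correlation is ignored — standard
errors are those of an independence working model, and the output notes
this. Note that conditional on baseline age, the "age in year" coefficient
captures time-on-study.

## Synthetic cohort generator

The generator emulates the *structure* of a post-index diagnosis history:
an index event per patient; pre-index chronic accrual; per-year first
diagnoses of chronic conditions and recurrent acute events; a latent
per-patient cluster label selecting a disjoint signature condition set;
exponential survival with a per-cluster hazard ratio; administrative
censoring; demographics (age ~ Normal(72, 10) truncated to 30–99, 40.6%
female, five deprivation quintiles, urban/town/rural at 68/18/14%) with a
multinomial-logit link from age and sex to the cluster label. Defaults:
2000 patients, 4 clusters, signatures of 8 conditions (6 chronic + 2
acute), per-year signature rates 0.25 (chronic first diagnosis) and 0.30
(acute), background rate 0.02, pre-index signature seeding 0.30, baseline
hazard 0.05/year with cluster ratios (1, 1.5, 2.5, 4), 15-year horizon —
chosen once as a well-separated but noisy regime at the scale of a
desk-size epidemiological simulation.

Deliberate simplifications, and hence what passing tests do *not* show
about real data: the latent label is fixed per patient (no trajectory
transitions — the predominant-trajectory concept needs a recoverable single
label; a transition option would be a config extension); survival is
exponential per cluster so that medians and RMSTs have closed forms for use
as oracles; events are dated mid-year because the matrix only resolves
years; condition co-occurrence beyond the planted signatures, coding noise,
misclassification and competing risks are absent. Real diagnosis data are
far less separable, so recovery rates measured here are upper bounds on
practice, not estimates of it.

The packaged default condition dictionary
(`data/default_conditions_synthetic.csv`) is a synthetic stand-in carrying
the class balance of the CALIBER-derived condition set used in post-MI
multimorbidity work (62 acute, 227 chronic); its identifiers are not real
phenotype codes.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by the package's own
choice: planted-recovery checks use 2000 patients (≈16k person-years),
the rank scan uses 5 runs per `k` over `k ∈ [2, 8]` with a 200-iteration
cap, bootstrap calibration uses `B = 100` with 5 restarts per replicate,
and hazard-ratio CI coverage uses 60 simulation replicates of 500 subjects.
Every stochastic stage takes an explicit seed; the whole pipeline is a pure
function of its config and master seed, and rerunning it reproduces
byte-identical output files (content hashes are recorded in the manifest).

## Known limitations

- The NMF objective is non-convex; restarts mitigate but do not eliminate
  local minima, and rank selection remains a judgement call.
- Percentile bootstrap CIs for the Jaccard index can be short near the
  boundary (JI ≈ 1).
- The flexible parametric fit assumes episodes are conditionally
  independent given covariates; frailty/random effects are out of scope.
- Multinomial standard errors ignore within-person clustering.
- The generator's independence assumptions (see above) make it a
  correctness instrument, not a realism benchmark.
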