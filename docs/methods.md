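# Methods

## Time and measurement conventions

All times are signed days relative to therapy start (day 0), with fixed
conversions 1 month = 30.4375 d and 1 year = 365.25 d, so that clinical
windows stated in months/years have exact, testable boundaries. EDSS lives
on the grid {0} ∪ {1.0, 1.5, …, 9.5}; off-grid values are rejected.

## PIRA detection

PIRA is confirmed disability worsening in a follow-up free of relapses.
The detector runs a single chronological scan per patient:

* **Cleaning.** Scores within 30 days (inclusive) of any relapse are
  ignored throughout.
* **Baseline.** The cleaned score closest in time to therapy start within
  (−365.25 d, +30.4375 d]; at equal |t| the pre-start score wins, since
  the pre-treatment state is the epidemiologically intended reference.
* **Worsening.** An increase from the current baseline of ≥ 1.5 points if
  the baseline is 0, ≥ 1.0 for 1–5.5, ≥ 0.5 for 6–9.5. Events must occur
  in (+1 mo, +6 y]; confirmation requires a score ≥ 12 months after the
  event with every score in the confirmation interval at or above the
  threshold level (baseline-at-event + required increase, fixed at event
  time). Scores recorded after 6 years may still confirm. The first
  confirmed event ends the scan.
* **Roving baseline.** The improvement magnitude that triggers
  re-baselining is not part of the worsening criteria, so the package
  mirrors the worsening structure: any decrease ≥ 0.5 (one grid step)
  below the current baseline, confirmed by a score ≥ 3 months later with
  all interim scores strictly below the current baseline, resets the
  baseline to the minimum score over the confirmation interval (earliest
  confirming score). The reset takes effect immediately after the
  improvement-onset score; improvement is evaluated before worsening at
  each score, so improved-then-worsened trajectories are judged from the
  improved level. These choices are parameters of `PIRAParams`.

Correctness is established by exhaustive agreement (~16k trajectories on
a coarse grid, plus seeded random property tests) with an independent
O(n³) oracle written directly from the definitions. One property worth
noting: with a roving baseline, *raising* a late score can legitimately
remove an event, because improvement confirmation requires interim scores
strictly below the baseline — monotonicity of the event in single scores
holds only for trajectories without re-baselining.

## Synthetic cohort generator

The generator emulates a therapy-start-anchored registry extract; its
defaults are frozen study conditions, not tuning knobs.

* **Demographics** follow the printed cohort: age ~ Normal(40.4, 10.6²)
  truncated to [18, 75]; 71.4% female; education, region, civil status and
  country of birth at the printed marginal frequencies; income a mixture
  (15% low-income uniform on [0, 60), else log-normal around 230) giving a
  right-skewed distribution with median ≈ 210 thousand per year.
* **Baseline EDSS**: category probabilities 74.9 / 20.4 / 4.7%
  (mild 0–2.5, moderate 3–4.5, severe 5–9.5), value uniform on the grid
  within the category.
* **Visits** every 182 d with ±30 d uniform jitter and 15% independent
  missingness, from −182 d to 7.5 y (the horizon extends past 6 y so that
  late events can be confirmed). The source registers do not dictate a
  cadence; these are assumptions exposed in `GeneratorConfig`.
* **Progression truth**: latent progressor status ~
  logistic(−1.44 + 0.018·(age − 40) + 0.25·(EDSS − 2)); progressors
  receive one sustained step of threshold + 0.5 (capped at the 9.5
  ceiling) at an onset time uniform on (1 mo, 6 y]. The intercept and age
  coefficient were frozen by a one-time grid search against the detector
  so the default cohort yields ≈ 20% detected incidence overall and ≈ 24%
  at age ≥ 50; the EDSS coefficient was fixed a priori to reproduce the
  direction of baseline-disability enrichment among progressors.
* **Measurement noise**: each observed score carries ±0.5 jitter with
  probability 0.10 (snapped to the grid), which makes non-progressors
  fluctuate mean-revertingly around baseline and occasionally produces
  false events/re-baselines, as in real scoring.
* **Relapses**: ~0.5/year in the pre-start year (exercising the
  relapse-proximal score exclusion) and 0.01/year during follow-up
  (exercising the relapse exclusion criterion; affected patients are
  removed, as in the study design).
* **Comorbidity histories**: per-patient Bernoulli flags at fixed
  prevalences (depression/anxiety 0.36, hypertension 0.15, headache 0.08,
  migraine 0.08, hyperlipidemia 0.06, …) realized as 1–3 ICD-10 records
  and/or ATC dispensations drawn uniformly over the 5-year lookback, plus
  58 background ICD categories (prevalences 0.4–7%, disjoint from every
  pre-specified prefix) and post-index noise records that the lookback
  window must ignore. One category (N31 by default) is planted with
  prevalence 5.5% in latent progressors vs. 2.4% in non-progressors,
  giving the phenome-wide screen a recoverable signal with implied crude
  OR ≈ 2.37.
* SDMT and MSIS-29 carry 28% missingness, matching the printed
  missing-data profile, so the imputation stages have real work to do.

What the generator does **not** emulate: register coding practice and
setting-specific code distributions, income/education dynamics, regional
care patterns, relapse-associated worsening, EDSS rater drift, or
correlated visit attendance. Passing tests therefore demonstrate that the
algorithms implement their definitions and recover planted structure at
realistic sample sizes — not that real-world effect estimates would be
reproduced.

## Association analyses

The two-sided Fisher exact p-value uses the point-probability convention
(sum of hypergeometric probabilities ≤ the observed one) with a 1e-7
relative tie tolerance, computed in exact integer arithmetic so that tie
handling is platform-independent; tests verify exhaustive agreement with
an independent Fraction-based enumeration (all tables with n ≤ 40) and
with `scipy.stats.fisher_exact`. Categories are screened after a [1%,
99%] prevalence filter (boundaries kept, per the strict "> 99%" reading)
against a Bonferroni threshold 0.05/k.

Crude and adjusted ORs come from maximum-likelihood logistic regression
(Wald 95% CIs, the convention of OR forest plots); separation is flagged,
never silently reported. For the adjusted model, missing covariates are
imputed by chained equations (default m = 20 datasets, 10 iterations):
Bayesian linear-regression draws for numerics and multinomial-logistic
draws for categoricals, with the outcome included as a predictor;
estimates are pooled by Rubin's rules (T = W + (1 + 1/m)B, t reference
with df = (m−1)(1 + W/((1+1/m)B))², normal when B = 0). The ICD-category
block is excluded from imputation models. Chained equations are
implemented in-package because the surrounding libraries do not provide
multinomial chained equations with independent seeded chains.

## Prediction benchmark

Predictor sets are cumulative: demographics (6 variables); + MS
characteristics (therapy-start year, disease duration, prior DMTs, prior
relapses, baseline EDSS, SDMT, MSIS-29 physical/psychological); + the 17
pre-specified flags; + the retained ICD categories. Preprocessing is
fitted inside each training partition: explicit-level handling of missing
nominals, dummy encoding (reference level dropped for elastic net and the
neural network; full one-hot for tree models), bagged-tree imputation of
missing numerics (25 trees; predictors are the outcome plus the current
set minus ICD categories — at prediction time the outcome column is used
when present, mirroring recipe-style baking in resampling), then
normalization with training statistics.

Hyperparameters follow the fixed/tuned split — random forest 1000 trees;
XGBoost 1000 trees with 10 stopping rounds (20% of the training fold held
out for stopping); neural network 50 hidden units — with 4-level
full-factorial grids for the tuned ones: elastic net penalty
{1e-4…1e-1} × mixture {0, ⅓, ⅔, 1}; random forest mtry √p·{0.5, 1, 2, 4}
× min node size {2, 5, 10, 20}; XGBoost learning rate {0.01, 0.05, 0.1,
0.3} × max depth {2, 4, 6, 8} × min child weight {1, 3, 5, 10}; neural
network weight decay {1e-4…1e-1} × epochs {25, 50, 100, 200}. Outer
resampling is 10 folds × 3 repeats (stratified by outcome to stabilize
small-fold AUC), inner tuning 5-fold, selection by mean inner Brier
score; SEs are SD/√30 over outer folds. AUC uses the Mann-Whitney form
(ties count ½); calibration bins use quantile edges computed from the
predicted probabilities of outcome-positive observations only, collapsing
duplicates.

A reduced **demo profile** (elastic net, 2 outer repeats, 2-level grids,
n ≈ 250–500) is the default in the pipeline and tests; the full 4 × 4
grid benchmark at n = 2837 is available through `PipelineConfig`
(`demo=False`, all families) and scales linearly in folds × grid size.

## Numerical and degenerate-input choices

* Zero-margin 2×2 tables: Fisher p = 1 by convention; OR fits on constant
  exposures raise (pipeline reports a non-converged row).
* EDSS jitter snapping: 0.5 is off-grid; downward noise from 1.0 goes to
  0, upward noise from 0 goes to 1.0.
* Rank-deficient logistic designs raise before fitting; MICE refuses
  columns with no observed values.
* Unseen nominal levels at transform time map to an all-zero dummy block.
* All randomness flows from a single integer seed per entry point
  (generator, MICE chains, per-fold learner seeds); reruns are
  byte-identical, which the manifest digests verify.

## Known limitations

* The pre-specified comorbidity code lists are editable defaults from
  standard groupings, not an authoritative register protocol.
* The planted-signal design ties the data-driven screen's power to a
  single category; interactions and code co-occurrence are not simulated.
* The latent progression model is a step function; gradual worsening,
  relapse-associated worsening, and regression to severe EDSS states are
  out of scope.
* Adjusted-OR pooling assumes the per-imputation log-OR is approximately
  normal; with very sparse exposures the Wald intervals (and hence the
  pooled CI) are unstable, which the non-convergence flag surfaces but
  does not fix.
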