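# Methods

`landboost` implements dynamic, yearly-updated 1-year risk prediction from
longitudinal clinical event tables, organised around *landmark analysis*: at
each landmark time t (t full years since diabetes onset) a model is built
from data recorded strictly before the landmark and predicts the probability
of a first event (diabetic kidney disease, DKD) in the following year, among
patients still at risk and observable at t.

## Phenotyping rules

**Diabetes onset** is the earliest day satisfying any of: (1) a
glucose-lowering-medication record (a single record qualifies by default;
configurable); (2) HbA1c >= 6.5%, random glucose >= 200 mg/dL or fasting
glucose >= 126 mg/dL on two different dates within 2 years; (3) two
type-1/type-2 diabetes diagnoses on two days within 2 years; (4) any two
distinct event types among (1)-(3), with no additional proximity window
imposed across types. Gestational-diabetes-flagged events are discarded
before any criterion is evaluated. For the two-date criteria, onset is
anchored at the earlier day of the earliest qualifying pair.

**Kidney status**: eGFR is the 4-variable MDRD estimate with the
IDMS-traceable 175 coefficient (configurable),
`175 * SCr^-1.154 * age^-0.203 * 0.742[female] * 1.212[black]`, with age
taken at the lab date. A day is *abnormal* when eGFR < 60 mL/min/1.73 m²
(exclusive) or a urine albumin- or protein-to-creatinine ratio >= 30 mg/g
(inclusive). The 30 mg/g protein-to-creatinine threshold is low relative to
common clinical practice; it is implemented as specified and exposed in
`PhenotypeConfig.ratio_threshold`.

**Outcome sequences**: the yearly status is read off the *last outpatient*
kidney lab in each window `[365t, 365(t+1))` days since onset (same-day
duplicates averaged; a valid lab is numeric, positive, outpatient); a year
without a qualifying lab is NA, with no imputation; the sequence truncates
after the first 1. **Eligibility at t** requires a non-NA status at t and
no earlier event; an NA year does *not* censor later windows (a patient can
be NA in year 1 and eligible again in year 2). Cohort inclusion requires
adulthood at onset, at least one valid outpatient kidney lab at/after onset,
no type-1/cystic-fibrosis-related diabetes diagnosis and no kidney
abnormality before onset; one patient may hit several exclusion criteria,
so exclusion counts may sum to more than the number excluded. Statuses and
end points are evaluated within the configured horizon (default 5 years).

## Temporal representations

All designs obey one leakage rule: a cell at landmark t may use only events
strictly before day 365t. History is carved into t+1 windows — window 0 is
the pre-onset history, window w >= 1 is `[365(w-1), 365w)`. Feature
identity is `domain|code|modifier`; a feature is numeric if it ever carries
a value (a schema-level property, like the rare-feature filter, computed on
the training split over the full record). Numeric absence is *missing*;
binary absence is 0. Same-day duplicate numeric observations are averaged;
within-window aggregation is last-value (consistent with the latest-value
rule). Demographics (age at landmark, sex, race) and two engineered history
counts (cumulative distinct features before t, increment since t-1) are
appended to every design. Features observed in fewer than 1% of training
patients are dropped.

* **latest-value**: last observed value per feature before the landmark;
  time-agnostic.
* **stack-temporal**: one column per (feature, window); width grows
  linearly in t+1.
* **discrete-survival**: pooled person-period rows over all landmarks,
  predictors from the immediately preceding window plus a window-index
  column, rows treated as independent; one model serves all landmarks.
* **landmark-boosting**: latest-value predictors plus the previous
  landmark's predicted risk carried as a log-odds offset (below).

## The boosted learner

A second-order (Newton) boosting implementation of the binomial log-loss
with sparsity-aware splits: per round, gradients `g = p - y` and hessians
`h = p(1-p)` are evaluated at the current margin (which includes any
per-row base offset); trees are grown by exact greedy search over all
midpoints of observed values, scoring *both* routings of missing values at
every node and keeping the gain-maximising direction, plus a pure
present-vs-missing candidate; leaf weights are `-G/(H + lambda)` with L2
penalty `lambda = 1` by default; `min_child_weight` bounds the hessian sum
per child. Before any trees, a scalar intercept is fitted by Newton's
method on the offset logistic model; with an informative base margin this
absorbs population-level shifts in the event rate between landmarks, which
AUROC-driven early stopping would never correct (AUROC is invariant to a
constant shift). A zero tree budget skips the intercept so the ensemble
stays the identity on its offset.

Tree count is chosen by early stopping on holdout AUROC (20% stratified
holdout, patience `early_stop_rounds`, default 100); depth, learning rate
and `min_child_weight` are tunable by stratified K-fold cross-validated
AUROC (`tune_by_cv`, default 10 folds; the out-of-fold set doubles as the
early-stopping holdout within each fold; ties prefer shallower, slower
configurations). Conventional tuning ranges are depth 2-10, learning rate
0.01-0.1, min-child-weight 1-10; depth 1 is additionally allowed for
diagnostics. Models serialise to JSON with hex-encoded floats and
round-trip bit-exactly.

## Landmark-boosting

At t=0 the model is a plain boosted fit. At t >= 1 each eligible patient's
base margin is the previous landmark's predicted log-odds (clipped to the
logit of [1e-6, 1-1e-6]), computed recursively; patients eligible at t
without a t-1 prediction (an NA year) cold-start at the logit of the
landmark-t training prevalence (configurable; `0` is the alternative). New
trees are fitted on top with the tree cap (1000 by default) and early
stopping; hyperparameters are re-tuned at each landmark when a grid is
supplied (a reuse switch keeps the first landmark's choice).

One detail matters in practice: margins carried for *training* patients are
computed out-of-fold (3-fold cross-fitting with the stage's own
configuration). An in-sample carried margin is optimistic during training
but honest at prediction time, so the incremental trees systematically
underfit the true correction; cross-fitting removes the asymmetry. The
test-time recursion always uses the full fitted models.

Risk trajectories report, per patient and landmark, the predicted
probability and its percentile within the concurrent test population
(average-rank ties, scaled to [0, 100]).

## Evaluation protocol

Per landmark and method on the test split: AUROC (Mann-Whitney, ties 1/2)
and AUPRC (precision-recall step curve, no interpolation); sensitivity,
specificity, PPV and NPV with the top `ceil(0.4 n)` predicted risks flagged
positive (stable score-then-index tie-break); percentile bootstrap
intervals (2.5th/50th/97.5th of 30 resamples by default; single-class
resamples are redrawn, up to 100 attempts). Calibration uses 20 equal-width
probability bins with O (observed events), E (sum of predicted
probabilities), the O:E ratio, and an exact binomial tail test in the
direction of the discrepancy (Poisson alternative available); a bin is
overpredicted when p < .05 and O < E, underpredicted when p < .05 and
O > E. Pearson r between predicted probability and outcome summarises
linear agreement. Feature-importance drift ranks features per landmark by
normalised total split gain (dense ranks; absent features rank
n_features+1) and correlates rank with landmark index (r < 0 = rising
importance).

The experiment design is an 80/20 *patient-level* split (train size
`round(0.8 n)`), the rare-feature filter computed on training patients
only, training on the train split, rolling prediction of eligible test
patients, and a case-mix table (eligible n, event %, age, sex, race per
landmark per split). All randomness derives from the experiment seed and
reruns reproduce the report bundle byte for byte.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not clinical semantics. Each patient has latent traits, one per feature:
standard normal for numeric features, Bernoulli carrier indicators for
binary ones. The true hazard at landmark t is
`sigmoid(logit(h0_t) + beta_t . centred_traits)`; effects act on centred
traits so `h0_t` is an average patient's event probability. Latent event
year, NA years (no qualifying lab) and yearly dropout produce the observed
sequence; one outpatient creatinine-or-ACR lab per non-NA year encodes the
realized status (creatinine values are inverted through MDRD for the
patient's age/sex/race); two qualifying HbA1c records anchor onset at day
0; patients exit after their first observed event year.

Observation timing: per (patient, feature) stream, the patient's mean gap
is a shifted lognormal (floor mean/3) around the domain's configured mean
with the configured between-patient SD, and successive gaps are Gamma with
the configured within-patient SD — both stages preserve the configured
mean exactly. Default intensities follow the observed-intensity profile of
a real integrated repository (visit events every ~36 days, medications ~70,
diagnoses ~87, labs ~107, with large within- and between-patient SDs).
Yearly Bernoulli thinning (`feature_sparsity`) makes features observed
only in some patient-years. Observed numeric values are the latent trait
plus measurement noise (default 0.8 feature-SDs — within-person lab
variability of the same order as between-person differences). An optional
AR(1) on numeric traits (`latent_autocorrelation < 1`) makes risk profiles
evolve; the presets keep traits static. Each patient draws from an RNG
stream derived from (seed, patient index), so generation is reproducible
under parallelism, and identical configs give byte-identical tables.

**Presets** (n=4,000 by default): 32 latent features across four domains,
sparsity 0.5, noise 0.8, NA rate 0.15, dropout 5%/year, and baseline
hazards rising 15.63% -> 25.73% over the five landmarks (the case-mix
shift) in *both* presets, so effect drift is the single difference between
them. `time_constant` uses one effect vector (many weak-to-moderate
effects, |beta| 0.25-0.65) at every landmark. `time_varying` rotates the
effect vector smoothly by 45 degrees total toward a second vector; most
components change magnitude and several flip sign by t=4 — gradual drift,
the regime where carrying a previous model's prediction forward is
informative. Development exploration showed the boundary of that regime
clearly: under fast change (a 90-degree rotation, or strongly
autocorrelated evolving traits) the fixed-weight carried offset is stale
and per-landmark refitting wins; this is a structural property of
offset-based sequential ensembling, not an implementation artifact.

What passing tests on these cohorts do *not* show: the generator has no
code semantics, no comorbidity structure, no informative missingness
beyond carrier-only binary events, static (by default) risk profiles, and
hazards exactly logistic in the latents — real EHR performance claims do
not follow.

## Acceptance protocol sizes

The packaged acceptance checks use: 50 random 20-row instances for the
split-search oracle; 100 random instances for the metric oracles; the
method comparison at n=4,000 with 10 replicate seeds, scored as the mean
test AUROC over landmarks t >= 2, with a fixed training configuration
(depth 3, learning rate 0.1, min-child-weight 1, 150-tree cap, 20-round
patience) rather than a per-landmark CV grid (the grid path is exercised
at unit scale); the four-method comparison under constant effects on one
seed; calibration at n=10,000 on one seed; end-to-end determinism at
n=600. Under constant effects the four methods do not meet within 0.03
AUROC: stack-temporal degrades at late landmarks (its width grows with t
while eligible samples shrink) and the carried offset retains a small
advantage even without drift (accumulated noisy observations help
regardless); the measured spread is typically 0.03-0.06.

## Known limitations

* The carried offset enters with fixed weight 1; no mechanism discounts a
  stale baseline, so the method degrades under fast temporal change (see
  above).
* Early stopping maximises holdout AUROC; calibration is protected only by
  the Newton intercept and the log-loss objective, not targeted directly.
* The exact-greedy learner has no column/row subsampling or histogram
  binning; it is intended for desk-scale designs (thousands of rows,
  hundreds of columns).
* Phenotyping treats codes as opaque strings; all clinical vocabulary
  mapping is the caller's responsibility via `PhenotypeConfig`.
* The discrete-survival representation treats person-period rows as
  independent, so its bootstrap intervals ignore within-patient
  correlation, as is conventional for that design.
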