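# Methods

## The five-state process

A patient's morbidity state is the number of active long-term conditions
(LTCs), capped at three, plus an absorbing death state:
S0 → S1 → S2 → S3+ with single-step moves in both directions, and death
reachable from every living state — ten transitions. The cap keeps the state
space interpretable; uncapped counts are still tracked for classification
and descriptive tables, so a patient moving from four to three conditions is
Remitted even though both counts map to S3+.

The process is assumed time-homogeneous and Markov ("memoryless"): the
intensity of each move depends on the current state and on fixed baseline
covariates, not on attained age or history. Covariates enter log-linearly
per transition, `q_rs(x) = q⁰_rs·exp(β_rs·x)`, with dummy coding and
reference categories fixed at zero (age 18–39, male, White ethnicity, least
deprived IMD quintile, risk factor never present). Each fitted model carries
the age block plus exactly one exposure block, mirroring the convention of
fitting separate models per exposure rather than one saturated model.

## Observation schemes and likelihood

EHR condition events are dated, so the **exact-times likelihood** is the
primary mode: a sojourn of length `d` in state `r` contributes `q_rr·d`
(minus the total exit rate times duration), each observed jump `r→s` adds
`log q_rs`, and a censored final sojourn contributes only its survival term.
This likelihood factorises over transitions into independent Poisson
likelihoods with log-exposure offsets — jump count `d_i` against person-time
at risk `T_i` — which the fitter maximises per transition by BFGS
(quasi-Newton) from the crude-rate initialiser `log(Σd/ΣT)`, after
collapsing patients with identical covariate patterns. Standard errors come
from the inverse observed information, which for this likelihood has the
closed form `Σ T·exp(η)·zz'`; Wald 95% intervals are `exp(β ± 1.96·se)`.

A **panel mode** is provided for sensitivity analysis: the state is treated
as known only at snapshot times, each interval contributing an entry of
`expm(Δt·Q)`, with a terminal jump into death handled as exactly timed
(`Σ_r P(Δt)[s,r]·q_r,death` over living `r`). Panel mode optimises the full
parameter vector by bounded L-BFGS-B with a finite-difference Hessian for
the covariance; it is intended for modest cohorts. The two likelihoods
differ by a parameter-free discretisation Jacobian (one `log Δt` per
interior jump), so numerical agreement of the *likelihoods* is checked on
paths whose only jump is death, while agreement of the *estimates* is
checked with a dense panel snapshot grid (`panel_grid` option).

Transitions with zero observed jumps in a stratum — and covariate
categories in which no jumps occur — are reported as **NA** rather than
regularised, matching how low-number cells are handled in stratified
hazard-ratio tables. Prediction treats NA transitions as rate zero and
flags them in the report.

Transition probability matrices use scipy's scaling-and-squaring Padé
`expm`; rows are validated to sum to one within 1e-8 (violations raise
rather than being silently renormalised beyond that tolerance). Mean
sojourn times are `-1/q_rr`, infinite when a living state has no exits.

## Building state histories from events

The state at time `t` (years since follow-up start, 365.25 days/year) is
`min(3, #{conditions with onset ≤ t and no resolution ≤ t})`. Conventions:

* Onsets dated on/before follow-up start set the starting state.
* Resolutions dated on/before follow-up start are ignored entirely: the
  condition counts at baseline and never produces a downward transition
  (the convention required for cancer remission codes, which predate
  follow-up).
* Resolutions dated after follow-up end leave the condition active
  throughout the window; onsets after follow-up end are dropped with a
  warning (strict mode raises).
* Same-day records are sequenced deterministically — resolutions before
  onsets, then alphabetically by condition code — and spaced by a
  configurable epsilon (default one day, 1/365.25 years) so that every
  consecutive pair of states differs by a single step regardless of input
  row order. If a cluster of same-day records would spill past the end of
  follow-up, the tail is compressed into the remaining window.
* A zero-length episode (onset and resolution the same day) never affects
  the count.

Classification compares **uncapped** counts at start and end of follow-up:
death → Progressed; otherwise more → Progressed, fewer → Remitted, equal →
Stable. Descriptive tables report class shares, per-category cross-tabs with
row percentages, follow-up medians (IQR), and LTCs acquired/resolved banded
0/1/2+. An opt-in low-number suppression threshold renders small cells as
"≤n". The patient record carries age *group* rather than continuous age, so
age is summarised as a categorical cross-tab.

## Mean cumulative function

The MCF is the Nelson–Aalen-type recurrent-event estimator: at each distinct
onset time `u`, the curve increments by (onsets at `u`) / (subjects still
under follow-up at `u`). Subjects exit the risk set at deregistration or
death — death is censoring, not a competing risk — and resolutions never
decrement the curve. Ties between an event and a risk-set exit at the same
time are resolved events-first. Onsets dated on/before follow-up start are
baseline conditions: they stratify (the baseline-LTC-count panel) but never
increment. No variance bands are drawn. With mortality increasing in the
morbidity state the estimator can be biased upward relative to a
competing-risk treatment; this is a documented limitation, not a corrected
one, and no test asserts a bias direction.

## Disease-sequence chains

Per patient, first-ever onsets are ordered by date (same-day ties broken
alphabetically), a Death token is appended for deceased patients, and
resolutions are ignored. "One time step" means the next acquisition event,
not a calendar interval. Adjacent pairs pooled over patients give the
maximum-likelihood first-order transition matrix over the 32 conditions plus
Death; rows with no observations are flagged empty, the diagonal is
structurally zero (only first onsets enter), and Death has no outgoing mass.
Pre-follow-up onsets are included by default since their dates are recorded
(`include_prior=False` restricts to in-window onsets). Top-k selection per
row (consequents) and column (antecedents) keeps every tie at the k-th
probability and drops zeros, so lists may exceed or fall short of k. The
report adds each condition's cluster label and cohort prevalence and
supports stratification by sex, ethnicity or IMD quintile.

## Synthetic cohort generator

The generator emulates the statistical structure of an urban, multi-ethnic
primary-care cohort and provides exact ground truth for recovery testing.

**Registration.** Follow-up durations are lognormal with median 4.2 years
and sigma 1.142 chosen from the quartile ratio 8.4/1.8 (a two-parameter
lognormal cannot match a median of 4.2 and both quartiles of that asymmetric
IQR simultaneously; the median is matched exactly). Durations are truncated
to the 15.1-year study window (April 2005 – May 2020) and entry dates drawn
uniformly over the feasible window, so administrative censoring never
shortens a drawn duration. Death truncates follow-up at the death time;
observed follow-up medians therefore run a few percent below the
registration target.

**Initial states and covariates.** Starting LTC counts follow a configured
4-vector, default (0.76, 0.15, 0.05, 0.04). Covariates (sex, age group,
ethnicity, IMD quintile, six risk factors with never/ever/resolved levels)
are sampled from configurable marginals defaulting to the profile of a
deprived, young, multi-ethnic borough. The latent count for a patient
starting in S3+ is exactly three, which keeps state and count identical
throughout and makes downward rendering always consistent.

**Latent paths.** Given the patient's covariates, the truth model's `Q(x)`
drives a Gillespie simulation (exponential sojourns, categorical jumps)
until death or the end of follow-up. The default truth model uses plausible
per-year baselines calibrated so the cohort descriptives resemble the
emulated population (roughly three quarters stable, a quarter progressed,
two percent remitted, five percent dead), with age and sex hazard ratios of
realistic magnitude. Every parameter is configurable, and recovery studies
supply their own truth.

**Event rendering.** Each upward move becomes an onset of a condition not
previously active; each downward move resolves an active condition flagged
resolvable (12 of the 32). Because the full path is known when rendering, a
look-ahead demand policy guarantees feasibility: before move `i`, the number
of active resolvable conditions `R` is kept at or above
`needed(i) = max(0, max prefix sum of future moves with down=+1, up=-1)`.
At each onset the draw is forced to a resolvable condition exactly when `R`
would otherwise fall below the future demand; since the path never goes
below zero conditions, `needed ≤ current count` always, so the policy never
runs out of candidates. An induction on moves shows `R ≥ needed` is
maintained, hence every downward move finds a resolvable active condition;
a violation raises an internal error. Prior onsets establishing a nonzero
starting state are dated uniformly in the ten years before entry and obey
the same policy.

Condition identities follow a cluster-weighted preference: with probability
0.7 (default) the next condition is drawn from the same A–F cluster as the
most recent onset, otherwise uniformly across the other clusters — giving
the chain module recoverable structure that mirrors within-cluster disease
sequencing. Times are kept in fractional years internally and rendered to
ISO dates at day resolution on output; day rounding can merge events less
than a day apart, which the history builder's epsilon sequencing absorbs.

**What the generator does not emulate:** coding-system artefacts
(Read/SNOMED), list-cleansing deregistration, under-recording and secular
recording trends, continuous age, or condition-specific intensities beyond
the cluster preference. Passing recovery tests therefore demonstrates the
estimators are correct under the model's assumptions, not that real EHR
data meet those assumptions.

## Study sizes used in automated checks

Chosen to make every transition well observed while keeping a full run on
one CPU within minutes:

* Parameter recovery: 50 replicates of 5,000 patients; truth plants a
  hazard ratio of 1.5 (binary covariate, S1→S2), initial state probabilities
  (0.55, 0.20, 0.15, 0.10) and death rates 0.03/year so all ten transitions
  accumulate events. Checks: ≥90% CI coverage, mean baseline-intensity
  relative bias <5% per transition.
* Sojourn calibration: 50,000 simulated sojourns vs `-1/q_rr`, three
  standard errors.
* Cluster-sequence recovery: 20,000 patients with enriched initial states
  (0.3/0.3/0.2/0.2) and acquisition rates 0.25/year; the top consequent
  (Death excluded) must share the antecedent's cluster for ≥80% of
  conditions.
* Matrix-exponential contract: 1,000 random valid intensity matrices.
* Pipeline determinism: the 2,000-patient demo run twice, byte-compared.

`scripts/acceptance.py` re-runs the same computations (30 recovery
replicates) and writes the resulting numbers as JSON.

## Numerical choices and degenerate inputs

* 365.25 days per year everywhere; dates are calendar dates at day
  resolution.
* Same-day epsilon 1/365.25 years; round-trip tests that compare latent
  paths against rebuilt histories use an epsilon of 1e-9 with exact
  (unrounded) times.
* BFGS gradient tolerance 1e-8; convergence additionally accepted when the
  score norm is below 1e-6 per observed event, guarding against spurious
  precision-loss flags after convergence.
* Probability matrices are clipped to [0,1] and renormalised only within
  the 1e-8 validation tolerance.
* A cohort with no observed jumps fits cleanly: every transition is NA, the
  one-year matrix is the identity, and "1 in N" renders as "—". A
  probability of 0.85 renders as "1" (N rounds to one).
* Ties in top-k selection are ordered by descending probability then
  alphabetically, making reports independent of input row order.
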