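# Methods

This note documents the models, estimation machinery, synthetic-data
generator and numerical choices behind `beliefmed`, and what the test
suite does and does not establish.

## Data model and preprocessing

A trial table is long-format: one row per participant × item with a
two-level cue (coded +1 for level 1, −1 for level 2; the level order is
an explicit configuration field, with a sorted-order fallback that
warns), a belief-based prediction in percent, an optional self-paced
study time in seconds, and a JOL in percent. Global beliefs are
constant within participant × cue level; this structure is validated
exactly (no tolerance) and violations route the analysis to the
item-varying-mediator path rather than silently averaging.

Exclusions run before everything else, in a fixed order: missing JOLs
and JOLs outside [0, 100]; study times below 200 ms; study times above
the participant's own mean + 3 SD; then the surviving study times are
natural-log transformed (raw values retained in `fluency_raw`). All
thresholds are configurable; these are the defaults. A participant left
without trials in one cue level is removed entirely, because every
model here estimates a within-participant cue contrast. Group-mean
centering then subtracts each participant's mean (over included trials)
from each trial; with balanced ±1 coding the centered cue equals the
raw cue exactly, and centering is idempotent.

## The mixed-model engine

All models are two-level Gaussian LMMs with participants as clusters,

y = Xβ + Z_j u_j + ε,  u_j ~ N(0, diag(τ²)),  ε ~ N(0, σ²I),

with a **diagonal** random-effects covariance only: correlated random
effects frequently fail to converge in this design, and the mediation
formulas only require the variances. Estimation profiles β and σ² out
of the REML (or ML) criterion and optimises the variance ratios
λ_k = τ_k²/σ² on the log scale:

* per-cluster Woodbury/capacitance algebra, batched across clusters;
* bounded L-BFGS-B on log λ ∈ [log 1e−10, log 1e10] with the analytic
  score (envelope theorem over the profiled β̂ and σ̂²);
* a safeguarded Newton polish on the analytic score, then — only if
  the interior score still exceeds 1e−9 — coordinate-wise bounded
  Brent sweeps. The polish matters: quasi-Newton termination alone
  leaves O(1e−6) error in λ̂, which is visible in the
  mediation/moderation equivalence check; near-flat ridges (a variance
  heading to zero) additionally defeat Newton steps, hence the Brent
  fallback. Starting values are λ = 1 (the OLS residual variance split
  evenly); there is no stochastic initialisation, so fits are
  deterministic and invariant to row/cluster order.

Convergence is judged by the final interior score (< 1e−6), not the
optimizer's own flag. A variance ratio ≤ 1e−8 counts as "at the
boundary"; ≥ 1e9 as "runaway" (the residual collapsing into a random
term, the signature of a random slope perfectly confounded with the
residual). A near-zero eigenvalue of the score curvature (computed
from finite differences of the analytic gradient) flags a flat ridge —
variances that are not separately identified, e.g. two random-slope
columns proportional within every cluster, or a random intercept with
a single cluster. With no random terms the model collapses to OLS with
residual dfs.

Wald t tests use **Satterthwaite** dfs: df = 2·C_ii²/Var(C_ii), with
the gradient of C_ii = Var(β̂_i) over the (non-boundary) variance
components by central differences and Var(θ̂) from the inverse observed
REML information (finite-difference Hessian of the unprofiled
likelihood). Against lmerTest on matched fits, estimates and SEs agree
to ~1e−6 and dfs to a few percent; the engines differ in
finite-difference details, so exact df parity is not claimed (nor with
SPSS, whose algorithm is unpublished). Satterthwaite was chosen over
Kenward–Roger to mirror the dfs reported by the common macro tooling
in this literature. If the information matrix is unusable, the df
falls back to the residual df with a diagnostics note.

**Pruning** re-fits iteratively, removing one random term per round:
first a structurally degenerate term (no within-cluster variation
anywhere), then a runaway term, then the largest term under residual
collapse, then a flat-ridge term, then the smallest boundary variance,
and finally — on plain non-convergence — the smallest variance.
Everything is logged with reasons. This is the "maximal then prune"
policy applied to every outcome model.

**BIC** is always computed from a fresh ML fit (−2ℓ_ML + k·ln n_obs,
k = fixed effects + variance components including the residual, n_obs
= total trials), never from REML, whose likelihoods are not comparable
across fixed structures. The n_obs convention matches common
mixed-model software; deviations from any particular package's BIC are
therefore explainable by this logged choice.

## Mediation

Path a for a *global* mediator is a fixed-slope regression of the
centered mediator on the centered cue: no random intercept (the
centered mediator's participant mean is identically zero) and no
random slope (within each participant the centered global belief is an
exact multiple of the centered cue, so a slope random effect is
confounded with the residual; requesting one raises an error). An
*item-varying* mediator (log study time) keeps the random cue slope,
pruned only on failure. The outcome model regresses JOL on the
centered cue and all centered mediators with the maximal random
structure (intercept + all slopes), pruned.

IND = a·b + cov(a_j, b_j) is reported with the covariance term always
present but structurally zero under this engine (fixed path-a slope,
diagonal covariance) — the full formula is retained for forward
compatibility. Inference: (i) Monte-Carlo intervals from independent
N(â, SE_a²) × N(b̂, SE_b²) draws, default 10,000, seeded through
`SeedSequence` substreams so every interval is reproducible and
mediators don't share streams; (ii) a first-order Sobel z
(ab/√(a²SE_b² + b²SE_a²)) without the second-order SE_a²SE_b² term —
macro tooling in this literature prints slightly different z values,
so z parity is not targeted. The proportion mediated
IND/(ΣIND + c') is reported unclamped with a suppression flag when the
total is ~0 or the indirect effect opposes the total's sign. With two
mediators, each gets its own path-a fit (separate models) and the
contrast of indirect effects gets its own Monte-Carlo interval.

## Moderation and equivalence

The moderation model regresses JOL on the centered cue, the raw
per-participant DiffBelief (not grand-mean-centered — only the
intercept and DiffBelief main effect, both of no substantive interest,
are affected) and their product, with random intercept + random cue
slope, pruned by the same criteria as the mediation outcome model. A
random-intercept-only variant exists behind a flag but is off the
default path: omitting the cue slope inflates the interaction's Type I
error. Constant DiffBelief (including all-zero) is a degenerate design
and raises.

Because Belief_c = (DiffBelief_j/2)·Cue_c for every trial (an exact
identity that survives unequal trial counts per level), mediation c'
equals the moderation cue main effect and mediation b equals twice the
interaction — *provided the two fits carry the same random structure
and the mediation outcome model has no random belief slope* (the
moderation model cannot express that term; with it retained,
`check_equivalence` raises). The package therefore fits the moderation
model with exactly the random terms the mediation outcome fit
retained whenever the two are being compared (`matched_random_terms`);
this mirrors how the published comparisons apply one set of
random-effects criteria to both models. Two fine points established
numerically during development:

* at matched structures, the fitted cue-slope variance *ratio*
  λ_cue = τ_cue²/σ² coincides between the two models to machine
  precision even under missing trials, and the equivalence holds to
  ~1e−8 relative;
* the intercept variance and σ² individually differ slightly between
  the models (the moderation fixed design contains the extra
  DiffBelief column), which is why only tightly-converged optima show
  the equivalence — a major motivation for the engine's polish steps.

Default tolerances: 1e−6 relative on synthetic data; 1e−2 absolute
when comparing against values printed to three decimals.

## The error-rate study

Each replicate draws, per participant, one belief per cue level from
N(50, 10²) (null) or N(60, 10²) vs N(50, 10²) (alternative), replicates
each belief over 20 items, and contrasts (i) the participant-level
paired t-test with (ii) the item-level path-a fit (fixed intercept +
slope, no random effects — OLS with residual df, matching the df of
n_items − 2 such analyses report). Beliefs are *not* truncated to
[0, 100] (the generating normals are used as-is; truncation is an
option). Defaults: 30 participants, 20 items/level, 1,000 replicates,
α = .05, one master seed spawning per-replicate substreams so any
replicate is reproducible independently of parallelism or consumption
order.

Analytic anchors used as test oracles: the item-level slope equals
half the mean within-participant belief difference exactly on balanced
replicates; its naive SE understates the true sampling SD by √T
(T = 40 items), so the null rejection rate is ≈ 2(1 − Φ(1.96/√40)) ≈
75.7%; the paired-t Type II rate under the alternative follows the
noncentral t with ncp = 10/(√200/√30) ≈ 3.87 and df 29 (≈ 3.4%).

## The synthetic mediation generator

`generate_mediation_dataset` instantiates the mediation process
generatively: per participant a belief base rate ~ N(50, 10²) (same
between-participant spread as the error study), level-specific beliefs
base ± a with N(0, 5²) level jitter (so DiffBelief varies realistically
across participants and the moderation design is identifiable), a JOL
intercept of 50 with N(0, 10²) participant spread, random b and c'
slopes with SDs 0.2 and 1.0 around the fixed values, and trial residual
SD 10 — all in percent, sized so that JOLs stay mostly inside [0, 100]
without clipping (clipping exists as an option and warns when it
censors > 5% of trials). Optional fluency: log study times with mean
0.1, per-±1-cue effect −0.1 (SD 0.05 across participants), trial SD 0.3
log-seconds, and a fluency→JOL slope of −5 per log-second (SD 1.0),
stored as raw seconds so the standard exclusion + log-transform
pipeline applies. JOLs are generated from the *balanced* centered
predictors; `missing_rate` then deletes trials completely at random
(always leaving ≥ 1 trial per level), emulating missing-JOL loss.

What the generator does **not** emulate: bounded/discrete JOL response
scales (multiples of 10), item-level heterogeneity (no crossed item
effects), belief updating over the course of study, skewed residuals,
or non-ignorable missingness. Passing recovery and equivalence tests
on this generator therefore demonstrates correctness of the estimators
under the stated Gaussian process, not robustness to those real-data
features.

Study sizes used by the test suite — 1,000 simulation replicates, 50
equivalence datasets at 30 × 40 trials with 5% deletion on alternate
seeds, and 200 recovery replicates at 50 × 40 with truth a = 5,
b = 0.4, c' = 2 — follow the designs and sample-size recommendations
of the literature this package serves (≥ 30 participants × ≥ 30
trials; 50 participants preferred for slope-variance questions).

## Degenerate inputs and tie-breaks

Constant cue columns and > 2 cue levels are rejected at read time;
non-numeric numeric fields report the offending row. Centering a
globally constant variable yields zeros with a warning. A zero-variance
belief difference makes the paired t undefined (an error distinct from
p = 0). Zero SEs in the Monte-Carlo interval give a degenerate point
interval; a zero Sobel denominator is an error. Rank-deficient fixed
designs name the collinear terms. All removal decisions in pruning are
deterministic (documented order; smallest variance breaks ties).

## Known limitations

* Crossed random effects (items), non-diagonal covariances,
  non-Gaussian outcomes and Kenward–Roger dfs are out of scope.
* df/z parity with SPSS-based macro output is approximate (±5% is the
  realistic expectation); estimates and SEs are the reliable points of
  contact.
* The between-participant mediation pathway is deliberately removed by
  centering; the package does not estimate simultaneous
  within/between decompositions from uncentered variables.
* At most two mediators, no serial or moderated mediation.
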