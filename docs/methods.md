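# Methods

This note documents the models, conventions and design choices behind
`milieu`, in the order the pipeline runs them.

## Data model and standardization

A dataset is participants × {baseline counts (28), cognition scores
(28 × 4), personality scales (5), follow-up counts (28)}.  Counts are
nonnegative integers ("how many times over the last two weeks"); cognition
scores live on 1–7 scales; no missing values are accepted (loading fails
rather than imputes).  Z-scoring uses the sample standard deviation (n − 1);
a zero-variance column is an error naming the column, never a silent drop.

The three risk behaviors are reversed (× −1) *after* z-scoring, for the
baseline and follow-up count columns only.  Cognition columns are not
reversed by default: the questionnaire wording targets the behavior as
phrased, so a strong intention "to smoke" is already oriented; a
`reverse_cognitions` flag records the alternative reading.  The health
behavior index is the row mean of the five reversed follow-up health
z-scores; it has mean 0 by construction and variance below 1 (the five
columns are not perfectly correlated).

The five predictor blocks are disjoint by construction and the five
follow-up health columns appear in none of them — they exist only inside
the target.

## Synthetic generator

The generator is the package's stand-in for undeposited questionnaire data
and defines the conditions under which the pipeline is validated.  Three
participant-level latent factors drive everything: motivation `c` (behind
the health cognitions), sociability `s` (behind the socially oriented
lifestyle activities and their cognitions), and habit `b` (shared by
baseline and follow-up behavior, giving past behavior its predictive power).
The follow-up health propensity is

```
h = w_c·c + conflict_g·s + w_b·b + λ·ψ + ε,     ε ~ N(0, σ_t²)
```

with `ψ` a standardized product of two designated lifestyle activities
(visiting friends × clubbing) — a planted nonlinearity a perceptron can use
but a main-effects linear model cannot — and `conflict_g ≤ 0` a group-level
weight implementing the counteractive-control idea that competing activities
depress health behavior only for weakly engaged people.

Counts come from a Poisson log-link by default,
`count ~ Poisson(exp(0.7 + 0.55·latent))`, whose base rate puts the median
around two events per two weeks (roughly half the sample engaging in a
behavior), or from a rounded-Gaussian link (`max(0, round(10 + 2.5·latent))`)
when variance control matters more than count realism.  Cognitions are
`clip(4 + 1.15·(latent + noise), 1, 7)`.  Group assignment uses
largest-remainder quotas so fixture sizes are deterministic (a multinomial
flag exists for realism).  Personality scales are continuous composites.

### Default study design

`default_study_config()` plants four groups of 92/50/64/5 at n = 211 with
strictly descending engagement.  Groups are separated along *several*
independent latent dimensions, not just engagement: the high group feels
normative support (+1.2 SD on subjective norms), the moderate group's
signature is weak norms (−2.8 SD), the low group is highly social (+2.5 SD
sociability, conflict −0.35, ACS-hesitation −2.2), and the very-low group is
a five-member committed-smoker cluster (pinned pro-smoking cognitions,
strongly elevated smoking counts, socially withdrawn, external locus of
control, preoccupied, low self-efficacy).  This matters quantitatively:
groups separated by ~1 SD on a single latent are unrecoverable by any
clustering method regardless of how many indicator columns echo that latent,
because indicators of one latent cannot beat the latent's own within-group
overlap.  The chosen shifts give between-group latent Mahalanobis distances
of roughly 3–4.5 — clearly separated, as a planted-partition recovery design
requires, without being trivially separable column by column.  Three
lifestyle activities (writing letters, renting videos, avoiding meat) carry
no sociability loading and no group shifts; they act as planted nulls for
the salience machinery.

### Planted-increment design

`planted_increment_config()` is a single-group variant whose target
decomposes orthogonally: variance fractions 0.18 through motivation
(measured by the health cognitions), 0.24 through a global lifestyle
conflict (measured by the lifestyle blocks), 0.29 through habit (measured
only by baseline counts), 0.29 noise; personality carries nothing.  The
rounded-Gaussian link and mild measurement noise keep attenuation small:
with 20 cognition indicators the recoverable step-1 increment is about
0.18 × 0.97 (indicator reliability) × 0.96 (index attenuation) ≈ 0.17, and
correspondingly ≈ 0.22 for the lifestyle step — the arithmetic behind the
recovery tolerances.

### What the generator does not emulate

Item-level measurement (constructs are stored directly), test–retest error,
floor effects in rarely performed behaviors, realistic covariance between
distinct lifestyle activities, and any calibration to a particular observed
sample's moments.  Passing recovery tests therefore shows the *pipeline*
extracts planted structure correctly; it does not show that real
questionnaire data contain such structure.

## Network waves

`MLPWaveRegressor` is a single-hidden-layer perceptron (default 5 tanh
units, linear output) trained with full-batch Adam (step 0.05) on
mean-squared error.  20% of rows are held out for early stopping, sampled
within target quartiles so the split is balanced on the outcome — at
n ≈ 200 an unstratified split makes validation error too noisy a stopping
signal.  Training stops after 50 epochs without validation improvement
(tolerance 1e−7); the best-validation weights over 5 independent seeded
restarts are kept, the standard defense against a nonconvex loss surface.
All sizes and budgets are configuration, not constants.

Determinism: given the data and `random_state` the fit is bit-reproducible.
When the design matrix carries column names the effective seed hashes the
*sorted* names and columns are reordered canonically, so estimates are
invariant to column order.  Index estimates are reported for all
participants from the early-stopped network — the downstream regression
needs one estimate per participant — with a cross-validated
`holdout_estimates` mode as a sensitivity analysis for in-sample optimism.

## Hierarchical regression

Entry order is fixed: health-cognitions estimate; + personality; + both
lifestyle estimates (one step, two predictors); + baseline-health estimate.
Fits are OLS with intercept on z-scored variables, so coefficients are
standardized betas.  Adjusted R² is `1 − (1 − R²)(n − 1)/(n − p − 1)`.  Two
ΔR² conventions circulate in published tables, so both are emitted: the
difference of adjusted R² between steps (printed in the rendered table) and
the raw R² difference, which is what the F-change test uses,
`F = (ΔR²/q) / ((1 − R²_full)/(n − p_full − 1))` with df (q, n − p_full − 1).
A saturated earlier step (1 − R² = 0) yields F = ∞ for a positive increment
and 0 otherwise.  Near-collinear designs (condition number > 1e10) warn and
fall through to the pseudo-inverse fit.  Significance stars are rendered at
.01/.001 with no multiplicity correction, matching reporting practice for
this table shape.

## Two-stage clustering

Stage 1 grows a Ward tree on Euclidean distances over the standardized
predictor columns plus the (re-standardized) saturated estimate
(alternatives: predictors only, or the network's hidden activations).
The number of clusters is the value in k_range = 2..8 with the largest
relative jump in merge heights, with two corrections that experience with
unequal-size planted structures forced:

* **Size normalization.**  The raw Ward height scales with
  `sqrt(2·n1·n2/(n1+n2))`, so a small distant cluster (the kind this
  analysis explicitly wants to retain — the interpretable five-member
  smoker group) can never produce a top-level jump against merges of
  50–90-member groups.  Heights are divided by the size factor, turning
  them into between-centroid separations.
* **Noise correction and eligibility.**  In d dimensions a pure-noise Ward
  merge has squared height ≈ 2σ²d *independent of sizes*; the median squared
  height estimates that constant and is subtracted (with a 5% ridge) before
  normalization, and merges that split off less than 2% of the sample carry
  no evidence about k.  Without these, 2–3-point noise clumps in
  ~150-dimensional data acquire inflated separations and k overshoots.

Stage 2 refines the chosen cut with k-means started from the Ward-cut
centroids (single deterministic run; k-means++ restarts were tried and
rejected — with high-dimensional noise, splitting a large group often beats
isolating a small true cluster on inertia).  Clusters are relabeled by
descending size; identical rows collapse to k = 1 with a warning;
`k_override` exists because cluster counts are ultimately a judgment call.

## Engagement ordering and salience

Groups are ranked by descending mean health index (ties broken by size,
logged) and labeled high/moderate/low/very-low (two groups: high/low; extra
groups numbered).  Cohen's d uses the classical pooled-SD estimator between
a group and all other groups combined; it is antisymmetric and
scale-invariant, returns 0 for equal means with zero spread and signed
infinity for unequal means with zero spread, and is undefined (missing, with
a warning) for groups smaller than two.  A variable is salient at
`|d| ≥ 0.50` (configurable); the rendered table blanks sub-threshold cells
while a companion file always carries the full matrix.  Note the sampling
SD of d for a five-member group against the rest is ≈ 0.45, so isolated
threshold crossings in very small groups are expected noise and are read as
such in the recovery tests.

## Problem sizes and numerical choices

Recovery experiments run at the design's own scale: n = 211 for cluster and
salience recovery (20 seeds), n = 2000 and 20 seeds for the
planted-increment recovery, n = 300–500 for the network oracles.  Oracle
comparisons are exact to 1e−10 (normal equations) and 1e−12 (effect sizes,
forward passes); moment checks use 1e−9.  Seeds derive from a master seed
via CRC32 of stage tokens, stay below 2³¹, and make every artifact —
including serialized models and reports — byte-reproducible.

## Known limitations

The perceptron is intentionally minimal; it will underfit strongly
interactive high-dimensional structure and slightly underestimate planted
increments through estimate unreliability (visible as ~0.01–0.03 attenuation
in the recovery experiments).  The k-selection corrections are tuned to
mean-separated group structure; elongated or nested clusters are out of
scope, as are model-based (BIC-type) two-step variants, bootstrap cluster
stability, and significance machinery for d beyond the threshold rule.
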