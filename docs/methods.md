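# Methods

This note documents the models, conventions and numerical choices behind
lambwatch, and what the synthetic-data experiments do and do not establish.

## The inference problem

A parturient ewe's collar track contains a brief, episodic signature: a
~2-day near-stationary bout beginning at birth, often preceded by a day of
elevated movement, embedded in a season of otherwise sporadic travel and
foraging. Single change-point methods on step length alone are unreliable
for such episodic patterns, so the pipeline classifies every fix into one of
three latent movement states using three complementary metrics, then applies
an explicit decision rule to the decoded non-movement state.

## Screening conventions

Rules: (1) all 2D fixes; (2) incoming speed > 5 km/h; (3) incoming and
outgoing speed > 2 km/h with turning-angle cosine < −0.97. Thresholds are
configurable constants; the 2 km/h spike threshold is not re-estimated from
the data at hand. Because removing a spike changes its neighbours' speeds,
rules 2–3 are re-applied to the surviving sequence until a pass removes
nothing. The first and last fix of the surviving series are never removed by
rules 2–3 (their kinematics are one-sided), and a fix bounded by a
zero-length step has an undefined turning cosine, so rule 3 cannot fire
there — both choices are conservative. Screening is idempotent.

## Movement metrics

**DIST** is assigned to the interval's *starting* fix (forward convention);
the final fix's missing value is imputed from its predecessor and flagged, so
the state model sees a complete series.

**RT100** accumulates forward and backward time until the animal leaves the
100 m circle for *strictly* longer than the 2-h gap tolerance (an excursion
of exactly 2 h does not stop accumulation). Crossing times are linearly
interpolated on the distance-to-centre series sampled at the fixes; a
sub-fix-interval dip of the true path in and out of the circle between two
outside fixes is therefore not seen, a deliberate convention shared by the
test oracles. At track boundaries, accumulation stops at the last known
crossing and the value is flagged truncated; flagged values are used as-is
downstream.

**HR** uses the fixes within ±12 h, drops the `floor(0.05·n)` fixes farthest
from the window's arithmetic centroid (ties: the later fix is dropped first),
and takes the convex hull area in hectares. Windows with fewer than three
distinct retained points get area 0 and a degeneracy flag. The 24-h window
deliberately smooths diurnal variation.

Units throughout: metres, hours, hectares; all coordinates in a projected
metric CRS (no lat/lon handling anywhere).

## The hidden Markov model

Three latent states evolve as a first-order Markov chain; given the state,
the three metrics are independent gamma variates (no cross-channel
covariance), each state × channel owning a mean and shape. Gamma support
excludes zero but DIST can be exactly 0, so each channel is floored at half
its smallest positive observed value; the floors are stored on the model and
re-applied when decoding new animals.

Fitting is Baum–Welch EM over all training sequences jointly: each
animal-season contributes its own scaled forward–backward pass, and
transition, emission and initial-state parameters are shared (sequences are
treated as independent; there is no cross-animal continuity). The gamma
M-step solves `log k − ψ(k) = log x̄_w − (log x)̄_w` by Newton iterations on
the weighted sufficient statistics. Initialization splits the RT100 channel
at its terciles and sets emissions by method of moments per tercile with
sticky (0.9 diagonal) transitions; additional restarts jitter the emission
parameters log-normally and draw sticky random transitions. Defaults: 10
restarts, relative log-likelihood tolerance 1e-6, 500 iterations maximum;
non-convergence returns the best iterate flagged. Per-iteration
log-likelihood is non-decreasing (checked to 1e-8 in the tests), and
forward likelihood and Viterbi decoding are verified against exhaustive
path enumeration on short sequences.

Labelling is deterministic from the emission means — non-movement has the
highest RT100 mean, high-movement the higher DIST mean of the remaining two —
and a tie (within 1e-9) raises rather than guessing, since tied means
indicate a degenerate fit. Viterbi ties break toward the lower state index.

## Decision rule and validation

A 48-h window slides one fix at a time; proportions are over fix counts
(fixes are near-uniform), only complete windows are scanned, and the window
with the greatest non-movement proportion wins, earliest on ties. Detection
requires the proportion to *strictly* exceed 0.5. All windows above
threshold are retained as diagnostics, but only the global maximum is the
call. The call carries a full timestamp; date-level reporting truncates in a
configurable timezone (default UTC).

LOOCV refits the model on n−1 animals and calls the held-out animal; a fold
succeeds when an event is called and its date falls inside that animal's
field-observation window. Fold errors are isolated and counted as failures.

## Habitat models

The LSD design labels the 15 days before the call 0 and the 15 days from
the call (inclusive) 1, windows closed-open; a window truncated to zero rows
on either side is flagged unbalanced. The RSF design pools all animals'
season fixes into one 95% MCP home range (the same habitat is available to
every ewe), and draws available points uniformly in the polygon by rejection
from its bounding box, 10 per used point, allocated to animals in proportion
to their used counts so the random intercept stays estimable.

Road and trail distances are transformed by `exp(−3d/range)` with
range = 500 m, putting the value at ~5% of its at-feature maximum at the
range — "saturated beyond 500 m" made concrete; the decay constant and range
are configurable. Continuous covariates are z-scored over the pooled design
table so coefficient magnitudes are comparable across covariates.

The mixed model is a logistic regression with one Gaussian random intercept
per animal, estimated by maximizing the exact marginal likelihood with
adaptive Gauss–Hermite quadrature: per group, a Newton search finds the
posterior mode of the random effect and the 15 quadrature nodes are
recentred and rescaled there. Optimization is L-BFGS-B over (β, log σ) with
log σ bounded below at −7 (σ is never exactly zero; at the bound the fit
coincides with plain logistic regression to well below coefficient
precision). Confidence intervals are Wald, from a central-difference
Hessian — chosen over profile likelihood for speed and determinism. The fit
is cross-checked in the tests against R lme4's `glmer` (nAGQ = 15), which
agrees to ~1e-3 on a shared fixture, and against plain logistic regression
in the zero-variance limit. (Quasi-)complete separation is detected at the
plain-logistic starting fit and raised with the offending covariate named.

The selection comparison reports, per covariate, both estimates, both 95%
CIs, their difference, and a CI-overlap indicator, sorted by covariate name.

## The synthetic-data generator

The generator defines the conditions under which the pipeline is validated.
One ewe-season is a correlated random walk at exact 2-h spacing over
May 15 – Jul 15: per-regime gamma step lengths and wrapped-Cauchy turning
angles, regimes switching under a sticky Markov chain. Defaults: step means
30 / 150 / 600 m per 2-h step (non/low/high — daily averages bracket the
~62 m postpartum daily minimum reported for ewes), shapes 1.5 / 3 / 3, and
turning concentrations 0.1 / 0.6 / 0.9. The rising concentration with
movement scale is what separates the regimes in RT100/HR space: near-uniform
turning keeps the non-movement regime inside a 100 m radius for tens of
hours, while directed travel prevents the faster regimes from loitering and
overlapping its emissions. Chain entries into non-movement are rare
(≤ 0.003 per step from other regimes) because that state is essentially
unique to parturient animals in the real system. The parturition bout is a
deterministic state override (48 h of non-movement at the event time, the
prior 24 h step means ×2) rather than a transition-probability effect, so
true event times are exact. GPS errors: 2D reclassification with probability
p_2d, and spikes that displace a single interior fix 4.2–8 km off the path —
incoming/outgoing speeds of 2.1–4 km/h on a 2-h interval with cosine ≈ −1,
exactly the rule-3 signature and below the rule-2 hard limit.

Landscapes are Gaussian-blurred white-noise fields standardized to mean 0,
sd 1 (elevation, ruggedness, snow depth, heat load, crown cover, slope) plus
Euclidean distance rasters to random polylines (road, trail) and random disc
unions (escape terrain, barren ground, herbaceous cover) — eleven layers on
a shared metric grid, serialized as ESRI ASCII text grids. Used points are
drawn from the cell-centre grid with probability ∝ exp(x·β) and jittered
within their cell.

**What passing tests show — and don't.** The generator produces regimes with
genuinely gamma-like marginals and near-uniform fix spacing, so recovery
results demonstrate the correctness of the estimation and decision machinery
under the model's own assumptions. Real collar data add missed fixes,
autocorrelated errors, diurnal rhythms, social movement (non-parturient ewes
following parturient ones to lambing areas), and habitat-driven rather than
regime-driven movement; the synthetic false-positive and success rates
therefore bound what the machinery can do, not what any field dataset will
yield. Likewise the simulated landscape has no spatial structure shared with
movement, so RSF recovery shows estimator correctness, not ecological
realism.

## Degenerate inputs and numerical details

- Trajectories need ≥ 3 fixes to screen and ≥ 1 complete 48-h window to call.
- Multi-state fits require ≥ 2 sequences or ≥ 500 total fixes.
- Emission probabilities are clipped away from hard zeros (log-space floors
  at 1e-300); a non-finite emission log-likelihood raises with the offending
  position and channel.
- Gamma shape solutions are clipped to [1e-3, 1e4]; a near-zero dispersion
  statistic maps to the upper cap (an effectively deterministic channel).
- The LSD/RSF pipeline stage records a statistically degenerate fit
  (separation) in the run manifest and continues instead of aborting the
  run; the fitting function itself raises, naming the covariate.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at deliberately moderate
sizes chosen to exercise every claim while keeping a full run inexpensive:
exact-inference oracles on 200 random models with sequences up to T = 8
(3^T enumeration); parameter recovery on one 2000-fix sequence with 10
restarts; event detection on 50 + 50 ewe-seasons under one pooled model;
LOOCV on 13 ewes; screening recall over five seeded seasons at a 2% spike
rate; and GLMM sign/coverage over 100 replicates of 8 animals × 120 rows.

## Known limitations

- MCP is the only home-range estimator (no kernel or autocorrelated
  estimators), matching the day-home-range definition.
- No covariates on HMM transition probabilities, no hierarchical HMMs, and
  no constraint preventing multiple non-movement episodes; the decision rule
  alone arbitrates among them.
- Wald (not profile) intervals; quadrature with a single scalar random
  effect only.
- The residence-time interpolation convention differs in sub-interval detail
  from kernel implementations in other ecology toolkits; it is pinned by its
  own oracle tests, and no numeric equivalence with other packages is
  claimed.
- The eleven-covariate roster is configuration-driven and generic; real
  analyses should substitute their own layers (and their own ruggedness /
  heat-load definitions).
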