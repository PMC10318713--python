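# lambwatch

Remote detection of parturition (lambing) events in GPS-collared ungulates,
with downstream habitat-use and habitat-selection analyses. Developed around
the movement ecology of bighorn sheep (*Ovis canadensis*) ewes, whose brief
(~2-day) near-stationary period after birth is detectable in collar data, but
applicable to any species with an episodic postpartum drop in movement.

The package is aimed at wildlife ecologists and managers who have collar fixes
at a regular interval (here 2 h) and want to (1) infer when and where each
female gave birth without intensive field observation, and (2) ask how habitat
use and selection differ around those events.

## Method

**Screening.** Erroneous fixes are removed by three rules: 2D fixes (fewer
than four satellites); fixes with incoming speed > 5 km/h; and spike fixes
with incoming *and* outgoing speed > 2 km/h whose turning-angle cosine is
below −0.97 (an out-and-back artefact). Rules 2–3 iterate to a fixed point.

**Movement metrics.** Per fix *i*:

- `DIST_i` — Euclidean step length to the next fix (m);
- `RT100_i` — residence time (h): forward + backward time before the animal
  leaves a 100 m circle around the fix for longer than 2 h;
- `HR_i` — day home range (ha): area of a 95% minimum convex polygon over
  fixes within a 24-h window centred on the fix.

**State model.** A 3-state hidden Markov model with independent gamma
emissions per metric (means on a log scale), fitted by Baum–Welch EM jointly
over all training animals and decoded with the Viterbi algorithm. States are
labelled *high-movement*, *low-movement* and *non-movement* from their
emission means (non-movement = highest RT100).

**Decision rule.** The lambing call is the start of the 48-h window with the
greatest proportion of decoded non-movement fixes, provided that proportion
exceeds 50%; otherwise no event is called. Validation uses leave-one-out
cross-validation against field-estimated birth windows, and out-of-sample
application to non-parturient animals (success there = no call).

**Habitat.** A latent selection difference (LSD) model contrasts the 15 days
before/after each call (prepartum = 0, postpartum = 1), and resource selection
functions (RSFs) contrast used fixes with available points sampled 10:1 inside
the pooled 95% MCP seasonal home range — both as logistic regressions with a
Gaussian random intercept per animal, fitted by adaptive Gauss–Hermite
quadrature. Distances to roads/trails enter as `exp(−3d/500 m)` so their
influence saturates beyond 500 m.

A fully synthetic data generator (trajectories with known regimes, bouts and
GPS errors; landscapes with known selection coefficients) makes every stage
testable end to end against exact ground truth.

## Worked example

`examples/02_detect_lambing.py` simulates six parturient and three
non-parturient ewes, fits the model, and calls events:

```
state labels: ('high-movement', 'low-movement', 'non-movement')
emission means (rows = states; cols = dist m, rt100 h, hr ha):
[[559.5   1.2 240.6]
 [151.7   3.5  55.9]
 [ 41.8  21.7  15.7]]
P01: called Jun 07 14:00 (window proportion 1.00, error 1.8 h)
P02: called Jun 15 22:00 (window proportion 1.00, error 0.8 h)
...
N01: no call (best window proportion 0.38)
```

The emission means show the expected structure — the non-movement state has
the shortest steps, the longest residence time and the smallest day home
range — and every simulated parturient ewe is called within hours of her true
event while non-parturient ewes yield no call. The other examples cover
screening and metrics (`01`), cross-validation (`03`), and RSF coefficient
recovery with a selection comparison between reproductive statuses (`04`).

A thin CLI mirrors the library: `lambwatch simulate|screen|metrics|fit-hmm|
decode|detect|run` (see `lambwatch --help`).

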