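# Methods

This note records the models behind `emtcomp`, the assumptions they make,
and the design decisions taken where the problem left room.

## Measurement model and error definition

A calibrated stud-grid phantom provides seats whose pairwise ground-truth
distances are known to ~0.02 mm (treated as exact). The full-volume
acquisition places a sensor at 10 calibrated seats, at 3 elevations
(9.6 mm steps, one brick height), and repeats the sweep with the phantom
rotated 180° about its azimuth axis — 60 measurements per scenario.
Because absolute positions in the tracker frame are unreferenced, error is
defined on relative displacements,

    e = ‖x₂ − x₁‖ − y,

over all unordered same-rotation measurement pairs (pairs across the two
rotations are not formed: seat correspondence between the rotated
acquisitions is not defined on the board). This yields 2·C(30,2) = 870
pairs per scenario. A scenario is summarized by the RMSE and maximum of
|e| over its pairs.

## Synthetic distortion generator

The generator stands in for undeposited hardware data; it is validated
against summary statistics only (per-scenario displacement RMSE between
0.37 and 1.39 mm), not against any field physics.

**Field.** A true position p is displaced by

    w(p) = s · g(‖p − c‖) · u(p),        g(d) = 1 / (1 + (d/L)²),

with distorter position c, decay length L = 60 mm, strength s (mm), and a
*unit* direction field u — a room-fixed axis smoothly perturbed by a seeded
linear vector field with a 40 mm spatial scale. Putting all short-scale
structure into the direction keeps ‖w(p)‖ exactly monotone in the distance
to the distorter while still giving the field enough curvature that raw
displacement errors accumulate visibly along a centimetre-scale path.
Scenarios of one suite share the direction field (one room, one C-arm) and
differ in distorter distance and strength. Measured positions add i.i.d.
Gaussian noise (σ = 0.05 mm per axis), the residual after median filtering
of raw samples; the generator emulates this post-median residual directly
rather than simulating 500 raw draws.

**Quality indicator.** Q = S·(ε − (b + m·r)) with raw settings S=1, b=0,
m=0 and r the sensor–transmitter range. The internal error indication is
modelled as ε = 0.5 + 2·‖w(p)‖ plus small noise (σ = 0.02) — affine in the
local distortion magnitude, since the indicator's purpose in the pipeline
is to carry distortion information the position alone cannot.

**Calibration.** Per-scenario strength is found by a Brent root search so
the generated 870-pair RMSE matches the scenario's reference magnitude
within 10% (the noise realisation is fixed by the seed, making the
objective deterministic and monotone over the bracket).

**Scenario geometry.** The virtual distorters sit on one axis at 70–170 mm
from the board centre. Two choices matter and were made for realism of the
*learning problem*, not to imitate the labels literally: (i) the
rotated-gantry scenarios are effective near-field distorters at 140/170 mm
— an inverse-square source at 300–500 mm could only reach their error
magnitudes with near-uniform multi-millimetre fields whose quality values
fall outside every training range; (ii) the laboratory scenario is weak
ambient distortion at 150 mm, so the quality ranges of all nine scenarios
overlap and the quality→amplitude mapping is interpolated, never
extrapolated. Both mirror the physical situation of one shared room.

## Compensation models

**Siamese network.** f(x, q; ω) is parameterised as a residual map
f(x, q) = x + d(x, q): the displacement loss determines f only up to a
rigid motion, and the residual head pins that gauge to the identity, which
is what makes single-branch absolute compensation meaningful. Inputs are
min–max normalised to [0, 1] on the training set (out-of-range inputs map
linearly outside the interval, with a warning); the head's output is in mm.
Default architecture: 3 hidden layers × 32 units, leaky ReLU α = 0.01,
batch 512, Adam lr 0.01, Glorot-uniform init with an explicit seed. The
planar variant uses 2 × 64 units on (x, y, Q) with two outputs. The loss is
the *squared* per-sample displacement residual (the raw signed residual is
unbounded below). Implementation is plain numpy — forward, backprop and
Adam are a few hundred lines and per-batch work is tiny.

**Training schedule.** Up to 800 epochs. For quality-aware models,
selection restores the weights with the best validation displacement RMSE
(patience 200); the clean validation scenario is a meaningful
generalization signal for them because the quality input lets one model
fit clean and distorted scenarios simultaneously. A quality-free model
cannot represent scenario-dependent amplitude, so clean-scenario
validation loss only ever punishes it; the online driver therefore trains
such models for the fixed epoch budget and keeps the final weights
(validation is still logged). This asymmetry is a deliberate design
decision, not an optimisation artefact.

**Polynomial baseline.** Per-axis mixed-term polynomials in the normalised
coordinates (default total degree 2; the quality value is not an input),
fitted on the same displacement residual by nonlinear least squares from
the identity map. A degree-1 fit exactly inverts an affine distortion,
which serves as a closed-form correctness oracle.

## Experimental protocols

**Online.** Train on the four strongest distorted scenarios (870 pairs
each), validate on the laboratory scenario, evaluate on the four held-out
scenarios; report per-scenario RMSE reduction and its mean.

**Offline.** Within one scenario, a spatially blocked 45/5/50
train/validation/test split: blocking units are the 30 3D seats
(grid index, elevation), both rotations of a seat stay together, and pairs
straddling blocks are dropped, so train and test are spatially
independent.

**Planar uncertainty experiment.** A 20 × 20-stud board (8 mm pitch).
Training data come from five 3 × 3 clusters — four over the lower half,
one upper-left — under three calibrated alignments; a held-out alignment
covers every stud for evaluation. The virtual C-arm sits beyond the *top*
edge: the far end of the insertion path is both strongly distorted and
sparsely covered, which is the heterogeneity the adaptive policy exploits.
The 2 × 64 dropout (10%) network trained on these pairs is sampled with
3000 MC passes per point; σ = √(σₓ² + σᵧ²). The deterministic
(dropout-off) pass gives the reported compensated position; MC samples are
used only for σ. Dropout acts on hidden layers only. Since the sampled
distributions are not Gaussian, σ is used ordinally (maps, thresholds,
accumulation) and never converted to confidence intervals. Absolute error
is estimated per stud as the mean absolute deviation of compensated
distances to all lattice neighbours within Chebyshev radius 3 (boundary
points use the neighbours that exist).

On this geometry the MC-dropout σ and the neighbourhood error correlate
strongly (Pearson r ≈ 0.6–0.9 across seeds), and σ grows with distance to
the nearest training point. The *error*-versus-distance relation restricted
to sparsely covered points is confounded here by distorter geometry (the
farthest points are not the hardest) and is not asserted.

**Hybrid navigation simulation.** Aorta-like paths of 219 mm (average
abdominal aorta 20–25 cm) are random biased lattice walks between measured
board seats, entering at a random bottom-row column and confined to the
central tracking region (3-stud margin — the board rim is outside the
tracker's specified volume and its extrapolation errors would dominate any
policy comparison). Per segment the error is |compensated distance −
ground truth|; per waypoint σ comes from MC dropout. Accumulated error is
the root-sum-square of segment errors — the accumulation rule for error is
not prescribed by the underlying procedure description, so the rule
symmetric with the uncertainty accumulation was chosen. Recalibration is
instantaneous and perfect (the X-ray restores ground truth), is evaluated
at waypoints, never fires at the final waypoint (no further travel to
protect), and interval 0 means "recalibrate at every waypoint". Policy
sweeps use τ ∈ [0.1, 1.2] mm and intervals ∈ [0, 219] mm averaged over 12
trajectory realisations; the τ grid spans the accumulated-σ range this
model actually produces (per-waypoint σ ≈ 0.04–0.5 mm, a few times smaller
than larger-volume setups where a 2 mm threshold is the interesting
region).

## Problem sizes and numerics

Default sizes: 870 pairs per scenario (10 seats × 3 elevations × 2
rotations), 400-stud planar evaluation grid, 3000 MC samples, 12
trajectory seeds, 5 online seeds. These reproduce the qualitative results
stably; the full acceptance recomputation takes about a minute on one CPU.
Numerical details worth knowing: the gradient of ‖c₂ − c₁‖ guards the
zero-distance case with a 1e-12 floor; nearest-training distances are
computed from exact squared-distance minima; model serialization is JSON
(floats survive round-trip bit-exactly via shortest-repr); every stochastic
component takes an explicit seed and derived seeds stay below 2³¹.

## Known limitations

- The generator matches published summary statistics, not field physics:
  no eddy-current modelling, no sensor orientation (5/6-DOF) effects, one
  distorter per scenario. Passing tests show the *pipeline* recovers
  distortions of this smooth, quality-correlated family; they do not show
  hardware-grade accuracy.
- The quality indicator is informative by construction (affine in local
  distortion). Real indicators are noisier and less specific; online
  generalization hinges on this signal.
- Radiation is counted in recalibrations, not dose units; trajectories
  ignore vessel-wall constraints.
- MC-dropout σ is a relative, model-inherent quantity; its absolute scale
  depends on architecture and dropout rate and should not be compared
  across models.
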