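# Methods

## The assay and its quantities

A population of 10–20 starved flies chooses between the sucrose-coated and
water-coated halves of a circular 76 mm arena for one minute.  The per-frame
preference index PI = (N_sugar − N_water)/(N_sugar + N_water) is pooled over
30–60 s (the first ~30 s are a startle transient of elevated activity);
frames in which no fly is countable are dropped, not imputed, and pooling is
an unweighted mean over frames.  Locomotion is summarised per consecutive
frame pair as linear velocity |Δx|·fps and absolute angular velocity
|Δθ|·fps of the fitted body-axis ellipse.

## Tracking pipeline

**Segmentation.** Frames are binarized at a user-set intensity threshold
(dark flies on a light background), the binarized empty-arena background is
subtracted, and one erosion + dilation with a disc (radius 1 px by default;
the structuring element is configurable since nothing pins it down) removes
single-pixel noise.  8-connected clusters form particles, each summarised
by area, centroid, bounding-box diagonal and second-moment eccentricity.

**Single-fly likelihood.** No parametric form is prescribed for the
"likelihood that a particle is one fly", so the package fits a robust
independent Gaussian (median and 1.4826·MAD per feature) to
(bbox diagonal, eccentricity) over all particles of the session and scores
each particle by the product density.  Particles outside the contour
holding 99% of the fitted mass (a χ²₂ radius; quantile configurable) are
"low": mis-thresholded or merged flies.  A degenerate reference (zero
spread) classifies everything high, with a warning.  A falsely-low single
fly is harmless: its estimated count is 1 and it is returned unchanged by
the resolution step.

**Merged-blob resolution.** The fly count of a low-likelihood particle is
estimated as round(area / mean single-fly area), minimum 1.  The particle's
own pixels are re-binarized at progressively darker thresholds — stepping
down by 1/40 of the gap between the working threshold and the particle's
darkest pixel — until the component count (components ≥ 3 px) equals the
estimate; the count cap of 40 iterations is part of the procedure's
definition.  Failure excludes the particle from that frame: exclusion is
preferred over fabricating detections, and it only costs one frame of
coverage.  Resolution works because fly bodies are darkest at the core;
two overlapped uniform-intensity blobs are genuinely inseparable and are
excluded.

**Ellipse fit and conventions.** Orientation, axis lengths and eccentricity
come from the particle's central moments, computed in arena coordinates
(x right, y up, origin at the arena centre — the image row axis points
down, so the xy covariance flips sign).  Orientation is a body *axis*,
reported in [0, 180); all angle arithmetic is the minimal signed mod-180
difference, reduced to (−90, 90] (so 178° → 2° is a +4° rotation).  This
convention is forced by the 90° association gate.  Particles under 3 px
cannot support a second-moment fit and are skipped with a warning.

**Association.** Greedy global closest-neighbour matching: repeatedly take
the smallest centroid distance among all remaining cross-frame pairs,
remove both members, and gate at 7 mm displacement and 90° axis rotation;
a selected pair violating a gate is rejected with both members unmatched.
Distance ties break to the lower detection index, making the pairing
deterministic and symmetric in frame order.  Only consecutive-frame pairs
are formed — the velocity read-outs need no longer tracks, so no long-range
stitching across occlusions is attempted.

## Synthetic arena generator

The generator emulates the recordings so the tracker and model can be
tested against exact ground truth.  Agents follow the same four-state
structure as the preference model: free-to-walk agents perform a correlated
random walk (heading + Gaussian(0, turn_sd) per step, default 30°/step at
10 fps) at the side-appropriate mean speed, with reflective walls that
preserve step length; feeding agents are stationary, so only walking flies
cross the boundary.  Feeding entry/exit is sampled per step with
probability 1 − exp(−k·Δt), Δt = 1/fps — exact for at most one transition
per step at the rates used.  The camera rate is not fixed by the assay;
10 fps is the default.

Defaults represent a hungry control group: speed_water = 8 mm/s,
speed_sugar = 3 mm/s (strong suppression, B ≈ 0.4), k_Sin = 0.1 s⁻¹,
k_Sout = 0.05 s⁻¹ (A = 2), k_Win/k_Wout = 0.001 (flies do not feed on
water).  An optional startle multiplier (default off) reproduces the
elevated 0–30 s activity when needed.

Because the stationary density of a walker with position-dependent speed
v(x) is ∝ 1/v(x), the emergent side-crossing rate ratio equals the speed
ratio, and the agent population converges to the well-mixed model's
equilibrium — verified in the suite at 200 agents × 10⁴ steps against the
closed form, within 3 Monte-Carlo standard errors (per-agent time averages
as independent replicates, first quarter discarded as burn-in).

Rendering draws each fly as a filled ellipse (2.2 × 0.9 mm, ≈ a starved
fly seen from above) at 0.12 mm/px, intensity graded from 30 at the core to
70 at the rim on a 200-intensity arena floor, plus additive Gaussian sensor
noise (σ = 4 by default) and a clean background frame.  The gradient is
what makes merged blobs resolvable by re-thresholding, as in real video;
flies closer than a body width merge purely by overlap.  What the generator
does *not* emulate: wings/legs and postural detail, shadows and uneven
illumination, wall-climbing, grooming clusters, and camera artefacts — so
tracking accuracy on synthetic frames bounds the idealised-geometry error,
not the full error on real video.

## Four-state preference model

States FS, FW (free to walk on sugar/water) and S, W (feeding) with
first-order transitions give a linear ODE system (written out in
`flypref.model`).  It is integrated with the exact matrix-exponential
propagator — the system is linear, so this conserves total occupancy to
machine precision (the 1e−9 conservation check is loose for it).
Stationarity gives S = A·FS, W = D·FW and FS·k_SW = FW·k_WS, hence

PI_eq = ((1 + A) − B(1 + D)) / ((1 + A) + B(1 + D)),

with A = k_Sin/k_Sout (sugar affinity), B = k_SW/k_WS (speed ratio,
equal to the sugar/water linear-velocity ratio since crossing rates are
proportional to walking speeds with a constant that cancels), and
D = k_Win/k_Wout = 0.001.  The closed form is verified against the ODE
steady state (100 random rate sets, 1e−6) and against the agent-based
simulation.  Limits are explicit: A = ∞ (zero feeding exit) gives PI = 1;
B = 0 with finite A gives PI = 1; A = D with B = 1 gives PI = 0 exactly.

**PER → affinity.** The PER dose–response is fitted with the logistic
p(x) = 1/(1 + exp(−slope·(x − thrd_PER))) (floor 0, ceiling 1).  Affinity
is the calibrated log-odds transform

A(x) = [p̃/(1 − p̃)]^c with p̃ the fitted curve at x − thrd_shift,
      i.e. A(x) = exp(c·slope·(x − thrd_PER − thrd_shift)),

which maps [0, 1] onto [0, ∞) with A = 0 at PER = 0 and A = ∞ at PER = 1.
thrd_shift is a concentration-axis correction (the dried filter paper of
the preference assay is a weaker stimulus than the solutions presented to
the tarsi) and c a scale correction on log-affinity.  A multiplicative
correction A = c·odds was rejected because for a logistic curve it
collapses with the shift into a single constant, leaving the pair
unidentifiable — whereas both factors are meant to be fitted from control
data.  Defaults c = 0.83, thrd_shift = 3.1.  A flat PER curve degenerates
to the constant pointwise transform of the observed fraction.

**Speed ratio.** Sugar-side velocity is assumed sigmoidal in
concentration, anchored exactly at the measured velocities with no sucrose
and at 2 M; only those two anchors are measured, so the interior shape
(slope 3 M⁻¹, half-suppression at 0.5 M by default) is a package choice
exposed as parameters.  B(x) = v_sugar(x)/v_water, so B(0) = 1.

**Calibration.** (c, thrd_shift) minimise the squared discrepancy between
predicted and observed control PIs across ≥3 concentrations (bounded least
squares, three fixed starts).  A flat PI curve is rejected as
unidentifiable.  Parameter recovery on synthetic control data is exact to
well under the 5% documentation tolerance.

**Mutants.** Theoretical perturbations of a calibrated model: affinity
mutant A = D = 0.001 (taste lost), suppression mutant B = 1 (slowdown
lost), and the double mutant.  Only the double mutant has PI ≡ 0; each
single mutant keeps PI > 0 wherever sucrose is present — preference is
abolished only when both responses are lost.  The affinity-ratio axis of
grid outputs can be read as A/D or as A with D fixed; with D = 0.001 they
differ by a constant factor 1000.

## Problem sizes and numerical choices

The accuracy evaluations use two 15-fly, 120-frame recordings (≈3,500
consecutive-frame pairs and detections) — enough for stable means while
keeping the whole suite around ten seconds; the agent-based equilibrium
check uses 200 agents × 10⁴ steps.  Sigmoid fits use analytic-free
`scipy.optimize.curve_fit` with data-driven starts and wide threshold
bounds; degenerate flat data are flagged rather than fitted.  All
randomness is seeded; simulation and rendering are bit-reproducible for a
fixed seed.

## Known limitations

- Tracking accuracy is measured against the generator's idealised
  geometry; real video adds postural variation, reflections and lighting
  drift that the synthetic frames do not contain.
- Identity is only maintained across consecutive frames, by design.
- The merged-blob splitter assumes darker-core blobs; flat-intensity
  overlaps are excluded rather than split.
- The PER→affinity transform and the interior shape of the velocity
  sigmoid are modelling choices constrained only by their boundary
  behaviour and anchors; alternative monotone forms would calibrate
  differently while preserving the qualitative structure.
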