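# flypref

Tools for quantifying and modelling two-choice sugar preference in
*Drosophila melanogaster*.

In the underlying assay, a group of starved flies is released into a
circular arena (76 mm diameter) whose floor is split into a sucrose-coated
and a water-coated half, and filmed from above for one minute.  The
preference index

```
PI = (N_sugar − N_water) / (N_sugar + N_water)
```

is computed from automatic fly counts per video frame and pooled over the
30–60 s window.  Preference arises from two separable behavioural
responses: an appetitive taste response (flies start feeding when their
tarsi contact sugar) and sugar-induced locomotion suppression (flies walk
more slowly on the sugar side).

`flypref` provides the full computational pipeline:

- **`flypref.synthetic`** — a ground-truthed arena simulator: flies as
  correlated random walkers with side-dependent speeds and stochastic
  feeding transitions, rendered as noisy grayscale frames.
- **`flypref.tracker`** — multi-fly detection and association:
  background-subtracted thresholding, morphological cleaning, particle
  measurement, likelihood-based detection of merged blobs and their
  resolution by local iterative re-thresholding (≤40 iterations),
  second-moment ellipse fitting, greedy closest-neighbour identity
  assignment across consecutive frames (gates ≈7 mm and 90°), and
  per-pair kinematics.
- **`flypref.metrics`** — PI time series, pooled PI, velocity summaries,
  PER (proboscis extension reflex) response fractions, and sigmoid
  dose–response fits.
- **`flypref.model`** — a four-state transition model of preference.
  Flies are free-to-walk or feeding, on the sugar or water side
  (FS, FW, S, W), with first-order transitions.  At equilibrium the PI has
  the closed form

  ```
  PI = ((1 + A) − B(1 + D)) / ((1 + A) + B(1 + D))
  ```

  where A = k_Sin/k_Sout is the sugar affinity, B = k_SW/k_WS the speed
  ratio (equal to the sugar/water walking-velocity ratio), and
  D = k_Win/k_Wout the water affinity (fixed at 0.001).  Affinity as a
  function of sucrose concentration is derived from PER dose–response data
  via a calibrated log-odds transform; the model then predicts PI
  dose–response curves and theoretical mutants.

## Worked example

```python
import flypref as fp

arena = fp.ArenaConfig(duration=60.0, frames_per_second=10)
dynamics = fp.AgentDynamics(
    k_sin=0.1, k_sout=0.05,        # sugar affinity A = 2
    speed_sugar=3.0, speed_water=8.0,  # locomotion suppression on sugar
    seed=11,
)
truth = fp.simulate_agents(dynamics, arena, 15)
frames, background = fp.render_frames(truth, arena, noise_sd=4.0, seed=12)

detections, steps, exclusions = fp.track_frames(frames, background, arena)
annotated = fp.annotate_detections(detections, truth)
rate, n_pairs = fp.identity_error_rate(steps, annotated)
matched = annotated[annotated.gt_id >= 0]
print(f"identity error {100 * rate:.3f}% over {n_pairs} pairs")
print(f"orientation error {matched.orientation_error_deg.mean():.2f} deg, "
      f"centroid error {matched.centroid_error_mm.mean():.3f} mm")

counts = fp.counts_from_detections(detections, arena)
from flypref.metrics import pi_series, pooled_pi
print(f"pooled PI (30-60 s): {pooled_pi(pi_series(counts)):.3f}")
```

prints

```
identity error 0.334% over 8969 pairs
orientation error 0.79 deg, centroid error 0.020 mm
pooled PI (30-60 s): 0.200
```

i.e. on a one-minute, 15-fly synthetic recording the tracker mis-assigns
identity in about 3 of 1,000 consecutive-frame pairs, recovers body-axis
orientation to better than a degree and position to about a sixth of a
pixel, and the counted preference equals the simulated ground-truth
occupancy of the same window (0.200): flies are drifting toward the
slower, stickier sugar side (the closed-form equilibrium for these rates,
A = 2 and B = 3/8, is PI ≈ 0.78, and one minute with these transition
rates is still mid-transient — as in the real one-minute assay).

The same pipeline is available from the shell:

```sh
flypref simulate --config config.json --out video/
flypref track --frames-dir video/ --config config.json --out tracked/
flypref metrics --detections tracked/detections.csv --out metrics.json
flypref model fit --per per.csv --velocity velocity.csv --pi pi.csv --out cal.json
```

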