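# casakit

Computer-assisted sperm analysis (CASA) as a scriptable Python library and
command-line tool: track motile cells in microscopy video, compute the full
kinematic parameter set, test populations for directional bias
(chemotaxis, thermotaxis, rheotaxis) with a bootstrap odds-ratio procedure,
measure head morphometry, count live/dead cells in dual-stained
fluorescence images — and simulate chemoattracted populations with a
persistent random walk model so the entire pipeline can be exercised and
validated without any real data.

It is aimed at reproductive-biology labs that want CASA measurements they
can script, version and re-run, rather than drive through a GUI.

## The statistics at the core

**Kinematics.** For a trajectory {p_t}, t = 1..N (pixels, one point per
frame at rate `fps`, scale µ µm/px) and its average path {q_t} (moving
average of width w):

- VSL = D(p₁, p_N) · fps/(N−1) · µ — straight-line velocity (µm/s)
- VCL = Σ D(p_t, p_{t+1}) · fps/(N−1) · µ — curvilinear velocity
- VAP = Σ D(q_t, q_{t+1}) · fps/(N−w) · µ — average-path velocity
- LIN = VSL/VCL·100, WOB = VAP/VCL·100, STR = VSL/VAP·100
- ALH — twice the lateral excursion of the raw path about the average
  path, read at strict local maxima of the excursion series (mean & max, µm)
- BCF — proper crossings between raw and average path · fps/(N−w) (Hz)
- MAD — mean absolute turning angle of the Δ-lagged direction series (°)
- FD — Katz fractal dimension log n / (log n + log d/L), 1 for a straight
  line, → 2 for a plane-filling walk
- DNC = VCL · ALH_mean (µm²/s)

A track is *motile* when VCL > min_vcl and it ends away from its start;
*progressive* when additionally STR > 80 % and VAP > 25 µm/s (defaults).

**Directional bias.** Each displacement gets an angle ψ relative to the
gradient direction θ.  With a half-cone γ (default 30°), N⁺ counts
ψ ∈ [−γ, +γ] and N⁻ counts the rest (option 1) or only the opposite cone
(option 2).  The ch-index is 100·N⁺/(N⁺+N⁻) — 16.67 % for a uniform
population at γ = 30°, option 1.  The test statistic is the odds ratio

    O.R. = (N⁺/N⁻)_test / (N⁺/N⁻)_control

whose null distribution is bootstrapped from control recordings by
repeatedly splitting the pooled trajectories into two disjoint random
subsets; bias is called when the observed O.R. exceeds the null's 95th
percentile (≈5 % type-I error).

**Simulator.** Cells swim at constant speed v0 with heading ψ diffusing at
rate D_rot and, for the "responsive" (capacitated) fraction, relaxing
toward the +x axis at rate β/τ:

    ψ' = ψ − (β/τ)·sin ψ + √(2 D_rot)·z,   z ~ N(0,1)   (per frame)

Populations can be rendered to synthetic 8-bit frame stacks (ellipse
cells) so that detection and linking are tested against known ground truth.

## Worked example

```
$ casakit simulate --config examples/config.yaml --seed 7 --out sim.csv --video sim.tif
simulated 100 trajectories x 500 frames -> sim.csv
rendered frame stack -> sim.tif
$ casakit track --video sim.tif --config examples/config.yaml --out tracked.csv
296 tracks -> tracked.csv
$ casakit chemotaxis --test tracked.csv --control sim.csv \
      --config examples/config.yaml --seed 1 --out chemo.json
chemotaxis report -> chemo.json
```

`tracked.csv` holds more tracks than the 100 simulated cells because
crossings and frame exits split tracks.  For this neutral (β = 0)
population `chemo.json` reports a test ch-index of 17.79 % (near the
16.67 % uniform baseline, lifted slightly by linking noise), an odds ratio
of 1.05 against the P95 threshold 1.12, and `"chemotactic": false`.
Simulating with `beta: 1` and `responsiveness: 0.5` instead lifts the
ch-index well above the baseline and flips the verdict.

A YAML config supplies any non-default thresholds, e.g.

```yaml
analysis:
  gamma: 30.0        # half-cone width, degrees
  max_displacement: 10.0   # linking search radius, µm
simulation:
  n_cells: 100
  n_frames: 500
  D_rot: 0.1
  v0: 3.0
```

`casakit motility` writes the per-track kinematics table plus a population
summary row; `casakit morphometry` and `casakit viability` process stained
stills (area, perimeter, Feret length/width, shape indices; green/red
live-dead counts).

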