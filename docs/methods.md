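# Methods

This note documents the models and procedures implemented in casakit, the
choices made where several reasonable definitions exist, and what the
synthetic-data validation does and does not demonstrate.

## Persistent random walk model

Each simulated cell carries a position (x, y) in pixels and a swimming
angle ψ in radians.  Per frame (the integration step is fixed at dt = 1
frame, so every rate parameter is per frame and every length in pixels):

    ψ ← wrap(ψ − (β/τ)·sin ψ + √(2 D_rot)·z),  z ~ N(0, 1)
    x ← x + v0·cos ψ
    y ← y + v0·sin ψ

- `D_rot` (rad²/frame, default 0.1) — rotational diffusion; the heading
  decorrelates over ~1/(2 D_rot) = 5 frames at the default.
- `v0` (px/frame, default 3) — constant swimming speed; every step has
  length exactly v0 because the displacement uses the updated angle.
- `β` (per frame, default 0) — alignment strength toward the +x axis
  (the gradient direction); negative values align toward −x.
- `τ` (frames, default 1) — alignment time constant.  Only the ratio β/τ
  enters the dynamics, so τ is kept at 1 and β carries the whole rate.
- `responsiveness` (0–1, default 0) — the fraction of cells that feel the
  alignment term, mimicking the capacitated subpopulation; the first
  ⌊responsiveness·n⌋ cells are flagged responsive.
- `psi0` — initial heading.  The default is "uniform" (headings drawn
  uniformly on the circle), which makes every displacement angle exactly
  uniform marginally — the right null for statistical checks.  The
  reference video configuration used for the rendered-pipeline validation
  instead starts every cell at ψ0 = 0; the early frames of such a
  recording are biased toward the gradient until diffusion mixes the
  headings, and that bias is part of what the full-pipeline check
  reproduces.

Euler order (angle first, displacement along the new angle) is one of
several equally defensible schemes; it is fixed for reproducibility.
Cells start uniformly inside the arena and are free to leave it; positions
are clipped only at render time, so a cell that wanders out simply
disappears from the video and its recovered track ends.  There are no
wall or hydrodynamic interactions and the attracting field is uniform.

Rendering paints each cell as a filled 255-valued ellipse (default
semi-axes 5 × 4 px, i.e. a 10 × 8 px cell) on a black background, major
axis along the current heading.

## Detection and linking

Frames are thresholded with Otsu's method (inverted first for dark-field
polarity), labelled with 8-connectivity, and components outside the
[min_cell_size, max_cell_size] µm² window are dropped.  Centroids are
intensity-weighted and sub-pixel.

Linking is greedy nearest-neighbour: all (track, detection) pairs between
consecutive frames whose distance is within the search radius
(`max_displacement`/µ pixels) are matched in ascending distance order,
ties broken toward the lower track then detection index; unmatched
detections open new tracks and unmatched tracks close.  There is no gap
closing and no motion model — a missed detection ends the track, exactly
as a crossing merges two cells into one blob and ends both.  This is
deliberate: the statistics downstream must be robust to that kind of
fragmentation, and the validation quantifies its effect rather than
hiding it.

Defaults for the simulated reference material (µ = 1 µm/px):
`max_displacement` 10 µm (≈3× the per-frame step of the default swimmer),
`min_track_length` 10 frames, cell-size window [10, 1000] µm².

## Kinematics

Definitions as in the README.  Numerical choices:

- **ALH.**  For each average-path segment midpoint, the lateral excursion
  is the distance to the nearest raw segment drawn from the w-point window
  that produced that part of the average path.  The excursion series is
  scanned for strict local maxima; each peak contributes twice its value
  (peak-to-trough).  A perfectly straight track has no peaks and reports
  0 (not missing), so DNC stays defined.
- **BCF.**  Only proper, transversal raw/average segment crossings count;
  collinear overlaps and shared-endpoint touches do not.  The orientation
  test uses exact sign comparisons, so the straight-line case is exactly 0.
- **MAD.**  Two readings of "mean angular displacement" circulate: the
  mean absolute turning angle between consecutive Δ-lagged direction
  vectors, and the plain mean of the direction angles themselves.  The
  default is the turning-angle reading (the standard Mortimer meaning);
  `mode="literal"` provides the other for cross-tool comparison.
- **Division by zero.**  Undefined ratios (stationary track, VAP = 0, …)
  propagate as NaN in the per-track report and are excluded from the
  population mean of that parameter only.
- Motility (VCL > min_vcl, endpoint ≠ start) and progressiveness
  (STR > 80 %, VAP > 25 µm/s by default) use strict inequalities.

## Directional-bias statistics

Angles are pooled across all trajectories of a sample before counting:
N⁺ and N⁻ are population totals, matching the definition of the odds
value as a per-recording quantity.  ψ exactly on the cone boundary counts
toward N⁺ (closed interval).  Zero-length displacements carry no
direction and are skipped.

**Bootstrap null.**  Each iteration draws two *disjoint* random subsets of
the pooled control trajectories, computes each subset's pooled odds and
records the ratio; trajectories return to the pool between iterations;
the threshold is the 95th percentile of 10 000 ratios.  The subset size
defaults to the mean number of usable trajectories per control recording.
This matters: the null must have the same sampling variability as the
experimental comparison it calibrates, which is one recording against one
recording.  Splitting the whole pool into two halves instead would shrink
the null spread by ~√(pool/recording) and turn the P95 rule into one with
a far higher false-positive rate; with recording-sized subsets the
empirical type-I error lands at the nominal ≈5 % (measured in the
acceptance suite).  When a single pooled recording is supplied the
fallback is half the pool.  Degenerate splits (a zero count) are redrawn,
capped at 100× the number of resamples.

## Morphometry

Length and width are the maximum and minimum caliper (Feret) diameters of
the convex hull of the sub-pixel (marching-squares) contour, by rotating
calipers; the test suite checks them against an exhaustive 0.1°-step
rotation oracle.  Perimeter uses the 4-direction Crofton estimator: a
plain boundary-polygon length systematically overestimates a smooth
digital outline (≈5 % on a disc), which would push the isoperimetric
roughness 4πA/P² of a circle down to ≈0.91; the Crofton estimate is
asymptotically unbiased and keeps roughness at 1 within discretization
error.  Mean gray is computed over the blob footprint on the original
grayscale (or luminance of RGB) image, not the mask.  Blobs touching the
image border are flagged as unreliable but still reported.

## Viability

Red and green channels are segmented independently with the same detector
as tracking; green blobs are viable, red non-viable, the blue channel is
ignored.  A green/red blob pair overlapping by more than 50 % of the
smaller footprint is one dual-stained cell, counted once and assigned to
the channel with the higher mean intensity over the joint footprint —
membrane-damaged cells retain some green signal in practice, so intensity
dominance is the natural tie-break.  The counting is exactly symmetric
under swapping the two channels.

## I/O

Frame stacks are exchanged as multi-page TIFF (lossless, codec-free);
AVI and other containers are routed through imageio and require a video
backend at runtime, with an explicit error naming the file otherwise.
Trajectories use one flat CSV schema (`track_id, frame, x_px, y_px[,
responsive]`) shared by the simulator and the tracker, so downstream
analyses cannot tell where tracks came from.

## Validation by simulation, and its limits

The quantitative checks run entirely on simulated material:

1. 400 neutral populations (100 cells × 500 frames each, uniform initial
   headings): the mean ch-index at γ = 30°, option 1 must sit within 3
   standard errors of the theoretical 16.67 %.
2. 30 neutral populations with ψ0 = 0 rendered to 800×800 px videos,
   re-detected and re-linked: the mean ch-index is compared with the
   reference value 17.90 ± 0.46 % for this configuration — the inflation
   over 16.67 comes from the initial heading alignment and from linking
   noise at trajectory crossings.  (30 runs rather than 400 keeps the
   check to a few minutes; the run-to-run spread is ≈0.5 points, so the
   mean of 30 is determined to ≈0.1.)
3. The bootstrap null from 100 control populations must have mean within
   [0.99, 1.01] (reference 1.0024 ± 0.0523).
4. Pairing those controls with 100 fresh neutral populations must produce
   a false-positive proportion consistent with the nominal 5 % (95 %
   binomial interval).

What this does **not** show: the simulator produces rigid, constant-speed,
always-visible cells on a clean background.  Real recordings add flagella,
focus drift, uneven illumination, debris in the size window of a sperm
head, cells swimming through z, and frame-rate-dependent sampling of the
flagellar beat — none of which are emulated.  Passing these checks
validates the statistical machinery and the tracking logic, not the
segmentation's robustness to real stain and optics; threshold settings
(cell-size window, search radius, polarity) must be re-tuned per
microscope and species.

## Known limitations

- Greedy linking is not globally optimal assignment; on dense scenes it
  fragments more than a Hungarian or Kalman tracker would.
- Head centroid only; no flagellum detection, no hyperactivation calls
  (FD is reported but no cut-off applied).
- The chemoattractant field is uniform and static; spatially varying
  gradients and flow fields are out of scope.
- AVI support depends on an external imageio backend; TIFF is the
  guaranteed path.
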