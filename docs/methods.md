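# Methods

`neutrotax` quantifies neutrophil chemotaxis in a co-flow microfluidic
gradient channel and reproduces, over synthetic ground-truthed data, the
analysis chain used to compare COPD and healthy-control sputum as
chemoattractant sources: per-cell chemotactic index and migration speed,
moment-ellipse morphometry, and cohort-level statistics against spirometry.
Because no raw image data from such assays is bundled, every measurement
stage is validated in closed loop against a simulator whose ground truth is
known exactly. This note records the models, their assumptions, the
parameter choices, and what the closed loop does and does not demonstrate.

## Gradient model

Two equal streams (chemoattractant at `c0`, plain medium) co-flow through a
channel of width W = 350 µm. In a frame advected with the fluid, the
cross-channel profile obeys 1-D diffusion on `y ∈ [0, W]` with no-flux walls
and a step initial condition (`c = c0` for `y < W/2`, source wall at
`y = 0`). The profile at downstream distance L with mean flow speed U is the
step diffused for the residence time `τ = L/U`. Two equivalent closed forms
are used: an image-source erf series for Fourier number `Dτ/W² ≤ 0.05` and a
cosine eigenfunction series above it (the image series converges slowly once
the diffusion length reaches W); both are truncated at term magnitude
1e-12. The model ignores channel height, Taylor dispersion, and the
upstream pressure-balance hydraulics: it claims only the cross-channel
profile shape, which is what a fluorescence calibration measures. Exact
consequences used as test invariants: spatial mean `c/c0 = 1/2` (mass
conservation), point symmetry `c(y) + c(W−y) = c0`, monotone flattening in
τ, and agreement with an explicit finite-volume solver (max error ~1e-4 on
a 64-cell grid).

Start-up is modeled as the steady profile scaled by the new-fluid fraction
`w(t) = ½ erfc((L − Ut)/(2√(Dt)))` — a front advected at U and smeared by
axial diffusion. The establishment time is the first `t` at which the
max-pointwise deviation `(1 − w(t))·max_y c` falls inside a tolerance,
floored at the advection time L/U. At high Péclet number it collapses onto
L/U: with dextran-scale D = 100 µm²/s and U = 500 µm/s the gradient at a
5 mm station is established (1% tolerance) in ~10 s, comfortably inside the
first minute of an assay.

Flow speed is not a measured quantity here; the default 500 µm/s is used
only in examples and the analysis drivers, never in calibration-critical
paths.

## Trajectory simulator and C.I. calibration

Cells take one step per frame (interval 10 s, 120 frames = 20 min by
default). Step direction is von Mises about the up-gradient axis with
concentration κ; step length is `v·Δt` with `v ~ Gamma(shape k, mean v̄)`
(defaults k = 2, v̄ = 0.15 µm/s, the scale of measured neutrophil speeds in
such channels). Because speed is independent of direction, the chemotactic
index of a long track — net displacement along the gradient axis divided by
path length — converges to the mean resultant length

    CI∞(κ) = I1(κ) / I0(κ),

the ratio of modified Bessel functions. `calibrate_kappa` inverts this by
bracketed root finding (tolerance 1e-12), so any target C.I. in [0, 1) can
be pinned exactly in expectation. For 120-step tracks the ratio estimator
carries an O(1/n) bias of ~0.003–0.005 (visible in the recovery benchmarks
as a mean C.I. of ~0.536 against a 0.533 target), well inside the 0.02
recovery band asserted in tests.

An optional persistence parameter blends the previous step direction into
the von Mises center; it breaks the Bessel-ratio identity and is therefore
excluded from calibration by design. Walls reflect specularly (coordinate
folding). Batch simulations seed cells away from the source wall
(y ∈ [0.5W, 0.95W] by default) so that up-gradient drift over 20 min rarely
reaches a wall; reflections would otherwise clip the measured C.I. below
its calibrated asymptote.

Competing gradients are phenomenology, not receptor biology: each
attractant has a family (`terminal` peptide such as fMLP, or `intermediate`
chemokine such as IL-8 and sputum) and a potency (the κ it would induce
alone). Terminal beats intermediate; higher potency wins within a family;
the winner's κ is reduced by half the loser's (clipped at 0), making
dominance dose-dependent. Uniform fields have zero bias.

## Rendering and morphometry

Cells are drawn as filled rotated ellipses of known area (150 µm² default)
and elongation; orientation follows the instantaneous movement direction
(`gradient_aligned`), a fixed random angle (`random`, used for uniform
fields), or is irrelevant (`isotropic`). Optional boundary perturbation
adds low-order Fourier modes to the radius. Seeding guarantees centers at
least two major axes apart (jittered-grid placement, so the bound is exact),
which keeps segmentation from merging neighbours and makes greedy linking
well posed.

Morphometry uses the moment-equivalent ("best fitting") ellipse: with
eigenvalues λ1 ≥ λ2 of the second-order central-moment matrix of the filled
region, full axes are 4√λ1 and 4√λ2 and the aspect ratio is √(λ1/λ2) —
independent of any axis-length convention and of uniform scaling. For a
solid ellipse this equals a/b exactly in the continuum; at 0.5 µm pixels
and 150 µm² cells the discretization error is ~0.1%. Regions of fewer than
5 pixels are rejected; zero-minor-eigenvalue regions (1-pixel lines) are
flagged degenerate rather than fitted. The final frame is measured by
default (end-of-assay morphology); this is configurable.

## Detection and linking

Label-mode detection reads the rendered label masks (exact centroids);
threshold mode segments grayscale frames with Otsu's between-class-variance
criterion, fills holes, and drops components below a minimum area (default
20 µm²). Linking is greedy globally-nearest-pair per frame transition with
a displacement gate (default 4·v̄·Δt) scaled by the gap length, optional
gap closing, and deterministic tie-breaking (distance, then track age, then
position), so the output is invariant to detection order. Greedy assignment
is exact under the generator's separation guarantee; it is not suitable for
dense scenes, which would need optimal assignment or motion models. With
the Gamma speed law a step exceeds the default gate with probability
~0.003, so a 120-step track occasionally fragments; tracks shorter than 10
frames are discarded before metrics. There is no mitosis handling and no
subpixel PSF fitting.

## Migration metrics

C.I. is the signed component of net displacement along the up-gradient
axis over total path length — negative values mean net movement toward the
opposite source, as required for competing-gradient readouts. The
"experiment period" in the speed denominator is the track's own duration,
since cells may enter or leave the field. Stationary tracks (zero path)
have undefined C.I.; they are excluded from aggregation and counted.
Condition aggregates are mean ± SEM over tracks, with SEM computed from the
sample standard deviation (ddof = 1). An optional per-experiment grouping
key is not implemented; pooling over tracks matches the per-patient SEM
magnitudes the statistics consume.

## Cohort generator

A synthetic cohort draws, per COPD-like subject, FEV1/FVC uniform in
[35, 75] (the observed clinical extremes) and sets the target C.I. by a
decreasing linear map scaled so the group hits mean 0.39 / sd 0.10, plus
Gaussian map noise (sd 0.03). Controls draw target C.I. from N(0.22, 0.06)
and carry no spirometry. These group parameters are the mean/sd of the
per-patient C.I. columns of the packaged clinical table. Each subject's κ
comes from `calibrate_kappa`; mean speed is drawn independently
(N(0.17, 0.05) µm/s, clipped at 0.05), so C.I. and speed are uncorrelated
by construction; sputum potency is a fixed increasing map of target C.I.,
making COPD-like samples the more potent attractant on average (emulating
their higher chemokine load as a covariate only — no ELISA chemistry is
modeled). Fifty tracks per subject by default. All randomness flows from
one root seed through `SeedSequence` spawning; identical seeds give
byte-identical exports.

At these study conditions (n = 5 + 5, effect ≈ 0.17 at pooled sd ≈ 0.085)
the two-sample t-test's power is about 0.77 by Monte-Carlo and analytic
calculation — the cohort separates the groups in most but not all
replicates, which is what the power test asserts.

## Cohort statistics

Group comparison is the pooled-variance two-sided Student's t-test (Welch
available behind a flag); three or more groups use one-way ANOVA; all at
α = 0.05 with no multiple-testing correction. The C.I.–spirometry
relationship is OLS of per-subject mean C.I. on FEV1/FVC reported as slope
and r². Small-cohort outlier exclusion is operationalized as an exhaustive
leave-one-out scan (all n regressions, sorted by r² descending with
deterministic tie-breaks) rather than a by-inspection exclusion; on the
packaged clinical table the scan excludes the youngest (age-57) subject —
who combines a low FEV1/FVC with a low C.I. — and the remaining four
subjects give slope −0.0060 per FEV1/FVC point and r² = 0.948, versus
r² = 0.341 with all five. Recomputing from the table's rounded values gives
a slightly different r² than analyses run on unrounded source data would;
tests therefore assert the scan result as a lower bound (≥ 0.93) plus the
frozen rounded-data value. Zero-variance regressions are guarded (r² = 0).

## Numerical and design choices

- Units: distances µm, times s, speeds µm/s; pixel→µm conversion happens at
  detection only. Pixel centers sit at integer coordinates, 0-based.
- The gradient axis is stored explicitly (unit vector toward the source
  wall, `(0, -1)` in channel coordinates) in configs and track-file headers.
- Series truncation 1e-12 (gradient), root-finding tolerances 1e-12
  (calibration) and 1e-6·t_adv (establishment time).
- The CLI condenses the pipeline to `simulate`, `analyze`, `stats`, and
  `run-all`; track linking and morphology are switches of `analyze`, and all
  fixtures are generated programmatically, so no separate fixture command
  exists.
- Benchmarks are sized for a single CPU: 500 tracks for C.I./speed
  recovery, 100 cells per morphology field, 200 cohort replicates for
  power, 1000 null replicates for type-I calibration.

## What the synthetic loop does not show

The simulator emulates the statistical structure the analysis assumes —
von Mises step directions, direction-independent Gamma speeds, elliptical
cells, separated seeding — not real neutrophil behavior. Passing the
closed-loop tests demonstrates that the measurement chain is unbiased and
correctly calibrated *under these laws*; it cannot validate the laws
themselves against living cells, detect segmentation failure modes of DIC
optics (halos, contact, partial focus), or certify tracking in dense
fields. Real-data use would need the threshold-mode detector retuned and
the linking gate revisited.
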