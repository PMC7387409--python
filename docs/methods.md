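# Methods

This note records the models, conventions and design choices behind
`ivmotility`, in the spirit of a methods appendix: what is computed, under
what assumptions, and where genuinely open choices were made.

## Coordinate and unit conventions

All analysis operates in the maximum-intensity-projected xy plane. Pixel
indices are 0-based, origin top-left; x increases rightward and is the
periphery→core axis throughout (the collagen-rich stromal band occupies the
low-x columns, the tumor core the rest); y increases downward. Positions
are reported in μm via the stack calibration, times in minutes. Default
acquisition geometry: 0.5 min frame interval, 61 frames (~30 min movies),
5 μm z-steps.

## Track metrics

Velocity is displacement-based: the straight-line origin→terminus distance
divided by track duration. This is deliberate — it differs from the mean
step speed and collapses toward zero for confined or looping cells even
when their instantaneous speed is high. The conventional path speed L/T is
exported alongside, clearly labelled as supplementary, for comparability
with other pipelines. The meandering index MI = d/L is defined as 0 when
L = 0 (a cell that never moved), keeping it in [0, 1]. Both v and MI are
invariant under rigid rotation and translation of a track; MI = 1 exactly
iff the track is collinear and monotone.

Tracks observed for 5 or fewer timepoints are excluded before any
statistic ("more than 5 timepoints" read strictly: a 6-point track is the
shortest retained). The cutoff is configurable.

## Motion models (synthetic generator)

- **ballistic** — fixed random heading, constant step `speed_scale·dt`.
- **confined_brownian** — isotropic Gaussian steps (per-axis sd
  `speed_scale·dt/√2`, so the RMS step equals `speed_scale·dt`), with
  radial reflection at a hard confinement boundary; positions never leave
  `confinement_radius` of the start.
- **levy** — step lengths from a truncated Pareto (density ∝ l^(−α) on
  [l_min, truncation]); the lower cutoff is 0.3·`speed_scale`·dt and the
  tail exponent defaults to α = 2 with an 8 μm truncation in the cohort
  defaults. These are placeholders for a phenomenon (clusters of small
  steps interspersed with long relocations) rather than fitted values — no
  quantitative Lévy fit exists for this system. Headings are isotropic
  with optional persistence blending (unit-normalised convex combination
  of the previous heading and a fresh random direction).
- **stationary_probing** — centroid jitter (sd 0.5 μm) plus a small 1.5 μm
  protrusion event every 10 frames lasting 2 frames; displacement ≈ 0 by
  construction, mimicking rounded cells probing their neighbourhood.

Every generator is a pure function of (parameters, seed). A master seed
fans out per-arm → per-mouse → per-cell via `SeedSequence.spawn`, so any
subset of a cohort is reproducible in isolation.

Within each mouse, motion models are assigned in *exact* mixture
proportions (floor of w·n with largest-fraction remainders, then permuted)
rather than multinomially. This removes mixture-composition noise from
arm-level contrasts, so a configured between-arm speed effect is
identifiable at desk-scale cohort sizes; the residual variance comes from
headings, step draws and placements. Cohort tracks are folded back into
the field by triangular reflection so rendering stays valid; region labels
use the starting compartment.

## Rendering

Cells are rendered as 2D Gaussian blobs (σ = cell radius / 2) at the
drift-shifted true centroid; amplitude decays geometrically at the bleach
rate per frame, before noise. The z-axis carries a fixed unimodal profile
whose maximum slice equals the 2D scene, so max projection recovers it
exactly — full 3D PSF rendering is out of scope. The mCherry channel fills
the core compartment, the SHG-like channel renders wavy fibers only in the
periphery band; stage drift shifts all channels (it is rig motion). Noise
is Poisson (photon scale) plus additive Gaussian, clipped at zero.

What the generator does *not* emulate: vascular flow, chemokine fields,
tumor growth, cell division/death, z-dependent scattering, non-rigid
tissue motion, and cell-shape dynamics beyond isotropic blobs. Passing
round-trip tests therefore demonstrates correctness of the analysis chain
on data matching its assumptions, not robustness to every property of real
intravital movies.

## Preprocessing

- **Debleach**: a single exponential is fitted to the frame means of the
  corrected channel by least squares on log-means, and each frame rescaled
  so means are flat; the first frame is unchanged. Chosen as the simplest
  model consistent with geometric photobleaching; an already-flat series
  passes through unchanged to ~1e−16.
- **Registration**: translation-only, integer-pixel phase correlation with
  classic (unnormalised) cross-correlation — the phase-whitened variant is
  brittle on smooth, low-texture fluorescence frames. All channels receive
  the same shift; the estimate uses the per-pixel channel sum by default so
  the static tumor/collagen signal anchors the drift. Rotation is out of
  scope. Exact recovery of integer drift holds when drift is the only
  motion; moving cells can legitimately bias a frame's estimate by ±1 px.
- **Detection**: Gaussian smoothing (default σ = 2.5 μm, half a cell
  radius), Otsu threshold by default (absolute threshold available),
  connected components, minimum area of a 3 μm-radius disk,
  intensity-weighted centroids. Otsu makes counts invariant to global
  intensity scaling. Two cells merged below the resolution limit count
  once — a stated limitation, optionally flagged by an area bound.
- **Contours**: local Otsu in a window around each detection; the
  component containing the centroid is kept; fitted-ellipse axes come from
  second-order region moments, and E = major/minor. Whether the original
  interactive measurement used this exact shape statistic is unknown; the
  axis-ratio choice is flagged as ours. Regions touching the window border
  or degenerate regions are recorded as failures and excluded. The
  temporal sd of E is an extension (a "morpho-dynamics" summary); only the
  mean has an external counterpart.

## Tracking

Deterministic greedy nearest-neighbour linking with a distance gate
(default 10 μm/frame, ≈ 4× the fastest expected per-frame displacement)
and gap bridging up to 1 missed frame; ties broken by lower track id then
detection index. This replaces interactive semi-automated tracking for the
sake of reproducibility; it does not attempt multi-hypothesis or
merge/split handling. Every detection ends up in exactly one track.
Region labels are assigned per track by majority vote of its positions
over the periphery/core masks (ties → peritumoral, conservative toward
the collagen interface), matching the one-region-per-cell reporting
convention. Tracking operates in the projected plane.

## Spatial analysis

Kurtosis is Pearson (m₄/m₂², population moments, no bias correction;
normal = 3, uniform = 1.8, symmetric two-point = 1, and K ≥ 1 for any
non-degenerate sample). The excess convention (K − 3) is exported
alongside for transparency. Reported kurtoses near 1.9–2.1 sit naturally
on the Pearson scale between the two-point bound and uniform/normal
values, which is why that convention was adopted. Kurtosis is always
computed from raw positions; the 25 μm histogram bins affect display only.
Concatenating multiple fields of view into one periphery→core coordinate
requires explicit field ordering metadata rather than guessing.

Vessel/cell correlation is Spearman with mid-ranks; the synthetic vessel
fields use a Gaussian copula with Pearson parameter 2·sin(πρ/6) so the
latent Spearman correlation equals the target, with Poisson marginals
(discretisation attenuates |ρ| mildly; |ρ| = 1 uses a strictly monotone
construction).

## Cohort statistics

Mean ± SEM throughout. Two groups: D'Agostino–Pearson gate on each group
(p > 0.05 both → unpaired equal-variance t-test, else Mann–Whitney);
groups with n < 8 skip the gate and use the rank test, since the gate
statistic is unreliable there. The Mann–Whitney path uses the asymptotic
normal approximation with mid-ranks and *no* continuity correction, so
exactly tied identical groups give p = 1; the U statistic itself is exact.
Three or more groups: Kruskal–Wallis, and when p < 0.05, Dunn's pairwise
z-tests on pooled mid-ranks with tie correction and Bonferroni adjustment
(the conventional family for Dunn; configurable). Type-I error of both
rank tests is calibrated by simulation in the test suite.

## Pipeline and problem sizes

The demo study uses three arms × 3 mice × 8–12 cells in a 256 × 256 px
field at 1 μm/px, 41 frames at 0.5 min, rendered with 1%/frame bleaching
and Poisson+Gaussian noise — sizes chosen so a full end-to-end run
completes in tens of seconds on one CPU while leaving every stage
statistically meaningful. Treated arms are configured slower (speed
multipliers 0.38 and 0.47 of the control) and more numerous, mirroring the
direction of checkpoint-blockade effects; the absolute velocities of real
cohorts are not reproduction targets. The pipeline manifest records every
parameter and seed; reruns with the same master seed are bit-identical.

## Known limitations

2D analysis only (projected plane); translation-only registration; no
deconvolution or learned segmentation; greedy tracker fragments tracks at
detection dropouts beyond one frame; elongation requires contours well
inside the segmentation window; merged cells under the resolution limit
are counted once; the Lévy generator parameters are illustrative defaults,
not fitted values.
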