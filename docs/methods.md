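# Methods

## Model

The package implements a systems-level model of hippocampal place-cell
formation driven purely by vision and the slowness principle.  A virtual
rat explores a 2-D arena at a constant 20 cm/s; at every time step it
records a panoramic grayscale frame covering 320° of azimuth and a narrow
vertical slice around the horizon.  The frame stream is the only input to
a four-layer network:

1. **Layer 1** — a grid of clone SFA nodes with small receptive fields
   tiling the frame, neighbouring fields overlapping by half their size.
   At full resolution (320×40 frames, 10×8-pixel fields) the grid is 63×9.
2. **Layer 2** — a second clone SFA grid over layer-1 feature maps
   (14×6-node fields → 8×2 grid at full resolution).
3. **Layer 3** — a single SFA node integrating all layer-2 channels; its
   outputs are the slowest features of the whole visual stream and play
   the role of entorhinal spatial codes.
4. **Layer 4** — a single ICA node performing linear sparse coding on the
   layer-3 features; its 32 outputs are the model's "cells", and localized
   positive bumps of their spatial activity are the model's place fields.

Each SFA stage solves, for input **x**(t), the problem of finding
projections g minimising Δ(y) = ⟨ẏ²⟩ subject to ⟨y⟩ = 0, ⟨y²⟩ = 1 and
pairwise decorrelation; nonlinearity comes from a quadratic expansion of
the input.  We solve the single generalized symmetric eigenproblem on the
pair (derivative covariance, covariance) via rank-truncated whitening
(eigenvalues below 1e-10 of the leading one are dropped).  Temporal
derivatives are forward differences over one time step.  Sign ambiguities
are fixed deterministically (largest-magnitude projection coefficient
positive; for ICA, largest-magnitude training output positive), so fields
are positive bumps and refits reproduce bitwise.

Every SFA node first reduces its input *linearly* (linear SFA) to
`reduce_dim` dimensions before the quadratic expansion.  Without this the
upper nodes would need to expand thousands of dimensions; the reduction
dimension (48 at full scale, 24 at desk scale) is the network's main
capacity knob.

### Regularisation

Single-experiment streams are short (an 8-minute session is 9,600 frames)
relative to the dimensionalities involved, and an unregularised fit
memorises the trajectory: its outputs look slow on the training stream but
are temporally white on a held-out trajectory from the same arena.  All
node fits therefore add an isotropic ridge of 1% of the mean signal
variance to both covariances — exactly the moment-domain equivalent of
training with additive white observation noise, the device the
hierarchical-SFA literature uses for the same purpose.  After solving the
regularised problem, the projection is symmetrically re-whitened against
the *unshrunk* covariance so the zero-mean/unit-variance/decorrelation
constraints hold exactly (to 1e-6) on the training data.

### Training stages

Generic pretraining fits layers 1–2 on pooled streams from four unrelated
"generic" mazes (a rectangular box, a plus-shaped multi-arm maze, an
obstacle-littered square, a T-maze with an obstacle) and freezes them;
clone layers fit one weight set on patches pooled over all receptive-field
positions (up to 200,000 patches, subsampled with the run seed).  Each
experiment then trains only layers 3–4 on its own visual stream.  The
ICA stage maximises a non-Gaussianity contrast by fixed-point iteration
with symmetric decorrelation (scikit-learn FastICA); the log-cosh
contrast is used because the cube (kurtosis) iteration diverges on the
heavy-tailed activity distributions sparse components produce.  All ICA
randomness is seeded from the run seed.

## Behaviour

Random foraging draws, each step, a new direction uniformly within ±160°
(the field-of-view half-angle) of the current heading, blends it with the
old heading through a momentum term, and advances exactly `speed·dt` cm;
steps that would come closer than `wall_margin` (default 5 cm) to a wall
are re-aimed toward the arena interior.  Waypoint following adds
Gaussian lateral noise (scale `waypoint_noise`, default 3 cm) to the
direct path and cycles the waypoint list, so no two laps repeat.

The momentum default is 0.2.  This is a deliberate model choice: in
slowness-based models the character of the learned code depends on the
relative timescales of rotation and translation — position is only
extracted cleanly when head direction varies much faster than location.
With momentum 0.2 the heading decorrelates within a few hundred
milliseconds while position decorrelates over tens of seconds, which is
the place-cell regime; at momentum ≳ 0.8 the heading itself becomes slow
enough to leak into the learned features and directional tuning appears
even in the open field.  The time step is dt = 0.05 s (20 frames/s,
1 cm per step), so 8 simulated minutes are 9,600 frames.

## Rendering

Frames are produced by per-column 2-D ray casting: each pixel column
covers an equal slice of the 320° field of view centred on the heading;
the nearest wall intersection determines, via perspective projection
(apparent height ∝ wall height / distance at 3 cm eye height, rows
spanning ±20° of elevation), which rows show the wall texture, which show
the floor, and which show the background.  Because walls never vary
vertically and all protocol arenas are convex (or use view-blocking tall
walls), the single-hit ray cast is exact.  Textures and the 360° "office
panorama" background are deterministic procedural patterns; the panorama
is rendered on a distant cylinder (default 5 m), giving genuine parallax.
Cue cards override their wall's colour over their arc, full height.
Circles are discretised at 1° (360 segments; 2° in the desk-scale
profile, matching its 2°/column resolution).

The morph-stage family interpolates a superellipse between the 62 cm
square (t = 0) and the radius-39 cm circle (t = 1), with exponent 2/t and
linearly interpolated extent.  The published intermediate shapes are not
reprinted anywhere we can reach, so this family is an explicit
approximation; its endpoints are exact.

## Sampling and analysis

Two readouts are implemented.  Dense sampling renders a frame at every
grid point of the arena (1 cm at full scale, 3 cm at desk scale,
respecting the wall margin) for each of the eight compass head directions
and records all 32 cell activities; maps are rectified at zero before
analysis, since they represent firing.  Trajectory sampling converts
activities along a behaviour trajectory into artificial spikes (per-step
probability = rectified activity / full-pass peak), bins them on a 3 cm
grid, divides by occupancy time and smooths with a 3 cm Gaussian
renormalised over the visited mask.

Directional consistency is the mean Pearson correlation between the eight
fixed-direction maps and their pixelwise average (zero-variance maps
contribute 0).  Place fields are 8-connected components above 50% of the
*cell's* maximum activity; components of 25 cm² or less are discarded
(the area rule is expressed in cm² so it is resolution-independent).
When one cell is sampled under several conditions — e.g. the two
traversal directions of a track — all its maps share one rate scale
(spike probabilities are normalised by the cell's peak over the whole
sampling run) and segmentation uses the cell-wide maximum, so a weak
condition cannot manufacture fields of its own.

Track cells are classified by rating each traversal direction *clear*
(has a segmented field), *active* (crosses half the cell's peak but
forms no field — significant yet spatially unstructured activity) or
*none* (never reaches the segmentation threshold, or peak below 10% of
the population median).  *Unidirectional* means clear in exactly one
direction with none in the other; a clear field accompanied by
significant unstructured activity the other way counts as
*bidirectional*; a cell with no clear field at all is *silent*.  The
10%-of-median floor and the reuse of the 50% segmentation constant are
this package's operationalisation of the qualitative experimental
judgement ("clear field", "little to no activity", "significant but
unstructured").  Cells of independently trained networks are paired by
maximising total absolute map correlation (Hungarian assignment).

## Profiles and problem sizes

The full profile reproduces the published architecture and is provided
and tested structurally, but training it takes tens of minutes per
protocol on one CPU, and generic pretraining at the default 100,000
frames holds the frame corpus and its layer-1 feature maps in memory
(roughly 16 GB of RAM; reduce ``generic_frames`` on smaller machines).  All quantitative tests and the acceptance script
use the desk-scale profile: 160×24 frames (2°/column), 20×8-pixel fields
(15×5 grid), 6×2-node layer-2 fields (4×4 grid), 16 channels in the clone
layers, reduction dimension 24, and 10,000 generic pretraining frames —
while keeping the 32-cell output layer, all arena geometries, durations,
speeds and behavioural parameters at their protocol values.  Protocol
durations follow the experiments: 8 min (development, cue cylinder),
12 min (cue removal), 5 min (linear track), 6.5 min (rhombus), 10 min per
arena (morph, stretch).

## What the desk-scale results do and do not show

The desk-scale model reproduces the qualitative phenomena: localized
place fields from vision alone, direction-invariant firing under random
exploration and direction-*sensitive* firing under constrained paths
(east/west tuning curves of the same cell are uncorrelated on the linear
track), cue-anchored field rotation by the cue's own angle, and
population splits into silent / unidirectional / bidirectional classes
on the tracks.  Three quantitative readouts carry known desk-scale
biases:

* **Open-field directional consistency** centres around 0.83–0.86 rather
  than tightly at 1.  Held-out-slowness diagnostics show the reduced
  network learns view-invariance only partially from a single 8-minute
  session in the large cylinder; lengthening the session closes the gap,
  identifying sampling density rather than the model as the cause.
* **Track directional-consistency histograms** sit around 0.4 instead of
  peaking at 0.  The corridor maps contain only a few dozen valid
  pixels at 3 cm resolution, and after rectification two sparse maps
  correlate substantially by chance overlap alone; the statistic is
  biased upward on very small masks.
* **The silent fraction is smaller than at full scale.**  The regularised
  desk network produces spatially reproducible structure (split-half map
  reliability ≈ 0.95) in nearly every cell even on the quasi-1-D track
  data, so few cells fail the "clear field" test.  An unregularised fit
  of the full 1,224-dimensional quadratic expansion on a 5-minute track
  stream has far more sample-starved components, and unstructured,
  effectively silent cells are plausibly a fingerprint of exactly that
  regime; the regularisation was kept because removing it degrades every
  open-field result.

The synthetic environments idealise real arenas: procedural textures
instead of photographs, no lighting or shadows, constant running speed
with no grooming pauses, and heading locked to the direction of motion.
Passing tests therefore demonstrate properties of the model under these
idealised study conditions, not claims about biological tissue.

## Degenerate inputs and numerical edges

Rank-deficient covariances are truncated rather than inverted, so
constant pixels (e.g. a cue filling a receptive field) and zero-noise
waypoint laps do not crash the fits.  A cell with all-zero rectified
activity produces an empty spike record and an empty field list, and
contributes 0 to directional consistency if its map has no variance.
FastICA non-convergence is reported on the model (`converged=False`) and
the best iterate is used.  All randomness flows from a single run seed
through named substreams, and every artifact (trajectories, networks,
maps, reports) reproduces bitwise under the same configuration.
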