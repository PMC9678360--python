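# Methods

This note documents the models, measurement rules, and numerical choices
behind `polegrowth`, in the order data flows through the package.

## The lineage model

A cell is a rod of length `L` (µm) that elongates only at its poles:
`rate_old` µm/frame at the established (old) pole and `rate_new` µm/frame at
the pole formed at the last division (one frame = `frame_interval_min`
minutes, default 15, the cadence of mycobacterial microfluidic time-lapse
imaging). Division fires at the first frame whose length reaches
`division_length` and places the septum at a relative position (measured
from the new pole) drawn from a normal distribution
(`septum_rel_position_mean`, `septum_rel_position_sd`) truncated to
(0.2, 0.8) — the truncation rules out degenerate near-zero-length daughters
while still allowing clearly asymmetric divisions. Each daughter inherits
one pre-existing pole, whose age in generations is incremented, and one new
pole of age 1. The daughter on the mother's old-pole side therefore carries
an old pole of age `mother_age + 1`; the daughter on the new-pole side
carries an old pole of age 2.

Founder cells have no recorded division behind them, so their new/old pole
assignment is a convention, not an observation. They are flagged
(`orientation_known = False`) and excluded from all pole-resolved statistics,
mirroring analyses that only use cells followed from birth to division.

The division trigger is a length threshold rather than a timer because it
makes the per-pole growth ledger exact: with the per-cell variability
switched off, every cell's old-pole share of elongation is
`rate_old / (rate_old + rate_new)` to machine precision, which is the
ground truth the measurement code is validated against. One caveat follows
from the discrete frames: full-cycle growth is
`rate_old * ceil((division_length − birth_length) / total_rate)`, and at
rate values where the ceiling drops by one frame the product can decrease
slightly even as `rate_old` increases. Monotonicity of old-pole growth in
`rate_old` therefore holds per frame, and across the full cycle whenever the
interdivision time is unchanged, but not across those ceiling boundaries.

### Biological variability

Two parameters give cohorts the cell-to-cell spread real single-cell data
shows: `rate_cv` (default 0.15) multiplies each cell's total rate by a
gamma-distributed factor with mean 1 and that coefficient of variation, and
`pole_share_sd` (default 0.03) jitters each cell's old-pole share around the
configured value (clipped to [0, 1]). The defaults are in the range reported
for single-cell mycobacterial growth. They matter statistically, not just
cosmetically: with identical cells, every replicate median ties exactly, the
error sum of squares of the paired ANOVA is zero and its p-value
degenerates. Setting both to 0 restores the exact closed-form ground truth
used by the deterministic tests.

All stochastic draws across the lineage, the renderers, and the pipeline
derive from a single seed; per-cell and per-stage streams are spawned
deterministically from it, so one integer reproduces a whole run
byte-for-byte.

## Fluorescence rendering

`render_localization_track` paints one axial profile per frame of a cell's
life (birth to the last frame before division), oriented new pole → old
pole, sampled at pixel centres (`pixel_size_um`, default 0.1 µm/px).
Localization programs: `old_pole`, `new_pole`, `bipolar` (per-pole
amplitude scales), `midcell_late` (a septal spot appearing after
`septal_onset_fraction` of the cycle), and `uniform`. Polar spots are
Gaussians of s.d. `spot_sigma_px` (default 2 px) centred on the terminal
sample; after the septal onset, `septal_transfer_fraction` of the polar
amplitude moves to a spot at the cell's (ground-truth) septum position.
This reproduces the program of an old-pole growth factor that partially
relocalizes to the septum late in division and disappears from the new
poles after separation. Gaussian noise of s.d. `noise_sd` is added last,
on top of `background`.

`render_pulse_chase_pair` renders the two profiles of a cell-wall
pulse-chase: at birth the labeled (bright, `background + label_intensity`)
region spans the cell minus any growth already accrued since staining
(`pulse_chase_offset_um` per pole, default 0); at the frame before division
the labeled block is flanked by dark margins equal to the growth each pole
inserted since birth, rounded to whole pixels. Edges are sharp (no optical
blur on 1-D profiles); consequences for the measurement are discussed
below.

`render_frame_image` renders live cells as spherocylinder footprints on a
blank field — random non-overlapping positions and angles per frame, a
placement error if the retry budget is exhausted — with the axial
localization signal painted along each cell's axis, an isotropic Gaussian
PSF (`psf_sigma_px`), and a ground-truth label mask. It is a snapshot
renderer: placements are independent between frames, so cross-frame
tracking goes through the lineage table (which records pole coordinates),
not through the images.

## Profile extraction from images

Segmentation is a global Otsu threshold plus connected components; objects
touching the image border or smaller than `min_area` are discarded (a
constant image yields an empty mask, not an error). The medial axis is the
morphological skeleton pruned to its longest geodesic path, extended
tangentially to the object boundary at both tips, and re-parameterised at
1-px arc-length steps. At each step the image is sampled (bilinear) at
`width_px` points perpendicular to the local axis direction — default 5 px,
matching segmented-line practice for localization profiles, with 7 px as the
pulse-chase preset — and averaged; samples outside the image or outside the
object are excluded so background never dilutes the profile. Axis placement
is sub-pixel: on a straight uniform rod the profile is exactly constant and
its length matches the rod length to ±1 px, but on a gradient the samples
can sit up to ~0.5 px off the integer grid. A disconnected skeleton raises a
shape error naming the object. Background, when subtracted, is the
per-frame median of non-object pixels (robust to sparse fields), with
values clipped at 0.

## Pole identity

Lineage route (`orient_track_new_to_old`): the daughter pole formed at the
mother's septum is the new pole. The track's end coordinates at birth are
compared against the mother's recorded septum coordinate; the nearer end
becomes sample index 0, all frames flip consistently, and a mismatch beyond
half the mother's division length raises a lineage error. Because the
endpoints themselves carry spatial continuity, daughters swapped in a table
are still resolved correctly. Founders keep orientation `unknown` and are
skipped downstream.

Brightest-pole route (`orient_by_brightest_pole`), for single-timepoint
cohorts with no lineage: the mean of the first versus last
`ceil(terminal_fraction × length)` samples decides the flip; an exact tie
keeps the original order, making the operation an involution. The default
`terminal_fraction` of 0.1 is a package choice — the window is not specified
by the upstream tooling this mimics.

## Kymographs

`grid_normalize_track` maps a track onto a T × L grid of relative cycle
time (row i at `i/(T−1)`; frame j of an F-frame track at `j/(F−1)`) by
relative position (0 = new pole, 1 = old pole): each frame's profile is
linearly resampled to L bins, then each positional bin is linearly
resampled across time — bilinear interpolation overall, no extrapolation,
grid endpoints mapping exactly to the first/last frame and the pole tips.
Relative (not absolute) time is used so cells with different interdivision
times average onto one map. Defaults T = 50, L = 100 give 1% positional
bins and oversample a multi-hour cycle imaged every 15 min.

`average_kymographs` normalizes each cell first — default `row_sum`, which
scales every time-row to sum 1 so the average reads as a localization
probability map per cycle stage — then takes the pointwise mean. `none`
(raw, used for intensity comparisons such as pole-intensity snapshots
between strains) and `global_max` are retained. Whether per-cell
normalization precedes averaging in the analyses this package mirrors is
not stated anywhere; `row_sum` is this package's documented default, not an
inference about anyone else's choice.

`pole_intensity_snapshot` takes the time-row nearest a requested cycle
fraction and averages the first/last `ceil(pole_window × L)` bins per cell.

## Demographs

One profile per cell, oriented brightest-pole-left, left-justified, padded
on the right with NaN (excluded from every statistic), stacked sorted by
ascending length — length as the cell-cycle proxy, shortest first; the
export records the convention so renderers can flip. No length
normalization: absolute length carries the ordering signal. The sort is
stable, so input order only matters among exact length ties.

## Pulse-chase growth measurement

For each profile, the labeled plateau level is estimated as the median of
the top quartile of samples; the labeled region is the maximal contiguous
run of samples at or above
`background + threshold_fraction × (plateau − background)` (default
threshold_fraction 0.5 — a half-plateau crossing, the simplest bias-stable
boundary rule; on noise-free data any threshold in [0.3, 0.7] gives
identical results). Runs separated by gaps of at most `max_gap_px` (default
2) sub-threshold samples are merged; if more than one run survives, the
longest is used and the measurement is QC-flagged `ambiguous_label`. No
sample above threshold raises `NoLabeledRegion` naming the cell.

Growth at a pole is the increase of its unlabeled margin (distance from the
cell end to the labeled-region boundary, whole pixels) between birth and
the pre-division frame, floored at 0; a floor that clips more than 1 px
adds a `negative_growth_clipped` flag. Margins are integers, so growth is
quantized at the pixel (0.1 µm default). Measurements are exported both in
µm and as a percentage of birth length. The intensity criterion separating
labeled from unlabeled wall is a package decision validated by parameter
recovery on synthetic data only.

## Super-plot statistics

Per-cell values are reduced to the median of each (strain, replicate)
group — a balanced design is required, and even-sized groups use the
ordinary sample median. The paired one-way ANOVA is the balanced
repeated-measures decomposition with replicate as block:

    SS_strain = n Σ_s (m̄_s − m̄)²,  SS_block = k Σ_r (m̄_r − m̄)²,
    SS_error = SS_total − SS_strain − SS_block,
    F = (SS_strain/(k−1)) / (SS_error/((k−1)(n−1))),

with the p-value from the upper tail of F_{k−1,(k−1)(n−1)}. For k = 2 this
equals the squared paired t statistic on block-wise differences. Zero error
variance with a non-zero strain effect is reported as F = ∞, p = 0 and
flagged degenerate rather than raised. With a reference strain, each other
strain gets a k = 2 paired contrast, Holm-adjusted by default (Bonferroni
and none are available); the choice of correction is a package default, not
a claim about upstream practice.

Two calibration notes from the synthetic design. First, with n = 3 blocks
the within-block permutation null has only 2³ = 8 arrangements, so
permutation and parametric p-values agree only on larger designs (the test
suite checks agreement at 3 strains × 8 blocks). Second, because growth is
quantized at whole pixels, replicate medians under the null often tie,
making the realized false-positive rate of the paired test conservative
(below nominal 5%) on simulated data.

## What the generator does and does not emulate

Emulated: per-cell axial profiles across the cycle for old-pole, bipolar,
late-septal and uniform programs; pulse-chase pairs with dark polar
extensions; lineage structure with pole ages and septum positions;
strain-level differences in per-pole growth shares and in per-pole signal
amplitudes; frame-level images with a Gaussian PSF and ground-truth masks;
additive Gaussian noise.

Not emulated: photobleaching, focus/stage drift, microfluidic flow
artifacts, crowded fields requiring robust segmentation, realistic
(non-Gaussian) PSFs, diffraction-blurred edges on 1-D pulse-chase profiles,
and cross-frame image registration. Passing tests therefore demonstrate
correctness of the measurement and statistics chain against the model's
ground truth — not robustness to the full failure modes of real
micrographs, which sit outside this package's scope. Whether redistributing
growth between poles conserves the total elongation rate is left open: the
simulator exposes the total rate as a free parameter instead of assuming
conservation.

## Problem sizes

The test and acceptance runs use cohorts of 25 cells for kymograph
averaging and pole snapshots, 30–50 cells per condition for pulse-chase
recovery (asymmetry levels 0.5–0.8, noise at 5% of the label), 3 replicates
× 30 cells for super-plot calibration over 50 seeded repetitions, and small
multi-strain pipelines for determinism checks. These sizes match the
cohorts typical of single-cell time-lapse studies and keep the full suite
fast on one CPU.
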