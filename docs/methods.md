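# Methods

## Scope and data model

The package measures macular neovascularization (MNV) on en-face OCTA
angiograms and relates the measurements to 3-year treatment demand.
The unit of image analysis is a 2-D intensity grid with an isotropic
physical pixel scale supplied by the caller (default 6 mm field over
500 samples, 0.012 mm/px). The scale is deliberately an input, never
inferred from file metadata: swept-source devices report a 6×6 mm cube
of 500 A-scans per B-scan, but the effective en-face grid spacing of an
export is not standardized. The MNV region of interest (ROI) is an
input mask or polygon — manual delineation in the clinic has no
algorithmic equivalent, and automatic MNV segmentation is out of scope.
Polygons are rasterized by even-odd containment of pixel centers.

## Measurement chain

**Binarization.** The flow threshold is computed from ROI pixels only
(Otsu by default, `fixed:<v>` as an alternative) after optional
Gaussian pre-smoothing (default σ = 1 px). The smoothing is part of the
default measurement chain: multiplicative speckle leaves binarized
vessel borders ragged, and thinning ragged borders inflates centerline
length by 20–30 %; with σ = 1 the end-to-end length error drops to a
few percent while Dice overlap with ground truth stays ≈ 0.9. On
noiseless two-level images, thresholding with smoothing disabled
recovers the true mask exactly. Specks up to 3 px are removed.
A constant-intensity ROI carries no threshold information: if the
constant equals the image background level the result is an empty mask
with a warning (a delineation over signal-free retina), otherwise a
degenerate-input error naming the ROI.

**Centerlines.** Topology-preserving thinning (Lee's method in
scikit-image) reduces the mask to 8-connected one-pixel midlines; the
skeleton has exactly as many connected components as the mask and is
idempotent on already-thin input. Thinning erodes roughly half the
vessel width from each free end, so terminal branches are re-extended
along their heading while still inside the mask (never closing a 2×2
block, which would violate thinness). An optional multiscale
vesselness step (Sato filter, σ = 1–3 px) can bridge faint narrow
segments before thinning (`bridge=True`); it is off by default because
the synthetic battery does not produce interrupted vessels.

**Graph decomposition.** Skeleton pixels with one 8-neighbor are
endpoints; pixels with three or more are junction pixels, and
8-adjacent junction pixels are merged into a single node so crossings
do not fragment into spurious micro-edges. Edges are maximal node-free
pixel chains; their length sums axial steps (1 px) and diagonal steps
(√2 px) times the pixel scale, plus the step onto each junction cluster
and from the attachment pixel to the cluster centroid (so length
absorbed into compact junctions still counts; a plus-shaped skeleton
measures its exact arm lengths). Isolated 8-connected cycles become
single self-edges. Chain-coded length overestimates true Euclidean
length by ≤ 8 % at worst-case orientations (≈ 22.5°), which dominates
the 10 % round-trip budget against rasterized ground truth.

**Fractal dimension.** Box counting on a single origin (no offset
averaging, for determinism): the structure is cropped to its bounding
box and occupied boxes are counted for sizes 2, 4, 8, … up to a quarter
of the *longer* bounding-box side (the shorter side would admit no
scales for a straight line, which must measure dimension 1). At least
three scales are required; fewer raise an error rather than return an
unstable slope. FD is the least-squares slope of log N versus
log(1/size); the (size, count) table is retained in the provenance
block. The default substrate is the skeleton — a cohort mean FD around
1.26 is consistent with curvilinear networks, whereas filled masks push
the estimate toward 2 — and `fd_substrate="mask"` switches. Reference
values: straight line 1.0, filled square 2.0, depth-5 Sierpinski carpet
1.853 measured against log 8/log 3 ≈ 1.893 (the power-of-two ladder is
incommensurate with the carpet's base-3 construction; the bias is
within the ±0.05 band used throughout).

**Area and flow density.** Area defaults to the delineated ROI (the
membrane's two-dimensional extent) with `area_substrate="mask"` for the
flow area; flow density is 100·|mask|/|ROI| exactly.

## Synthetic ground truth

**Networks.** A stochastic recursive branching model (chosen over
L-systems for direct length bookkeeping): each root sprouts a tip that
grows one straight segment per generation (log-normal length, default
0.30 ± 0.10 mm; Gaussian heading jitter, σ = 25°) and bifurcates with
probability 0.6 at ±22.5°; 2 roots, 5 generations. Defaults give
lesions of ≈ 10 mm total length within the 6 mm field, the scale of
typical treatment-naïve membranes. Total length is recorded as the
exact sum of segment lengths. Branching probability is the documented
monotone complexity knob: its measured FD after rasterization increases
with it (Monte-Carlo checked at 50 seeds per level).

**Rasterization.** Bresenham centerlines (inclusive endpoints) on the
500×500 grid, clipped at the field border, dilated to the vessel width
(default 3 px ≈ 36 µm, the caliber OCTA resolves well).

**Angiograms.** Two-level image (vessel 0.75, background 0.28 on
[0, 1]) times gamma speckle with fractional SD 0.25 (moderate residual
speckle after on-device averaging), plus a spatially correlated
background texture (Gaussian field, σ = 2 px, amplitude 0.05),
clipped to [0, 1]; 16-bit on disk. With all amplitudes zero the image
is exactly two constants. The model does not emulate projection or
motion artifacts, segmentation-line errors, or signal falloff —
passing round trips show the measurement chain is correct on clean
vascular geometry, not that it is robust to every clinical artifact.

**Cohorts.** Marginals are calibrated to the published 68-eye moments.
Area and sumL are log-normal (printed SDs ≈ means exclude normality on
positive support) with their underlying normals correlated at ρ = 0.8 —
a joint distribution is not published; a strong positive size–length
correlation is the physiologically defensible choice, fixed once. FD
and flow density are truncated normals on [1, 2] and [0, 100] whose
location/scale are solved numerically so the *truncated* moments equal
the printed ones (naive parameters would bias the FD mean by ≈ +0.012).
The injection count is negative binomial (printed variance 72.25 >
mean 19.8) with log-mean linear in standardized log-area, log-sumL and
FD. Standardized *log* size predictors are used in the data-generating
process because the raw log-normal has no moment-generating function —
a log-link on raw area would give the count an infinite mean. The
intercept and dispersion are solved in closed form (normal and
truncated-normal MGFs) so the count's marginal mean and SD equal
19.8/8.5 for any effect sizes, including all-zero (the exact null
generator used for type-I-error studies).

Effect sizes are free parameters — the source cohort reports only a
significance pattern. Defaults (0.11, 0.11, 0.17 per standardized
predictor) were fixed from a power computation: each of area, sumL and
FD then carries a marginal correlation ≈ 0.40 with the count, power
≈ 0.92–0.95 at n = 68 and α = 0.05, while flow density carries none.
Visual acuity: baseline N(0.58, 0.33) logMAR; change N(−0.04,
√(0.40² − 0.33²)) independent of baseline and of every vascular
parameter, reproducing both printed marginal SDs and the null
acuity associations. MNV type is multinomial (31, 19, 18)/68,
independent of outcomes.

## Robust statistics

Percentiles use linear interpolation between order statistics (the
default of mainstream statistical software; conventions differ, so it
is fixed and documented). The printed form of the weight function is
typographically ambiguous; the adopted reading is a Gaussian kernel in
the normalized excess over the fences,

w(x) = exp(−0.5·(max(0, t_low−x, x−t_high)/(0.5·(t_high−t_low)))²),

implemented in one central function so an alternative reading is a
one-line change; the properties that matter (w ≡ 1 on the fence
interval, continuity, symmetric monotone decay) hold under any
plausible reading. Degenerate fences (p10 = p90) yield unit weights
with a warning. Model weights are geometric means over the numeric
variables in that model (including the dependent variable and any
confounder).

Fits delegate to statsmodels — WLS (coefficient t tests on n − p
residual df; an integer weight k is equivalent to k-fold row
replication) and GLM-Binomial with variance weights for the logistic
branch (IRLS, tolerance 1e-8, ≤ 100 iterations, Wald tests; rescaling
all weights leaves coefficients unchanged). Separation is detected as
perfectly fitted probabilities and raised as an error with guidance.
Rank-deficient designs raise an error naming the collinear columns.
The count outcome is analyzed by weighted linear regression (matching
the reported analysis style for interval-scaled outcomes); no
dichotomous outcome occurs in the battery, so the logistic branch is
exercised only by its oracle tests. The acuity outcome is the change
score (3-year − baseline logMAR) with baseline as confounder —
"final adjusted for baseline" is computable but not the default. Raw
p-values at the 5 % level are reported (no multiplicity correction, to
mirror the source analysis; Holm adjustment is an option). Eyes are
treated as independent.

Under the null generator the four parameter-vs-count tests reject at a
pooled rate of ≈ 0.04 (250 cohorts × 4 tests in the suite; 0.0375 at
1000 cohorts during development) — slightly conservative because
downweighting heavy-tailed regressors without re-inflating the residual
variance shrinks the effective sample.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; a pipeline run fans a
single global seed into per-stage child seeds via `SeedSequence` spawn
keys, so stages re-run independently and bit-identically. The test
suite uses fixed seeds throughout; Monte-Carlo checks use 200 cohorts
for calibration and power, 250 × 4 for size, and 50 seeds per level for
the branching-knob check — sizes at which the quantities under test
have standard errors a few times smaller than their acceptance bands.
The acceptance script reports grand means over 200 cohorts of 68 eyes
(n = 13 600 draws per marginal).

## Known limitations

- The generator produces trees (with incidental raster-level loops),
  not the anastomosing capillary plexus of a real membrane; no
  hemodynamics, no 3-D structure.
- Chain-coded length is orientation-biased by up to ≈ 8 %; offset-free
  single-origin box counting is ladder-dependent (carpet bias above).
- Flow density of paired synthetic images depends on the ROI dilation
  radius and sits below the cohort-calibrated marginal; the cohort
  sampler, not the image battery, carries the published moments.
- The weighted fits do not model within-patient correlation of fellow
  eyes, mirroring the source analysis.
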