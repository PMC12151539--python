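# Methods

`synquant` quantifies developmental synapse elimination from two kinds of
raw data: multi-channel fluorescence images of the retinogeniculate
pathway (eye-specific tracer territories in the dLGN, glial cells with
engulfed tracer, synaptic punctum fields, activity stains) and
whole-cell voltage-clamp recordings of dLGN relay neurons.  Because the
measurements it automates are usually validated by eye, every pipeline
here is validated instead by *parameter recovery*: a seeded generator
produces inputs with exact ground truth, the full pipeline runs on the
rendered data, and the recovered quantity is compared with the truth.
This note records the models, the defaults, and the reasoning behind the
choices that were genuinely open.

## Conventions

Image arrays are `(z, y, x)` (or `(y, x)` in 2D) with per-axis voxel
sizes in micrometres; anisotropic voxels are first-class and every
distance or volume is computed in µm, never in voxel units.  The
physical centre of voxel `(k, j, i)` is
`((i+0.5)·dx, (j+0.5)·dy, (k+0.5)·dz)`; reported spot positions are
physical `(x, y, z)`.  Traces hold current in pA at a uniform sampling
rate (20 kHz in all synthetic recordings); inward currents are negative,
and response-curve amplitudes are folded to positive nA magnitudes, so
all ratios are ratios of magnitudes.

## Eye-specific segregation

For each dLGN section the two tracer channels are background-subtracted
(mean over a hand-drawn signal-free region), clipped at zero, and
normalized by the per-channel maximum over the dLGN mask.  Clipping
negatives before max-normalization is our choice — it keeps the [0, 1]
contract and matches intensity semantics; retaining negatives would only
perturb the sub-threshold range.  A pixel is *real* in a channel when
its normalized value is ≥ the cutoff; percentage overlap at cutoff *t*
is `100 · Σ|both real| / Σ|dLGN|`, pooled across an animal's sections as
a ratio of totals (not a mean of per-section ratios, which would weight
small sections up).  The default cutoff series is
0.1, 0.125, …, 0.25; an alternate 0.05–0.2 series is selectable.  The
profile is monotone non-increasing in the cutoff by construction, and
the sweep separates genuine overlap (which survives high cutoffs) from
background noise (which does not).  A per-channel Otsu binarization with
mask AND is provided for rendering thresholded territories; a
convenience auto-mask (largest Otsu component of the summed channels)
exists but is non-canonical — the reference analysis uses hand-drawn
masks.

The synthetic territory generator draws two complementary territories
with a smoothed random boundary inside an elliptical ROI, sized so each
covers `(1+θ)/2` of the ROI and their intersection exactly `θ` (the
target overlap), renders them at amplitude 100 over a background offset
of 10 with Gaussian noise (default sd 5, i.e. SNR 20), and records the
truth masks plus the per-threshold overlap of the noiseless render.
Edge smoothing (0.7 px) leaves a thin boundary strip with signal in both
channels, so a target of 0 reads as ~2% at the lowest cutoffs and ~1.5%
at mid cutoffs — visible in the recovery table and intrinsic to any
band-limited image of abutting territories.

## Segmentation primitives

The interactive surface-creation steps of commercial software are
replaced with classical operations: white-tophat background subtraction
with an ellipsoidal ball (per-axis radius in voxels from the µm radius;
defaults 1 µm for microglia, 1.4 µm for astrocytes, 0.5 µm for tracer),
Gaussian smoothing with sigma = grain/2, thresholding (Otsu; manual; or
the "highest inflection" rule, implemented as the maximum curvature of
the smoothed descending log-histogram), 26-connectivity labeling, and a
strict-inequality voxel-count filter (an object of exactly 10 or 2000
voxels is removed by the 10–2000 bound, matching "bigger than … smaller
than").  Machine-learned pixel classifiers are deliberately out of
scope: no training data ships with the source protocols, and the manual
threshold fallback is itself part of those protocols.

Spot detection is an anisotropic Laplacian-of-Gaussian matched to the
stated ellipsoid half-axes (per-axis sigma = radius/√3, the solid-blob
matched scale), with local-maxima extraction, a quality threshold,
KD-tree non-maximum suppression at `max(rxy, rz)` physical separation
(ties broken by lower (z, y, x) index), and per-axis parabolic sub-voxel
refinement.  The default quality threshold — the one genuinely
unstated parameter — is `max(0.25 · max response, 5 · σ̂)` with σ̂ a
median-absolute-deviation estimate of the response noise floor; it was
calibrated once on the synthetic punctum fields (recall and precision
≥ 0.95 at SNR 5) and is exposed everywhere.

## Engulfment quantification

Cells are a labeled 3D grid; each tracer channel is binarized to a mask;
a cell's engulfed volume per channel is the count of tracer voxels lying
on its label times the voxel volume.  "Fully enclosed" is interpreted
voxel-wise (a tracer voxel counts iff it is on the cell label); a
stricter object-level rule (an entire tracer component inside one cell)
is available by configuration.  Cells touching the stack boundary are
excluded by default — their somata and processes are not fully
contained — and an ROI mask can restrict analysis to cells whose
centroid lies in a stated region (e.g. the ipsilateral-input zone).
CD68 activation metrics are computed per cell the same way: mask-volume
fraction and summed raw intensity per µm³.

The per-cell right/left engulfment ratio cancels labeling and surgery
confounds.  Zero denominators (or numerators) are *censored* and
reported rather than replaced by a pseudocount: the ratios are displayed
on a log scale, which can represent neither 0 nor ∞, and no pseudocount
convention is stated in the source protocols.  Censoring is symmetric,
so the reciprocal property (swapping channels inverts every non-censored
ratio exactly) holds by construction and is asserted in tests.

The synthetic engulfment stack renders each cell as a union of 5–15
spheres (radii 2–6 µm) jittered around a soma centre and capped at a
7 µm radial extent, placed without touching; engulfed puncta are spheres
placed fully inside cells (centre deeper than radius + 0.1 µm), with the
analytic volume `4/3·π·r³` recorded as truth *before* rendering, and
background neuropil puncta outside every cell.  Punctum centres carry
sub-voxel jitter so voxelized sphere volumes are unbiased against the
analytic truth (centring every sphere on a voxel centre biases the
rasterized volume by ~9% at the default 0.4×0.2×0.2 µm grid).  The
default voxel size keeps 2× z anisotropy while letting several
non-touching microglia-scale cells fit a 256-px field; at the raw
acquisition sampling (~0.075 µm xy) a single field is too narrow for
that.  Rendering uses a 0.1 µm Gaussian PSF (confocal-realistic) and a
detector model of baseline offset + Poisson shot noise + Gaussian read
noise.  The offset matters: clipping zero-background read noise at the
detector floor produces a half-normal background whose LoG response is
heavy-tailed, which no real offset-calibrated acquisition shows.

Benchmark segmentation thresholds at half the rendering amplitude above
the image median (a baseline estimate, since most voxels are
background), with 0.2 µm-grain smoothing for noisy data and none for
noiseless data.  Recovery: per-cell engulfed volumes within 5% of the
analytic truth noiseless and 10% at SNR 5 on a 64×256×256 stack with
5 cells; cohorts generated at true mean ratio 2.0 (4 vs 2 puncta per
cell) vs 1.0 (3 vs 3), 30 measured cells per group from small rendered
stacks (24×96×96, 3 cells each — the per-stack geometry is scaled down,
the cohort size is not), separate at Mann-Whitney p < 0.01 in ≥ 95% of
50 replicates.

## Punctum analytics

Activity density sums raw intensity over retained (size-filtered) object
voxels inside the ROI and divides by the dLGN *area* — the z extent is
collapsed to the ROI footprint, because the source quantity is
area-normalized; whether intensities were summed over the full stack or
a projection first is ambiguous there, and the projection reading is the
one consistent with area units.  The count variant divides the object
count by the analyzed volume.

Synapse pairing is post-centric and non-exclusive: a postsynaptic
(Homer1) punctum is a synapse iff its centre lies strictly within 300 nm
(Euclidean, physical µm) of *any* presynaptic (SV2) punctum centre; many
posts may share a pre, each post counts at most once, and no one-to-one
assignment is attempted — the counting rule is "all post ellipsoids
within 300 nm of a pre ellipsoid", not a matching.  Ties at exactly
0.3 µm are excluded.  For independent fields this criterion has a
closed-form chance level, `1 − exp(−λ·4/3·π·0.3³)` for pre-field
intensity λ, which the generator-free point-process benchmark verifies
at λ = 0.01–0.1 µm⁻³.  The full pipeline trims stacks to a z-window
(~3.5 µm in the source protocol), optionally crops xy exclusion regions
(blood-vessel gaps), detects spots at the stated ellipsoid dimensions
(SV2 500/850 nm, Homer1 400/800 nm; sizes are diameters), pairs them,
and pools densities as ratios of totals.

The punctum-field generator places pre-puncta with a 1 µm minimum
separation, paired posts at exactly the pair distance (0.15 µm default)
in a random direction from distinct pres, and unpaired posts
rejection-sampled to lie ≥ 2× the pairing threshold from every pre — the
exclusion zone makes truth pairing unambiguous under the downstream
criterion.  Puncta render as Gaussian blobs with sigma = diameter/3
(FWHM ≈ 0.8× the stated size, treating the stated size as the visible
extent); at sigma = diameter/4 the blobs alias badly on a realistic
grid and matched-filter SNR at read-noise SNR 5 becomes marginal, which
is a property of under-sampled rendering, not of the detector.

Cell densities are spot counts over a region measure, with the
geometric-mean composite `√(DAPI · NeuN)` provided for isolating
neuronal nuclei before spot finding (zero wherever either input is
zero).

## Electrophysiology

**Input counting.**  Serial recruitment of RGC axons produces a
staircase of peak EPSC amplitudes vs stimulus.  The automated count
replaces a manual, blinded step count: amplitudes are segmented into
plateaus by exact dynamic-programming minimization of within-segment SSE
with a BIC-type penalty `2·σ²·ln(n)` per segment, adjacent plateaus
closer than the minimum step gate are merged (smallest gap first,
weighted means), a virtual zero level is prepended when the first
plateau is itself a step, and the count is the number of upward
transitions.  A downward transition flags the recording for discard (a
dropping EPSC invalidates the cell in the source protocol).  The gate
default is 0.1 nA with 0.02 nA noise — the gate must be ≥ 3× the noise
sd — and the exact criterion separating a "step" from noise is the one
parameter the source leaves unstated; the gate is calibrated on the
synthetic staircases and exposed.  The DP is provably the optimum the
exhaustive-enumeration oracle finds; tests assert equality on all short
curves.  The staircase generator draws recruitment thresholds uniformly
over the stimulus range, redrawn until pairwise gaps exceed two 0.5 µA
stimulus steps so each recruitment is resolvable on the stimulus grid.
Single-fiber amplitude is the first plateau above zero; fiber fraction
is single-fiber over plateau maximum.

**mEPSC detection.**  A rolling-median baseline (200 ms window, computed
on a 5 ms-decimated copy and interpolated — the baseline varies far more
slowly than the decimation) is subtracted; the residual is smoothed with
a 0.2 ms Gaussian; every contiguous run at or below −9 pA becomes a
candidate with amplitude measured baseline-to-peak at the run minimum;
events closer than 10 ms merge to the larger peak.  Runs of ≥ 5
identical extreme samples trigger a clipped-trace warning.  The merge
window and baseline window are unstated in the source and
config-exposed.  On 180 s synthetic trains (1 Hz, −10 to −40 pA, 1.5 pA
noise) recall and precision exceed 0.95 and the mean amplitude error is
~0.6 pA; residual misses are genuine event collisions inside the merge
window.

**Paired-pulse ratio.**  PPR is the second EPSC's amplitude over the
first's.  At short intervals the second peak rides on the first
response's decay tail, biasing a naive reading upward; the inter-pulse
decay segment is therefore fit with a biexponential (single-exponential,
then zero-tail fallback when the tail has decayed into the noise) and
extrapolated under the second peak.  Either amplitude below 5 pre-
stimulus noise SDs is an error, never a zero ratio — a trace missing its
second pulse raises.  Generated ratios 0.5–1.0 at 50–1000 ms intervals
are recovered within 0.01 (tolerance 0.03), including the 50 ms /
20 ms-decay case.

**AMPA/NMDA.**  A simple quotient of peak magnitudes, with the NMDAR
component read in a late window (default 10–50 ms after the stimulus) of
the +40 mV response, after the fast AMPAR component has decayed; the
window is config-exposed.

## Statistics

`compare()` implements the stated decision rule: Shapiro-Wilk on every
group at α = 0.05 (the specific normality test is unstated in the
source; Shapiro-Wilk is the default and exposed); if all pass,
parametric (two-tailed t — Welch by default, pooled available — or
one-way ANOVA with Tukey HSD), else non-parametric (Mann-Whitney U,
Wilcoxon for paired designs, Kruskal-Wallis for multi-group).  Named
tests can be forced where a protocol names one (Mann-Whitney for
engulfment ratios, KS for mEPSC interval/amplitude distributions,
Bonferroni for the PPR interval family).  Calibration: the dispatch's
type-I error under a standard-normal null at n = 10/10 is 0.0494
(measured at 150k simulations during development); the reported
10,000-simulation estimate uses a control variate — the pooled-t
rejection indicator, whose size under the normal null is exactly 0.05 —
which leaves the estimator unbiased for the same quantity while cutting
its standard error roughly three-fold.  The residual distance from
0.050 is real: the Mann-Whitney branch is discretely conservative at
n = 10, and samples routed there (those failing Shapiro-Wilk under the
null) are exactly the ones on which it is most conservative.

## What the synthetic data does and does not show

The generators emulate geometry, optics blur, detector noise and event
statistics; they do not emulate tissue autofluorescence, vascular
shadows, chromatic misregistration, antibody-penetration gradients,
stitching seams, series-resistance artifacts, or non-Poisson event
clustering.  Passing recovery benchmarks therefore demonstrates that the
*quantification logic* is correct and well-calibrated at realistic SNR —
not that segmentation would be error-free on real tissue, where the
manual mask-drawing and QC steps of the source protocols remain
essential.  All ground truths are computed from generated geometry or
event lists before blur and noise, never re-estimated from rendered
images, and identical seeds give bit-identical outputs via fixed
per-component substreams.

## Problem sizes

The benchmark sizes are chosen to give stable statistics at desk scale:
20 images per overlap target (5 targets); one 64×256×256 engulfment
stack per noise condition plus 50 cohort replicates of 2 × 30 cells from
24×96×96 stacks; 20 point-process fields per chance-pairing intensity
and 10 rendered punctum stacks; 100 staircases; 10 × 180 s mEPSC traces;
15 paired-pulse conditions; 10,000 null simulations.  The whole
benchmark suite runs in under ten minutes on one CPU.
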