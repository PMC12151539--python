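# synquant

Quantification pipeline for studying activity-dependent synapse
elimination in the developing mouse visual pathway — and for anyone who
needs the same measurements on their own imaging or slice-physiology
data.  During the first postnatal weeks, retinal ganglion cell (RGC)
inputs to the dorsal lateral geniculate nucleus (dLGN) are pruned:
eye-specific territories segregate, microglia engulf weakened synapses,
and each relay neuron ends up with a handful of strong inputs.
`synquant` implements the standard quantitative readouts of that
process as a tested, scriptable Python library, together with seeded
synthetic-data generators that provide exact ground truth for every
stage.

## What it measures

**Eye-specific segregation.**  From two-channel tracer images
(contra/ipsilateral CTB), percentage overlap under a rising threshold
sweep: after background subtraction and per-channel normalization to
[0, 1], a pixel is *real* in a channel when its value ≥ t, and

&nbsp;&nbsp;&nbsp;&nbsp;overlap(t) = 100 · Σ|pixels real in both| / Σ|dLGN pixels|,

pooled over an animal's sections as a ratio of totals and swept over
t ∈ {0.1, 0.125, …, 0.25} (plus an Otsu-binarized territory rendering).

**Glial engulfment.**  From 3D stacks of labeled microglia/astrocytes
with eye-specific tracer channels: per-cell engulfed tracer volume
(tracer-mask voxels on the cell label × voxel volume), its
cell-volume-normalized form, the per-cell right/left engulfment ratio
R = V_right / V_left (zero denominators censored, not pseudocounted),
and CD68 activation metrics.

**Synapse counting.**  Anisotropic Laplacian-of-Gaussian ellipsoid spot
detection (SV2 500/850 nm, Homer1 400/800 nm defaults); a synapse is a
postsynaptic punctum whose centre lies strictly within 300 nm of any
presynaptic punctum centre; density is pairs per analyzed µm³.  Chance
colocalization follows 1 − exp(−λ·4/3·π·0.3³) for independent fields,
which the tests verify.  Activity-stain density (summed object
intensity / dLGN area, with a 10–2000-voxel object filter) and cell
densities (RGC, NeuN/DAPI geometric-mean composite) use the same
primitives.

**Retinogeniculate physiology.**  EPSC staircase input counting by
exact penalized change-point segmentation (automating the manual step
count), −9 pA threshold mEPSC detection on rolling-median-baselined
traces, paired-pulse ratio with biexponential tail subtraction, fiber
fraction and AMPA/NMDA ratios.

**Statistics.**  The protocols' decision rule: Shapiro-Wilk normality
per group, then t/ANOVA+Tukey or Mann-Whitney/Kruskal-Wallis, with KS
and Bonferroni where named; calibrated to nominal size (see
`docs/methods.md`).

## Worked example

Recover a known territory overlap from a rendered image pair:

```bash
python analysis/01_segregation_overlap.py --seed 0
```

```
Recovery over 100 images (targets 0/10/30/60/100% overlap):
 target_overlap_pct  mean_abs_error_pct
                0.0            1.457285
               10.0            1.478852
               30.0            1.246405
               60.0            1.124191
              100.0            0.000000
mean |error| = 1.06 percentage points; 100% of profiles monotone non-increasing in threshold
Example profile (target 30%):
  threshold 0.100:  32.1% overlap
  threshold 0.125:  31.4% overlap
  ...
  threshold 0.250:  30.3% overlap
```

The per-threshold profile is the quantity plotted in a segregation
analysis: a well-segregated dLGN gives a profile that collapses toward
zero as the cutoff rises, while genuine overlap (here, a simulated 30%)
stays flat across the sweep — the generated truth is recovered within
about one percentage point, and the slight elevation at low cutoffs is
boundary blur, exactly the artifact the rising sweep is designed to
discount.

The same pattern holds for the other pipelines, e.g.:

```bash
python analysis/04_input_counting.py --seed 0
# 100 staircases, 1-10 inputs: exact count in 100%, off-by-one in 0%, worse in 0%
# Example cell: true inputs 4, counted 4; plateau 1.57 nA, single fiber 0.70 nA,
#   fiber fraction 0.45 (truth 0.45)

python analysis/05_mepsc_detection.py --seed 0
# 10 x 180 s traces at 20 kHz: recall 0.988, precision 1.000,
#   mean |amplitude error| 0.62 pA; events above -9 pA reported: 0
```

Library use mirrors the scripts:

```python
from synquant import segregation, synthio

image, truth = synthio.gen_territory_image(overlap_target=0.3, seed=1)
profile = segregation.overlap_profile([segregation.normalize_channels(image)])
print(profile.as_dict())   # {0.1: 32.3, ..., 0.25: 30.4}
```

## Repository layout

- `src/synquant/` — the library: `imgseg` (segmentation primitives),
  `segregation`, `engulfment`, `puncta`, `ephys`, `stats`, `synthio`
  (ground-truth generators), `benchmarks` (recovery studies), `io`.
- `analysis/01…07_*.py` — numbered drivers, one per analysis; each
  prints what it found and writes its tables under `results/`.
- `tests/` — unit, property and end-to-end recovery tests, with
  independent brute-force oracles (exhaustive Otsu sweep, BFS flood
  fill, enumerated change-point segmentation, ECDF sweep).
- `docs/methods.md` — models, defaults, numerical choices, limitations.

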