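# Methods

## Problem and pipeline

In autosomal dominant polycystic kidney disease (ADPKD), total kidney
volume (TKV) — the number of kidney voxels times the physical voxel
volume — is the principal imaging biomarker of progression. Measuring it
requires segmenting two grossly enlarged, cyst-filled kidneys in
T2-weighted abdominal MR, a task made hard by irregular organ shapes,
variable border contrast, and bright liver cysts that must not be counted
as kidney.

`pkdseg` implements a fully automated pipeline for this task:

1. **Voxel classification.** A 2-D encoder-decoder convolutional network
   with skip connections maps each axial slice to a per-voxel kidney
   probability. Each resolution level is a block of same-padded 3×3
   convolutions (ReLU) followed by dropout; 2×2 max pooling halves
   resolution while filter counts double, 2×2 nearest-neighbour
   upsampling mirrors the descent, and encoder features are concatenated
   into the decoder at every level. The head is a 1×1 convolution with a
   sigmoid, so outputs are probabilities. Input height/width must be
   divisible by 2^depth.
2. **Artificial multi-observer ensemble.** K networks (K odd) are trained
   on different random subsets of the cases, each with its own 80/20
   train/validation split. At inference each member's probability map is
   binarized at 0.5 and the K binary opinions are fused per voxel by
   strict majority (≥ ⌊K/2⌋+1 votes). Averaging probabilities before
   thresholding is available (`vote_on_probabilities`) but off by
   default: the voting metaphor treats members as independent observers.
3. **Post-processing.** The voted mask is reduced to its two largest
   3-D connected components (26-neighbourhood by default), then the
   borders are refined with a morphological geodesic active contour
   (edge-attracted, no balloon force) initialized from the mask.
4. **Evaluation.** Voxel-overlap metrics (Dice, Jaccard, sensitivity,
   specificity, precision), slice-wise border distance (D_mean), TKV in
   ml, signed percent TKV error, Bland-Altman limits of agreement, and
   cohort summaries in `m ± SD [min/max]` form.

## Training

The loss is `1 − soft_dice`, where
`soft_dice = (2·Σ p·t + s) / (Σ p + Σ t + s)` with smoothing `s = 1`
during optimization; the monitored validation score uses `s = 1e-6`
aggregated over all validation voxels. Making the optimized and monitored
quantities coincide avoids a surrogate-loss mismatch; on binary inputs the
soft score reduces to the confusion-count Dice `2TP/(2TP+FP+FN)`.

Optimization uses Adam with learning rate 2e-3 and batch size 4 (slices).
These defaults were set by a small convergence probe on a clean
(noiseless, high-contrast) phantom task, where they reach validation Dice
≥ 0.99 in 20 epochs; larger batches and smaller rates converged several
times slower at this problem size. Epochs default to 100 at full scale;
the desk-scale experiment uses 20. Dropout (0.35) is active only in
training mode. Volumes are z-score normalized per volume before slicing;
this is configurable but on by default since phantom (and MR) intensity
scales are arbitrary.

Weights are checkpointed at the epoch with the best validation soft-Dice;
ties resolve to the earliest epoch for determinism. The returned member
carries the checkpointed weights, and re-evaluating them on the stored
validation cases reproduces the recorded best score.

The network engine itself is a compact NumPy implementation (im2col
convolution via BLAS, hand-derived backward passes, Adam); every backward
pass is validated against central finite differences in float64 in the
test suite (worst relative error ~1e-6).

## Ensemble member subsets

How the original multi-observer design distributed cases across members
is an open choice; we draw, per member, a random 80% of the training pool
without replacement, seeded by (run seed, member index). Bootstrap-style
draws would be a one-line change; we kept the simpler reading. Member
seeds derive from the run seed through `numpy` `SeedSequence`, so the
entire K-member training is reproducible from one integer.

## Synthetic phantoms

The generator emulates the structural properties the segmentation task
assumes, on a configurable grid (default 64×64×8 voxels at
1.5×1.5×3.0 mm — the in-plane resolution and slice thickness typical of
the clinical acquisitions this pipeline targets; 256×256×Z is supported):

- **Kidneys**: two ellipsoids with a smooth low-order radial perturbation
  (direction-harmonic terms, amplitude 15%, coefficients normalized so the
  perturbed surface always lies between the (1±0.15)-scaled ellipsoids).
  Semi-axes are drawn from 9–16 mm, positions anchored left/right with
  jitter; overlap triggers bounded retries, then an explicit generation
  error.
- **Cysts**: 2–6 bright spheres per kidney (radius 1.5–4 mm), centres
  drawn well inside the parent so every cyst voxel is kidney in the
  reference mask. Cyst intensity 100 vs parenchyma 60 vs background 20
  (arbitrary units, T2-like ordering).
- **Border contrast jitter**: per-kidney intensity scaled by ±20%.
- **Liver confounder**: with probability 0.5, a liver-like region
  (intermediate intensity, its own bright cysts) is placed away from the
  kidneys; it contributes nothing to the reference mask, so a correct
  segmenter must learn to ignore bright cysts outside kidneys.
- **Bias field**: multiplicative 1 + a·P(x,y,z) with P a random
  second-order polynomial normalized to unit sup, a = 0.2 — a cheap
  surrogate for MR coil shading.
- **Noise**: additive Gaussian, SD 4 (≈10% of the kidney-background
  contrast). Real magnitude MR noise is Rician; at these SNRs the
  difference is modest and we accept the simplification.

What passing tests on phantoms does **not** show: robustness to real MR
artifacts (banding, motion, wrap-around), to anatomical variability
beyond perturbed ellipsoids, to inter-scanner contrast differences, or to
the renal-pelvis ambiguity that troubles human readers. Phantom results
validate the pipeline's mechanics, not clinical performance.

## Post-processing choices

Connected-component analysis uses 26-connectivity by default
(configurable to 6). The active contour evolves **slice-wise in 2-D**:
with 3 mm slices against 1.5 mm in-plane voxels, 3-D curvature smoothing
erodes the mask along z far faster than in-plane and overshot the true
border on a sharp-border fixture (Dice 0.87 with 3-D evolution vs 0.97 slice-wise);
2-D evolution also matches the slice-wise network. The speed image is the
inverse Gaussian gradient (α=50, σ=1) of the min-max-normalized volume;
5 iterations, smoothing 1, no balloon. A guard rail returns the input
mask unchanged (with a logged warning) if refinement would change the
volume by more than 5% — post-processing is meant to finalize, not
overturn, the network's segmentation.

## Evaluation conventions

- `D_mean`: per axial slice where both masks have foreground, the
  symmetrized maximum border-to-border distance (slice Hausdorff, mm
  in-plane), averaged over those slices. "Average maximum border
  distance" admits several readings; this slice-wise one matches 2-D
  planimetry practice, and mean symmetric surface distance is emitted as
  a secondary column. Slices where only one mask is present are skipped
  (the directed distance is undefined there); an empty mask yields NaN.
- Cohort summaries use the sample SD (n−1); Bland-Altman limits are
  mean ± 1.96·SD of the signed percent TKV differences.
- Metrics with zero denominators surface as NaN in reports, never as 0.

## Desk-scale experiment

The pinned experiment (acceptance tests and `scripts/acceptance.py`)
uses 60 phantoms, 40 for training and 20 held out, K=3 members, a
depth-2/8-filter network, and 20 epochs per member — sizes chosen so the
whole pipeline, training included, runs on one CPU core in minutes while
still exercising every stage at full fidelity. Scaled-up runs (K=11,
depth 4, 100 epochs, 256×256×Z) use the same code path via the CLI
config.

## Known limitations

- 2-D slice-wise processing ignores through-plane context; a voxel's
  probability never sees neighbouring slices.
- The NumPy engine is single-threaded except for BLAS matmuls; it is
  sized for desk-scale experiments, not clinical-cohort training.
- Left/right kidneys are not labelled separately; the two largest
  components are kept jointly.
- Phantom realism limits are listed above; no claim transfers to
  patient data without retraining and revalidation.
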