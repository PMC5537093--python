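# pkdseg

Fully automated segmentation of polycystic kidneys with an artificial
multi-observer neural-network ensemble, plus total-kidney-volume (TKV)
evaluation — exercisable end to end on synthetic ADPKD-like phantom
volumes.

## The problem

In autosomal dominant polycystic kidney disease (ADPKD), kidneys grow
from ~200 ml to several litres as fluid-filled cysts proliferate. TKV is
the standard imaging biomarker of progression, and measuring it requires
segmenting both kidneys in T2-weighted abdominal MR — slow to do by hand
(manual planimetry takes 45–90 minutes per examination) and hard to
automate: organ shapes are highly irregular, border contrast varies with
tissue composition, and bright liver cysts sit right next to kidney
cysts yet must not be counted.

## The method

`pkdseg` segments each axial slice with an encoder-decoder convolutional
network with skip connections (U-Net family): 3×3 convolutions + ReLU +
dropout per level, 2×2 max pooling down, 2×2 upsampling back up, encoder
features concatenated into the decoder at each resolution, and a 1×1
sigmoid head giving per-voxel kidney probabilities p(x) ∈ (0,1).
Training minimizes 1 − softDice, with

    softDice = (2·Σ p·t + s) / (Σ p + Σ t + s),

which reduces to Dice = 2TP/(2TP + FP + FN) on binary inputs.

To emulate a panel of observers, K networks (K odd, default 3 at desk
scale, 11 at full scale) are trained on different random subsets of the
cases, each with its own 80/20 train/validation split and
best-validation-Dice checkpointing. At inference each member's
probability map is binarized at 0.5 and the K opinions are fused per
voxel by strict majority voting (≥ ⌊K/2⌋+1 votes). The voted mask is
cleaned by keeping its two largest 3-D connected components (left and
right kidney) and refining borders with an edge-attracted morphological
geodesic active contour. Agreement with reference masks is reported as
Dice/Jaccard/sensitivity/specificity/precision, slice-wise border
distance D_mean, TKV percent error, and Bland-Altman limits
mean ± 1.96·SD.

Because clinical ADPKD MR with reference segmentations is not publicly
distributable, the package ships a phantom generator producing
image/mask pairs with the task's structural challenges: perturbed
ellipsoidal kidneys containing brighter cysts, variable border contrast,
an optional cyst-bearing liver confounder, polynomial bias field, and
noise. The whole pipeline — generation, training, voting,
post-processing, evaluation — runs on these phantoms in minutes on one
CPU. The network engine is a self-contained, gradient-checked NumPy
implementation; no GPU or deep-learning framework is required.

## Worked example

```python
from pkdseg.experiments import run_desk_scale_experiment

res = run_desk_scale_experiment(seed=1, progress=True)
print(res.cohort.formatted())
```

prints (seed 1; reproduced exactly on rerun):

```
member 0: best val Dice 0.9998 at epoch 18
member 1: best val Dice 0.9962 at epoch 19
member 2: best val Dice 0.9275 at epoch 18
dice             0.99 ± 0.01 [0.97/1.00]
jaccard          0.98 ± 0.02 [0.95/1.00]
sensitivity      0.98 ± 0.02 [0.95/1.00]
specificity      1.00 ± 0.00 [1.00/1.00]
precision        1.00 ± 0.00 [1.00/1.00]
d_mean_mm        1.00 ± 0.71 [0.00/1.81]
mssd_mm          0.16 ± 0.16 [0.00/0.48]
pct_diff       -1.98 ± 2.00 [-4.94/0.22]
```

Read: on 20 held-out phantom cases the voted, post-processed
segmentations overlap the reference masks with mean Dice 0.99; TKV is
recovered with a mean signed error of −2.0% (SD 2.0%). The voted
ensemble's percent-error SD (2.00) is smaller than the worst single
member's (2.98) — the variance reduction that motivates the
multi-observer design (note member 2, the weak observer with validation
Dice 0.93, is outvoted wherever the other two agree).

The same pipeline is scriptable stage by stage:

```bash
pkdseg generate --config run.yaml --out data/
pkdseg train    --config run.yaml --manifest data/manifest_train.csv --out model/
pkdseg segment  --config run.yaml --model model/ --image data/case_059_img.nii.gz --out segs/
pkdseg evaluate --pairs pairs.csv --out eval/
```

with one YAML config (sections `phantom`, `network`, `training`,
`ensemble`, `postprocess`) driving all stages from a single seed.

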