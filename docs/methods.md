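# Methods

## The model

`clavibmd` implements an explainable multi-task convolutional model that
predicts areal bone-mineral density (BMD, g/cm²) from a single
chest-radiograph-like image while simultaneously segmenting the clavicles.
The backbone is a depth-4 U-Net: four encoder stages of
(3×3 conv → batch norm → ReLU) × `convs_per_stage` followed by 2×2
max-pooling, a bottleneck block at 1/16 resolution, and (in multi-task
mode) a symmetric decoder with 2×2 nearest-neighbour up-sampling,
channel-concatenated skip connections, and a 1×1 conv + sigmoid
segmentation head. The regression branch reads the bottleneck feature maps
through global average pooling and a single linear unit, producing BMD in
raw g/cm².

The training objective mixes the two tasks linearly,

    L_intg = λ · L_seg + (1 − λ) · L_reg ,

with `L_seg` a soft Dice loss (per image, batch-averaged, smoothing
ε = 1e−6 for the empty-mask edge case) and `L_reg` the mean squared error
of the BMD prediction. λ defaults to 0.8 and can be selected over the grid
{0.5, …, 0.9} by the validation heatmap-overlap rate. The single-task
comparison model is the encoder + regression branch trained with `L_reg`
alone; built with the same seed it starts from bitwise-identical
encoder/regression weights, so any difference in behaviour is attributable
to the segmentation task.

The segmentation task functions as an attention prior: it forces the shared
encoder to represent clavicle shape and cortical thickness, which the
regression branch can then exploit. Explainability is probed with
regression Grad-CAM: channel weights α_k are the spatial means of the exact
backpropagated gradients ∂BMD_pred/∂A^k at the final encoder convolution,
the heatmap is ReLU(Σ_k α_k A^k) bilinearly up-sampled to the input size,
and a case counts as "overlapping" when the pixels above 50 % of the
heatmap maximum share at least one pixel with the ground-truth clavicle
mask (a stricter area-fraction variant is also exposed). The 50 % threshold
uses a strict inequality; an exactly uniform positive heatmap would then
highlight nothing, so that degenerate case highlights every pixel instead,
and an all-zero heatmap counts as no overlap.

All layers, the backward passes, and the Adam optimizer are implemented
directly on NumPy (`clavibmd.nn`): convolutions via im2col + BLAS matmul,
float32 by default with float64 available for gradient checking. The full
backward pass is verified against central finite differences in the test
suite.

## The phantom generator

Patient radiographs cannot be redistributed, so the package ships a
synthetic phantom cohort generator that preserves the statistical and
causal structure the method needs:

* **Demographics.** Exactly `round(n × female_fraction)` females
  (default 69.5 %); ages N(63.3, 14.6²) clipped to [20, 91] years (used
  only in the manifest — the model sees the image alone).
* **Latent BMD.** Sex-specific normals, female N(0.860, 0.180²) and male
  N(0.985, 0.175²) g/cm², moment-matched so the default mixture reproduces
  the pooled 0.898 ± 0.188 g/cm² of the reference population; clipped to
  (0.2, 1.6) g/cm².
* **Anatomy.** Two mirrored S-curved clavicle bars at ~30 % image height
  whose half-thickness (0.018–0.048 of the image side) and in-mask
  intensity increase strictly with BMD; a brighter cortical rim occupies
  the outer 40 % of the thickness. Per-case jitter perturbs vertical
  position, curvature, and left/right symmetry. The ground-truth mask is
  the union of the bars; at the default geometry it covers ~2–8 % of
  pixels.
* **Background.** A smooth thorax-like gradient with a mediastinal column
  and low-contrast rib bands, plus two deliberate non-clavicular cues:
  a BMD-*correlated* soft-tissue band in the lower torso (coupling 0.12
  per g/cm², corrupted by a per-case error of SD 0.10 g/cm² — soft tissue
  is only a noisy correlate of bone density) and a BMD-*independent*
  bright radiopaque marker in the upper-right corner. A per-case exposure
  gain N(1, 0.06²) emulates acquisition variability.
* **Noise.** Additive Gaussian noise (default SD 0.02 display units).

The intensity model is deliberately calibrated so that the cortical bone
signal is precise but *not* trivially linear in the global image mean
(bone intensity gain 0.10 across the BMD range, with most of the signal in
thickness), while the soft-tissue band is an easy, large-area, but noisy
shortcut. This reproduces the phenomenon the multi-task design targets:
a regression-only model gravitates to the background shortcut (its
Grad-CAM rarely touches the clavicles), whereas the segmentation-steered
model reads the clavicles and achieves a lower MAE. What passing tests on
phantoms do **not** show: robustness to projection geometry, scatter,
implants, vendor post-processing, or real anatomical variation — the
phantom has none of these.

The whole cohort is a pure function of `CohortParams` (including the
seed): demographics, BMD draws, ages, per-case render seeds, and noise all
derive from independent seeded streams.

## Protocol

The experimental protocol mirrors the clinical study design: ids are
shuffled and split into k = 5 near-equal test groups; for each fold the
remaining cases are divided 3:1 into training and validation (for
n = 1600, exactly 320/960/320 per fold). Augmentation — random shifts
(±10 % of the side), rotations (±10°), horizontal flips (p = 0.5),
re-sampled every epoch — is applied to the training set only. Adam
optimizes `L_intg` (multi-task) or `L_reg` (single-task); validation MAE
is monitored every epoch and the weights of the first epoch attaining the
minimum are kept. λ selection, when enabled, trains one candidate per grid
point on a fold's train split and picks the highest validation overlap
rate, ties toward the larger λ; test ids never influence weights,
checkpoint choice, or λ. The default `TrainConfig` carries the full-scale
protocol (learning rate 4e-5, batch 16, 60/30 epochs).

## Problem sizes and numerical choices

The NumPy backend on a single CPU core dictates the scale of the
end-to-end study the test suite runs: n = 400 phantom cases at 64×64 with
8 base filters, 5-fold cross-validation of both models, learning rate
2e-3, batch 16, and 8 (multi) / 4 (single) epochs — roughly a 1:4 cohort
and 1:16 image-area reduction of the full protocol, with the epoch budget
scaled to the faster convergence that the larger learning rate and the
cleaner phantom signal allow. Under these conditions the multi-task model
reaches pooled test Pearson R above 0.9 and mean Dice near 0.9, and its
heatmap overlap rate exceeds the single-task model's by a wide margin
(the recovery and explainability tests assert R > 0.8, Dice > 0.8, and
the strict ordering).

Other numerical choices: Dice smoothing ε = 1e−6; evaluation Dice
binarizes the soft map at 0.5 (sigmoid midpoint); LOWESS uses fraction 0.3
with 3 robustifying iterations and is evaluated at the distinct observed
BMD values; Bland–Altman limits use the n−1 sample SD and ±1.96; the
model comparison applies Shapiro–Wilk to the paired differences (the
quantity the paired test assumes) and falls back to a paired t-test when
normality is not rejected; macro metrics are unweighted class means, with
empty-class cells reported as NaN and excluded with a warning. WHO classes
follow the boundary-inclusive rules (T ≤ −2.5 osteoporosis; T ≥ −1.0
normal) with reference values YAM/SD = 1.024/0.131 (male) and 1.010/0.119
(female) g/cm². Radiograph preprocessing scales the longer side to the
target, zero-pads the shorter side symmetrically, and normalizes by the
12-bit full scale 4095.

## Design decisions on open points

* Filter widths double per stage (f, 2f, 4f, 8f, bottleneck 16f);
  convolutions per stage default to 2; both configurable.
* Batch-norm order defaults to conv → BN → ReLU with a switch for
  conv → ReLU → BN.
* Up-sampling is nearest-neighbour + conv (not transposed convolution);
  skips are channel concatenations.
* λ selection is performed once on fold 1's train/validation split and
  reused across folds, recorded in the run manifest.
* The Grad-CAM layer for the single-task model is likewise the final
  encoder convolution, so the two models' heatmaps are directly
  comparable.
* Checkpoints are .npz weight archives with a JSON architecture sidecar;
  all CSV/JSON writes are atomic (temp-then-rename).

## Known limitations

* The phantom is a statistical stand-in, not a physical x-ray simulation
  (no beam hardening, scatter, grids, or DICOM semantics).
* Parameter parity with the original clinical network cannot be verified
  (its channel widths are unreported); conclusions here are about the
  method, not about reproducing the clinical error figures, which require
  the private patient cohort.
* Grad-CAM at the bottleneck has a spatial resolution of input/16 per
  side; at 64×64 the 4×4 grid makes the overlap metric coarse, which is
  why the phantom places the clavicles and the confounders in distinct
  grid cells.
* Regression Grad-CAM is sign-ambiguous (a feature may lower the
  prediction); the overlap metric only scores the positive evidence.
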