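# clavibmd

Explainable multi-task deep learning for estimating bone-mineral density
(BMD) from chest-radiograph-like images, using the clavicles as the
anatomically meaningful signal — together with a synthetic phantom cohort
generator so the whole pipeline runs and is tested without any patient
data.

## The problem

Osteoporosis screening relies on dual-energy x-ray absorptiometry (DXA),
which is not widely deployed; chest radiographs are ubiquitous. A
convolutional regressor can predict lumbar BMD (g/cm²) from a chest film,
but a clinically trustworthy model should base that prediction on bone —
not on soft tissue, markers, or other shortcuts. `clavibmd` implements a
multi-task U-Net whose encoder is shared between

* a **clavicle segmentation** task (decoder + 1×1 conv + sigmoid), and
* a **BMD regression** branch (global average pooling + one linear unit)

trained with the combined loss

```
L_intg = λ·L_seg + (1−λ)·L_reg ,      λ = 0.8 by default,
```

where `L_seg` is a soft Dice loss and `L_reg` the mean squared error. The
segmentation task acts as an attention prior that steers the shared
features toward the clavicles. A single-task comparison model (encoder +
regression only, same initialization) isolates the effect. Explainability
is quantified with regression Grad-CAM: α_k = spatial mean of
∂BMD_pred/∂A^k over the final encoder feature maps, heatmap
L = ReLU(Σ_k α_k A^k), thresholded at 50 % of its maximum and scored for
overlap with the clavicle mask. The evaluation stack covers MAE, Pearson
R, Dice, Bland–Altman agreement, LOWESS error trends, T-score conversion
(T = (BMD − YAM)/SD with sex-specific references), WHO three-class
reclassification with macro metrics, and a Shapiro–Wilk-gated Wilcoxon
signed-rank model comparison.

Everything — layers, backward passes, Adam — is implemented on NumPy; no
deep-learning framework is required.

## Worked example

Generate a cohort, train the multi-task model on one cross-validation
fold, and evaluate (`examples/train_multitask_model.py`; ~1 min on a
laptop CPU):

```
$ python examples/train_multitask_model.py
epoch  L_seg   L_reg   L_intg  val_MAE
    0  0.883   0.8041  0.867   0.5433
    1  0.830   0.0975  0.684   0.1826
    ...
    4  0.765   0.0315  0.618   0.0974
    5  0.745   0.0150  0.599   0.2508
selected epoch (lowest validation MAE): 4
test MAE: 0.1043 g/cm²   Pearson R: 0.744   Dice: 0.770
```

The combined loss falls as both tasks are learned; held-out cases show the
regression branch recovering the latent BMD (R) and the decoder
reproducing the clavicle mask (Dice). Clinical-style evaluation of a
predictions table (`examples/tscore_reclassification.py`):

```
MAE: 0.067 g/cm²,  R: 0.913
Bland–Altman bias -0.014, limits of agreement [-0.179, +0.150] g/cm²
female BMD at T = -2.5: 0.713 g/cm²
female BMD at T = -1.0: 0.891 g/cm²
macro: {'sensitivity': 0.796, 'specificity': 0.891, 'precision': 0.77, 'f1': 0.781}
```

The two printed BMD values are the osteoporosis (T = −2.5) and osteopenia
(T = −1.0) boundaries implied by the female reference values
(YAM 1.010, SD 0.119 g/cm²). `examples/explain_with_gradcam.py` prints a
trained model's Grad-CAM channel weights, its low-resolution heatmap, and
the per-cohort clavicle-overlap rate; `examples/generate_phantom_cohort.py`
shows the cohort calibration (69.5 % female, BMD ≈ 0.898 ± 0.188 g/cm²).

## Command line

A thin CLI wraps the library:

```
clavibmd phantom  --n 400 --size 64 --seed 1 --out cohort/
clavibmd crossval --config cfg.yaml --manifest cohort/manifest.csv --out run/
clavibmd explain  --checkpoint run/checkpoint.npz --manifest cohort/manifest.csv --out xai/
clavibmd evaluate --predictions run/predictions.csv --out eval/
clavibmd compare  runA/predictions.csv runB/predictions.csv --out cmp/
```

Every output directory receives a `run_manifest.json` with the seeds and
fold id lists needed to reproduce the run.

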