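# scintigrade

Automated detection and Perugini grading of cardiac tracer uptake on 2D
bone scintigraphy with compact convolutional neural networks.

Transthyretin amyloidosis (ATTR) binds bone-avid [99mTc] tracers, so it
appears as incidental myocardial uptake on routine bone scans. Uptake is
graded on the Perugini scale relative to bone signal (0 none, 1 < bone,
2 ~ bone, 3 > bone; grade >= 2 positive). `scintigrade` implements the full
analysis pipeline for screening such scans:

* **Phantoms** — a seeded generator of synthetic whole-body and planar
  thoracic scans whose cardiac-to-bone intensity ratio encodes the grade,
  with Poisson counting noise, hot spots and bone metastases, so every
  stage is testable without clinical data.
* **Preprocessing** — anterior-view selection; automatic 128 x 128 thoracic
  cropping (window top at 0.85 x patient height measured from the lowest
  nonzero row, columns +/-64 around the image centre); `ln(1 + x)` count
  transform; pixel-wise z-scoring against training-fold statistics.
* **Models** — two compact custom CNNs sharing one topology (a stem
  convolution plus four blocks of six 3x3 ReLU convolutions with average
  pooling between blocks, then flatten -> dropout -> softmax): **Linear**
  (plain) and **Residual** (parameter-free skips into convolutions 2, 4, 6
  of each block). Both count exactly 1,112,644 trainable parameters under
  the default filter plan (stem 16, blocks 16/32/64/128) — ~1M versus the
  138M of canonical VGG16. Adapters for VGG16 / ResNet50 / InceptionV3 /
  MobileNet with a replaced head are included. Everything runs on a small
  NumPy NHWC engine (forward + backprop + Adam) written for this package.
* **Training & evaluation** — stratified 5-fold cross-validation,
  randomized shift/rotation/zoom augmentation, inverse-frequency class
  weights `w_c = n/(k n_c)`, Adam with a reduce-on-plateau schedule, and
  pooled out-of-fold ROC-AUC / accuracy / per-class precision-recall for
  three tasks: four-class grading, positive detection (grade >= 2) and
  high-grade detection (grade 3), plus a bone-metastasis subgroup report.
* **Interpretability** — maximum-activation maps (channel-wise maxima of a
  layer's post-ReLU features, upsampled to input scale) for the four
  block-entry convolutions, and a quantitative cardiac-focus score.

See `docs/methods.md` for the model details, parameter tables and design
rationale.

## Worked example

```python
import scintigrade as sg

# 60 phantoms, uniform grades, seeded
studies = sg.generate_dataset(60, (0.25, 0.25, 0.25, 0.25), seed=7)
images = sg.preprocess_studies(studies)          # AP-only, crop, log

spec = sg.ModelSpec(family="residual", stem_filters=4,
                    block_filters=(4, 8, 12, 16))
cfg = sg.TrainConfig(epochs=5, batch_size=8, initial_lr=1e-3,
                     lr_factor=0.5, scaled_init=True, head_init_steps=500,
                     average_tail_fraction=0.34, snapshot_ensemble=3)
result = sg.run_cross_validation(
    images, spec, task="four_class",
    aug_cfg=sg.AugmentationConfig(multiplier=0), train_cfg=cfg, k=5, seed=7)
r = result.report
print(f"pooled macro-OVR AUC {r.auc:.3f}, accuracy {r.accuracy:.3f}")
print("grade-3 recall:", round(float(r.recall[3]), 3))
```

Output from this exact script:

```
pooled macro-OVR AUC 0.916, accuracy 0.833
grade-3 recall: 0.933
```

The pooled AUC is the macro-averaged one-vs-rest area under the ROC curve
over the out-of-fold predictions of all 60 studies; grade-3 recall is the
fraction of true grade-3 phantoms the model recovers (14 of 15 here). At
this deliberately tiny scale (48 training studies per fold, 5 epochs) the
skip-connected model already ranks the four grades well; the package's
full validation study (n=200, three seeds, both families) reaches pooled
AUC >= 0.95 (see `docs/methods.md`).

There is also a CLI for dataset generation and end-to-end runs:

```bash
scintigrade generate --n 200 --proportions 0.25,0.25,0.25,0.25 --seed 1 --out data/
scintigrade run --data data/ --models linear,residual \
    --tasks four_class,pos_vs_neg,grade3_vs_rest --folds 5 --seed 1 --out runs/
scintigrade visualize --checkpoint runs/checkpoints/residual_four_class_fold0.npz \
    --data data/ --out montage.png
```

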