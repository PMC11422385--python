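# fundusfocus

Lesion-focused analysis of retinal fundus photographs: a desk-scale,
fully-tested implementation of a two-stage diagnostic pipeline for the
common blinding eye diseases — glaucoma (GLAU), age-related macular
degeneration (AMD), retinal vein occlusion (RVO), diabetic retinopathy
(DR) — against normal fundus (NORM).

## The idea

End-to-end CNN classifiers trained on raw fundus photographs are easily
distracted by camera artefacts and exposure differences. This package
implements the *lesion-focused* alternative:

1. **Segment** anatomy and lesions with one binary U-Net per class
   (`Retina-Unet`: a five-stage decoder on a residual 18-layer encoder;
   256×256×3 in, 256×256×1 out).
2. **Pack** the resulting binary mask channels losslessly into a single
   RGBA PNG. Pixel bit *i* of channel ⌊i/8⌋ stores mask plane *i*:

   `I_R = Σ_{i=0..7} 2^i·mask_i`, `I_G = Σ_{i=8..15} 2^(i−8)·mask_i`, …

   and the inverse `mask_i = ⌊I_{⌊i/8⌋} / 2^(i mod 8)⌋ mod 2`. A
   512×512×32 stack that would occupy 32 MiB as raw float32 fits in a
   ~1 KB PNG when sparse.
3. **Compose** the classifier input by saturating the blue channel
   (B ← (B ∧ ¬L) ∨ L, i.e. B=255) at every selected mask pixel inside
   the camera's field of view, leaving red and green untouched — a
   hard attention map the classifier cannot ignore.
4. **Classify** with a nine-stage mobile-inverted-bottleneck network
   (MBConv blocks, expansion 1 or 6, swish activations); two-way
   early/late **grading** heads are fine-tuned from the trained
   diagnosis weights.
5. **Evaluate** with ROC curves, the Youden-index operating threshold
   (J = sensitivity + specificity − 1), micro/macro one-vs-rest AUROC,
   and a risk-stratification report: the cohort is split at the median
   risk score, and the high-vs-low odds ratio OR = ad/bc is reported
   with a Woolf interval, Byar-approximation Poisson CIs on event
   counts, bootstrap CIs on positive rates, and a Pearson χ² test.

Because no image data ships with the package, a seeded synthetic
generator renders fundus phantoms (field-of-view circle, optic disc and
cup, macula, vessels) with per-disease lesion signatures and paired
ground-truth masks, so every stage is exercisable offline.

All network training runs on a small numpy CNN engine included in the
package (`fundusfocus.nn`; im2col convolutions, manual backprop, Adam)
— deterministic for a given seed and dependency-free beyond numpy.

## Worked example

Run the full pipeline (simulate → segment → fuse → train → evaluate) on
an 80-patient synthetic cohort at 64 px:

```python
from fundusfocus.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(
    outdir="runs/demo", seed=7, n_patients=80, images_per_patient=3,
    image_size=64, segment=True, seg_epochs=12, seg_multiplier=0.125,
    cls_multiplier=0.25, cls_epochs=12, cls_learning_rate=3e-3,
    batch_size=8, patience=5, bootstrap_reps=500,
))
ev = report["stages"]["evaluate"]
print(ev["micro_auroc"], ev["macro_auroc"])
print(ev["per_disease"]["GLAU"])
```

This run (about 40 s on one CPU) prints:

```
0.9138454861111112 0.8981481481481481
{'auroc': 1.0, 'threshold': 0.292..., 'sensitivity': 1.0,
 'specificity': 1.0, 'accuracy': 1.0,
 'odds_ratio': 30.03..., 'or_ci': [1.63, 553.55], 'chi2_p': 0.00087}
```

meaning: on the held-out patients the diagnosis scores reach micro
AUROC 0.914 / macro 0.898 overall; glaucoma in particular is perfectly
separated (AUROC 1.0), and splitting the cohort at the median glaucoma
risk score puts essentially all glaucoma images into the high-risk
group (odds ratio ≈ 30, χ² p < 0.001). The segmentation stage reports
per-class train/validation IoU and the summary score
0.4·IoU_train + 0.6·IoU_val. Larger cohorts (see
`tests/test_acceptance.py`) push held-out macro AUROC above 0.95.

The same stages are scriptable from the shell:

```sh
fundusfocus simulate --n 20 --out cohort/
fundusfocus bitmap inspect cohort/masks/P00000_I0_masks.png
fundusfocus fuse --image img.png --bitmap img_masks.png --out focused.png
fundusfocus pipeline run config.yaml
```

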