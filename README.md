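# fundusroar

Where does the predictive signal for glaucoma live in a fundus photograph?
Convolutional networks detect glaucoma and estimate the vertical
cup-to-disc ratio (VCDR) from disc-centered fundus images with high
accuracy, but standard occlusion tests cannot tell whether performance on
masked images drops because information was removed or merely because the
test distribution shifted. The fair test is *remove and retrain*: black out
a standardized region in **both** training and test images and retrain the
model from scratch.

`fundusroar` implements that crop-policy evaluation framework end to end,
together with a synthetic cohort generator that makes the claim testable
without any clinical data:

- **Synthetic cohort generator** — disc-centered stereo fundus images
  (2 images/eye, 1–2 eyes/patient) with a bright optic disc (vertical
  diameter 23 % of image height), a cup excavation encoding the VCDR label,
  vessel arcades, illumination gradient, sensor noise, and supero-/infero-
  temporal peripapillary RNFL wedges whose texture contrast attenuates with
  disease severity. A latent-Gaussian copula couples age, VCDR and the
  glaucoma label to clinic-realistic targets (mean VCDR 0.67, prevalence
  0.55, r(VCDR, age) = 0.29, point-biserial r(glaucoma, age) = 0.56).
  Crucially, *where* the disease signal is planted is a switch:
  `disc_only`, `periphery_only`, or `both`.
- **Preprocessing** — square crop → background-subtraction local contrast
  enhancement → circular ROI clip → resize, all deterministic.
- **Crop policies** — a disc-centered circle with diameter a fixed
  percentage of image width is blacked out (*ONH crop*) or kept exclusively
  (*periphery crop*).
- **Training** — a small fully-convolutional network (4 stride-2 conv
  blocks, global average pooling, single output unit) trained with Adam,
  plateau learning-rate decay (×0.75 after 10 stale epochs), MSE (VCDR
  regression) or binary cross-entropy (glaucoma classification), and
  mirror/elastic/brightness/cutout augmentation. Implemented directly on
  numpy (im2col convolutions with full backprop), so it runs anywhere.
- **Evaluation** — MAE, R², Pearson r, baseline MAE and error reduction for
  regression; patient-level AUC (max score over a patient's images) for
  classification; percentile 95 % CIs from patient-resampled bootstrap
  (5000 iterations by default).
- **Saliency** — absolute input-gradient maps, mirrored for left eyes,
  aligned on the disc centroid, averaged, and summarized over the 8
  clinical sectors inside the disc and in the 1–2 disc-radius annulus.
- **Orchestration** — the full experiment grid (7 ONH + 9 periphery crop
  sizes per task, 3 repeats for classification = 64 trainings) plus a
  desk-scale grid that runs on one CPU.

## Worked example

```python
from fundusroar import CropSpec
from fundusroar.experiments import desk_cohort, desk_train_config, run_cell

# plant the disease signal ONLY outside the optic nerve head
cohort, gen = desk_cohort(n_patients=200, signal_mode="periphery_only", seed=1)

# remove-and-retrain: black out a 60%-of-width circle over the ONH
run = run_cell("glaucoma", cohort, gen, spec=CropSpec("onh", 60.0), seed=1,
               train_config=desk_train_config("glaucoma", seed=1))
r = run.report
print(f"patient-level AUC {r.auc.point:.3f} "
      f"[95% CI {r.auc.ci_low:.3f}-{r.auc.ci_high:.3f}] "
      f"on {r.n_patients} test patients")
```

prints (one CPU, ~1 minute):

```
patient-level AUC 0.961 [95% CI 0.900-1.000] on 40 test patients
```

The optic disc is completely blacked out, yet the classifier discriminates
glaucoma — the planted peripheral (RNFL) signal carries it. Re-running
with `signal_mode="disc_only"` collapses the same cell to chance
(AUC ≈ 0.5): the crop-policy framework correctly attributes where the
signal lives. The scripts in `examples/` walk through each capability
(generation, preprocessing and cropping, training, saliency averaging, the
retrain-vs-occlusion sweep).

A thin CLI mirrors the library: `fundusroar simulate|preprocess|train|sweep --help`.

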