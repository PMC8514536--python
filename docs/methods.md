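# Methods

## The question and the design

Occlusion testing — masking part of a test image and recording the change
in model output — conflates two effects: the loss of information and the
shift between training and test distributions. The remove-and-retrain
design eliminates the confound by applying the same standardized mask to
training, validation and test images and training a fresh model per mask.
`fundusroar` implements this design for two tasks on disc-centered fundus
images, glaucoma classification and vertical cup-to-disc ratio (VCDR)
regression, with two complementary mask families: a disc-centered circle
of diameter `size_pct`% of image width is either blacked out (ONH crop) or
kept exclusively (periphery crop). Mask sizes are *absolute* (relative to
image width, not to the individual disc) to avoid coupling the mask to a
quantity the tasks themselves predict; the identity cell (`size_pct = 0`)
doubles as the full-image baseline and as the model reused by the
occlusion condition.

## Synthetic cohort model

The generator produces a statistically realistic stand-in for a tertiary
glaucoma-clinic population, with the one property no clinical dataset can
offer: *ground-truth knowledge of where the disease signal is in the
image*.

**Joint label model.** Age, VCDR and glaucoma are coupled through a
latent-Gaussian (copula-style) construction. Per patient, an age latent
`A ~ N(0,1)` gives age `62.9 + 17·A` (clipped to [0, 100]); a patient
severity latent loads on it with weight ρ. Eye severity mixes the patient
severity with an eye-specific innovation at inter-eye correlation `w = 0.8`
(a design constant, exposed in config; no per-eye asymmetry statistics were
available to calibrate it). The glaucoma label thresholds eye severity at
`c = Φ⁻¹(1 − prevalence)`; the VCDR latent loads on eye severity with
weight λ, and `VCDR = clip(0.67 + 0.15·latent, 0, 1)` (0.15 is a
clinic-realistic spread; only the mean 0.67 was a stated target). The two
loadings are solved in closed form from the correlation targets: the
point-biserial correlation of a thresholded standard normal with another
normal at latent correlation ρ_e is `ρ_e·φ(c)/√(p(1−p))`, so

- ρ_e = 0.56·√(0.55·0.45)/φ(c) ≈ 0.704, ρ = ρ_e/√w ≈ 0.787,
- λ = 0.29/ρ_e ≈ 0.412.

At the cohort sizes used for verification (6486 and 3592 patients) the
realized statistics land within sampling error of all four targets
simultaneously. One cohort carries both labels; the clinic tables the
targets come from describe two overlapping sub-cohorts, but a single
jointly-consistent population is the cleaner object for a generator and
matches both sets of pairwise statistics to within their tolerances.

**Image model.** 96-px (configurable) square RGB images, canonical
right-eye layout (temporal side left), mirrored exactly for left eyes:

- reddish fundus background with a radial illumination falloff;
- a bright disc of vertical diameter 23 % of image height, center jittered
  per eye by ≤ 3 % of width plus ≤ 1 % per stereo image; a brighter cup
  whose vertical radius is `VCDR · disc_radius`;
- two dark vessel arcades leaving the disc vertically and sweeping
  temporally;
- two peripapillary RNFL wedges (45° sectors centered supero- and
  infero-temporally, annulus 1.15–3.9 disc radii) rendered as a brightness
  plateau *with radial fiber striations* (sinusoidal texture across the
  fiber direction, ~5 px period). Wedge amplitude is
  `0.12 − effect_size·noise_sd·g`, where `g = Φ(eye severity) ∈ [0, 1]`,
  i.e. brightness and texture contrast attenuate with disease — the fundus
  correlate of RNFL loss. With `signal_mode="disc_only"` the wedge
  amplitude is fixed at its mid-level instead (severity-independent);
  the cup always encodes the VCDR label;
- additive Gaussian pixel noise (sd 0.02), seeded per image.

The striation texture matters: the preprocessing chain includes
background-subtraction contrast enhancement, a high-pass operation that
removes smooth brightness plateaus almost entirely. A purely smooth wedge
would make the planted peripheral signal invisible to any model that sees
only enhanced images; the high-frequency striations pass through the
enhancement with their contrast intact. The wedges extend to 3.9 disc
radii (≈ 43 px at 96 px) so that an annulus of signal survives even the
largest (60 %, radius 28.8 px) ONH crop — without this the "signal outside
the ONH" condition would be vacuous at the extreme crop.

**Defaults as study conditions.** `effect_size = 4` (wedge dimming range in
units of pixel noise), `noise_sd = 0.02`, prevalence 0.55, mean VCDR 0.67,
correlation targets 0.29/0.56, 2 images/eye, 90 % of patients with both
eyes. Determinism: every random draw derives from `(seed, stream, id)`,
so a config reproduces its cohort bit-for-bit and any single image can be
re-rendered in isolation.

**What the generator does not model** — and hence what passing tests do
not show about clinical data: photorealistic texture, myopic disc
morphology (tilt, peripapillary atrophy), disease staging, stereo
disparity, camera/color variation, localized (as opposed to diffuse) RNFL
defects. Results on this cohort validate the *mechanics and fairness* of
the crop-policy pipeline (signal placement is recovered, occlusion is
pessimistic, saliency localizes), not clinical performance levels.

## Preprocessing

Fixed order: centered square crop → local contrast enhancement → circular
ROI clip → (crop policy) → bilinear resize, intensities kept in [0, 1].
Enhancement is `clip(4·(image − G(image, σ)) + 0.5, 0, 1)` per channel
with σ = ROI_radius/30 and reflect padding — the standard fundus
background-subtraction recipe; gain, offset and σ are config. The clip
zeroes pixels beyond `width/2 − inset` (inset 10 px at the 512-px
reference scale, scaled proportionally by `PreprocessConfig.for_size`),
removing the overexposed rim the subtraction creates at the ROI border.
Coordinates are 0-based (row, col) from the top-left; circle membership is
Euclidean distance from pixel center ≤ radius; resizes map geometry with
pixel-center convention.

## Disc localization

Synthetic images carry ground-truth geometry, which downstream modules use
by default (`GROUND_TRUTH` mode). A deliberately simple intensity detector
(`DETECT`: smoothed-luminance peak, half-contrast region growing, centroid
+ equivalent radius) stands in for a segmentation network, because
localization is an input contract here, not a contribution; it reports
NOT_FOUND below a peak-to-background contrast of 0.2 (config), and the QC
filter drops such images per image, never moving a patient across splits.

## Model and training

The desk-scale backbone is a fully-convolutional network: four 3×3
stride-2 convolutions (widths 16/32/64/128), ReLU, global average pooling,
one output unit — linear for regression (MSE), sigmoid for classification
(binary cross-entropy with logits). It accepts any square input ≥ 32 px.
Forward, backward, Adam and input-pixel gradients are implemented directly
on numpy (im2col + BLAS matmul, float32; float64 switchable for numerical
tests), since no deep-learning framework is assumed. A ResNet-50 config
enum exists for full-scale replication but raises: it would require an
external framework and GPU-scale data.

Recipe: Adam, base learning rate 1e-4, ×0.75 after 10 successive epochs
without validation improvement, best-validation weights restored, early
stop after 20 stale epochs, batch 32, augmentation per image with
probability 0.5 each (horizontal mirror; elastic deformation, displacement
sd 8 px at 512-px scale; brightness shift ±0.1; cutout square of 10 %
width). Cutout may overlap the crop hole; the crop precedes augmentation.
A leakage guard refuses train/val splits sharing a patient.

The desk-scale recipe (`desk_train_config`) adapts three dials to the
small network and 96-px images: base lr 2e-3, plateau patience 5,
max 40 epochs with effectively disabled early stopping (patience 25) —
validation loss on these small cohorts is noisy and the loss typically
plateaus for 10–15 epochs before dropping, so aggressive early stopping
truncates runs that are about to converge. Elastic deformation is off at
desk scale (costliest transform, negligible effect at 96 px).

## Evaluation

Regression: MAE, R² = 1 − SS_res/SS_tot about the test mean (may be
negative), Pearson r; baseline MAE is the mean absolute deviation about
the test mean, and error reduction is `100·(1 − MAE/baseline)` rounded to
integer percent. Classification: AUC (Mann–Whitney with midrank ties, via
scikit-learn) on patient-level scores — a patient's score is the max over
their images, the label is any-positive — matching referral practice.
Confidence intervals: percentile 2.5/97.5 over seeded bootstrap resamples
drawn at the *patient* level (images within a patient are dependent), 5000
iterations at full scale, 1000 in desk sweeps; degenerate resamples
(single-class) are redrawn and counted. KDE summaries use a 2-D Gaussian
kernel with Scott's bandwidth on a common grid for both axes.

## Saliency

Per image: absolute gradient of the model score w.r.t. input pixels
(plain input-gradient; the score is the logit for classification), reduced
over channels by max, max-normalized per image so no single high-gradient
image dominates the average (normalization is a config switch). Averaging:
left-eye maps are mirrored horizontally, each map is translated (no
rotation/scaling) so its disc centroid lands on the center of a 2H×2W
canvas, and pixels are averaged over the maps covering them (coverage
tracked). All-zero-gradient maps are excluded and counted. Sector
summaries report mean saliency in 8 × 45° sectors (canonical right-eye
orientation) for two rings: inside the disc and the 1–2 disc-radius
annulus.

## Orchestration and problem sizes

The full grids are 7 ONH sizes (0–60 %) and 9 periphery sizes (1, 2.5, 5,
10, 20, 30, 40, 50, 60 %) per task — the periphery list is the natural
9-point completion of the stated endpoints — with 3 repeats for
classification and 1 for regression: 64 trainings in total. Cell seeds are
`base_seed + crc32(task|policy|size|repeat) mod 2³¹` so any cell is
independently reproducible. Occlusion cells reuse the size-0 model of the
same repeat and add no trainings.

Desk-scale defaults used by the test suite and the acceptance script:
200-patient cohorts (~760 images) at 96 px, sizes {0, 20, 40, 60}, 1
repeat, 1000 bootstrap iterations. The stochastic signal-placement
measurements (ONH-60 retraining under periphery-only vs disc-only signal)
are evaluated on a fresh 400-patient held-out cohort rather than the
40-patient test split, because the standard error of a null AUC at 40
patients (~0.07) would swamp the quantity being measured; at 400 patients
it is ~0.02. The occlusion-vs-retrain comparison accepts the occlusion
value when its CI lower bound does not exceed the retrain CI upper bound
(at-or-below up to bootstrap noise).

## Known limitations

- The numpy backbone is desk-scale by construction; absolute performance
  numbers are not comparable to GPU-scale transfer-learned models, only
  the *relative* pattern across crop policies is.
- The generator's peripheral signal is diffuse and bilateral; localized
  RNFL wedge defects, which clinicians grade, are not modeled.
- `DETECT` localization is validated only on synthetic renders; on real
  fundus photographs a trained segmentation model should replace it.
- Training determinism holds for a fixed BLAS/thread configuration;
  across numerical libraries bit-identity is not guaranteed, though seeded
  results agree statistically.
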