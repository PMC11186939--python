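# Methods

This document records the modeling conventions, parameter defaults and
numerical choices of `neoecho`. The desk-scale problem sizes (frame sizes,
cohort sizes, epoch counts) are the package's own choices, selected so every
experiment completes in CPU minutes.

## 1. Problem setup

Each subject contributes one grayscale cine loop per standard transducer
view (PSAX-P, PLAX, A4C, PSAX-S, PSAX-A). The target is a three-level PH
grade: 0 (none), 1 (mild, septal flattening), 2 (moderate-to-severe, septum
bowing into the LV). Grading is per subject; recordings of one subject never
straddle a train/validation boundary.

## 2. Preprocessing (`neoecho.preprocess`)

- **Sector estimation**: pixels whose temporal maximum exceeds a threshold
  (default 10) are candidates; the largest connected component with holes
  filled is the scanning sector. A manual mask can be supplied instead.
- **Masking/cropping**: out-of-sector pixels are zeroed; frames are cropped
  to the sector bounding box.
- **Resizing**: bilinear (`skimage.transform.resize`, order 1, no
  anti-aliasing), rounded back to uint8. Full-scale target 224×224; the test
  preset is 64×64.
- **Equalization**: classic per-frame histogram equalization,
  v → round(255·CDF(v)), computed over in-sector pixels only. The map is
  monotone, so intensity rank order inside the sector is preserved.
- **Model normalization**: x → (x/255 − mean)/std with train-split statistics
  and a leading channel axis (replicated to 3 for RGB-style backbones).

## 3. Augmentation (`neoecho.augment`)

A sample is augmented at all with probability p_sample = 0.9; each of the
eight transforms then fires independently with p_transform = 0.5. Parameter
draws — and noise realizations — happen once per sample and are shared by
every frame, preserving temporal structure. Order is fixed (intensity before
spatial); when both spatial gates fire, rotation/translation and scaling are
composed into a single bilinear resampling pass.

Default ranges: blur factor [0, 0.9999] or sharpen (1, 8] (branch chosen
uniformly); brightness [0.5, 1.2]; gamma [0.25, 2.0]; Gaussian σ up to 12.75
intensity units; salt-and-pepper per-tail probability θ = 0.005 (each tail
0.5%); multiplicative speckle strength up to 0.2; rotation ±15°; translation
≤ 0.1 of the side length; scaling [0.8, 1.2].

## 4. Clip sampling (`neoecho.clips`)

The spatio-temporal classifier consumes n = 10 clips per recording of
k = 12 frames at interval s = 1 (effective length l = k·s = 12 frames,
covering at least one neonatal heartbeat of ~10 frames at 25 fps). Clip
starts are uniform on [0, T − (k−1)s − 1], drawn independently.

For frame-based analysis, the per-frame **relative ventricle area**
(fraction of LV ∪ RV pixels from segmentation masks) identifies cardiac
phase: its minima mark systole — when septal morphology is most informative
— and its maxima diastole. `select_extreme_frames` takes the ⌈fraction·T⌉
extreme frames with a stable sort (ties → earlier frame).

## 5. Classifiers and training (`neoecho.classifiers`, `neoecho.nn`)

Three backbones share one layer library: an 18-layer 3D residual network
(`spatiotemporal_3d`), its 2D counterpart obtained by collapsing every
kernel/stride to a singleton time extent (`spatial_2d`), and a reduced-width
4-block 3D network (`tiny_3d`, channels 8→16→24→32) sized for CPU training
on the phantom.

The backend is plain numpy with hand-written backward passes: Conv3d
(strided-slice GEMMs per kernel offset), BatchNorm (train/eval), ReLU,
global average pooling, a linear head, softmax cross-entropy, and Adam with
L2 weight decay added to the gradient (biases and normalization parameters
exempt). Every layer's gradient is validated against central finite
differences in the test suite (float64, tolerances 1e−5 to 1e−6).

Training defaults: Adam with learning rate 0.001 and weight decay 0.001;
batch size 8 for clip models, 64 for frame models; 150 epochs at full scale
(desk-scale runs use 4–10). Class imbalance is handled by a weighted random
sampler: per-sample weight 1/count(class), drawn with replacement each
epoch, so each class is seen approximately equally often. Exact ties at
prediction time resolve toward the higher severity (clinically conservative).

## 6. Aggregation (`neoecho.aggregate`)

- **Clip → view**: majority vote over n clip labels; modal ties break toward
  higher severity. View confidence C = (modal count)/n.
- **View → subject**: majority vote over view labels. Vote ties go to the
  tied label backed by the single most confident view; exact confidence ties
  resolve toward higher severity. The probabilities used for subject-level
  AUROC are the mean clip probabilities of the winning view's most confident
  supporter.

## 7. Saliency (`neoecho.saliency`)

3D Grad-CAM at the last convolutional stage: channel weights
α_c = mean over (t, h, w) of ∂y_target/∂A_c; map = ReLU(Σ_c α_c A_c),
trilinearly upsampled to the clip's (k, H, W) and min-max normalized per
volume (constant maps become all-zero). Overlays blend a colormap with
weight proportional to local saliency, so irrelevant pixels show the
original grayscale. The **randomization sanity check** re-initializes the
final block and head with scale-matched Gaussian weights and reports the
Spearman rank correlation between original and randomized maps; low values
confirm the map depends on learned weights rather than input edges.

At desk scale the last convolutional stage is coarse (the tiny backbone
reduces 12×64×64 clips to a few cells per axis before upsampling), so how
sharply the map localizes the septum varies with the training seed: some
seeds concentrate saliency on the septal band, others on wider context that
also predicts the grade. Localization statistics should therefore be read
per trained model, not as an architecture-level guarantee.

## 8. Evaluation (`neoecho.evaluation`)

Monte-Carlo cross-validation: repeated independent stratified subject-level
80/20 splits (default 10 repetitions). Each class contributes
round(0.2·class size), at least 1 and at most size−1, subjects to
validation. Metrics per repetition: one-vs-one AUROC (probabilities
renormalized over the classes present; NaN when undefined), balanced
accuracy, weighted F1/precision/recall, mean confidence. Summaries report
mean ± sample SD (ddof = 1; a single repetition reports SD 0).

## 9. Clinical formulas (`neoecho.clinical`)

Simplified Bernoulli on the tricuspid regurgitation jet:
sPAP = 4·TRV² + RAP (TRV in m/s, pressures mmHg); mean pressure from the
linear relation mPAP = 0.61·sPAP + 2. PH is defined as mPAP > 20 mmHg at
rest.

## 10. Synthetic phantom (`neoecho.synth`)

A schematic, seeded generator of echo-like loops with ground truth:

- Fan-shaped scanning sector from a virtual transducer above the frame.
- LV ellipse and RV crescent separated by a bright septal wall; chamber
  blood pools darker than tissue, walls brighter.
- Cardiac cycle: 10 frames/beat at 25 fps (~150 bpm, neonatal range). Phase
  0 is systole by convention; the contraction envelope
  e(φ) = ½(1 + cos 2πφ) scales chamber axes by 1 − 0.18·e, so ventricle
  area is minimal at systole and maximal at diastole.
- Severity controls the systolic septal displacement (fraction of the LV
  x-semiaxis): +0.45 into the RV (grade 0, round LV), 0 (grade 1, flat
  chord), −0.55 into the LV (grade 2, D-shaped LV). The flat-septum chord
  tracks the contracting ellipse so the morphology stays visible at systole.
- Per-view presets scale the morphological signal (PSAX-P 1.0, A4C 0.5,
  PLAX 0.4, PSAX-S/PSAX-A 0.3) and apply rigid rotation/shift/contrast —
  PSAX-P is the most discriminative simulated view by construction.
- Texture: multiplicative gamma speckle (shape 1/strength²) inside the
  sector.
- Cohorts: class prevalence 126:32:34 (≈65/17/18%) via largest-remainder
  rounding; per-subject jitter in scale (±10%), rotation (±5°), brightness
  (±10%) and length (122 ± 2 frames). Identical seeds give byte-identical
  archives (fixed zip timestamps).
- Ground truth per frame: LV/RV masks, their union, the septal band, and
  the cardiac phase. The severity signal is measurable from ground truth via
  the systolic LV circularity 4πA/P² (Crofton perimeter, which is much less
  biased than pixel-edge counting on small rasterized shapes): grade 0 ≈
  0.98, grade 1 ≈ 0.93, grade 2 ≤ 0.62 at the 64-px test preset, with clean
  separation under the cohort jitter.

**Limits**: the phantom is not a physical ultrasound simulation — no beam
physics, no shadowing, no probe motion, schematic anatomy. It exists to make
the pipeline's claims testable (severity recoverability, phase conventions,
localization), not to model image formation.

## 11. Desk-scale experiments (`neoecho.pipeline`)

- **Single-view recovery**: 120 subjects (79/20/21 per class), PSAX-P only,
  64×64, ~122 frames; stratified 80/20 subject split; `tiny_3d` trained for
  6 epochs on 6 clips per training recording with full augmentation;
  evaluation with n = 10 clips per held-out recording and clip → view
  voting. Seed 0: balanced accuracy 1.00, ~3 min on one CPU.
- **Multi-view voting**: 60 subjects × 3 views (PSAX-P strong; PLAX and A4C
  weak), one classifier per view (4 epochs), subject-level voting with
  confidence tie-break. Seed 0: PSAX-P 1.00, PLAX 1.00, A4C 0.96, voted
  1.00 (~3 min).

Evaluation always uses the full n = 10 clip protocol; only training-side
sizes are reduced.
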