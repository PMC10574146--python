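# Methods

This note documents the models, algorithms and default study conditions
implemented in `mtpi`, the reasoning behind the open design choices, and
what the synthetic benchmark can and cannot say about real aerial imagery.

## Problem setting

A semantic-segmentation network pre-trained on one season's vegetation
imagery (classes: tree, shrub, grass, non-vegetated area/NVA) degrades when
the scene appearance shifts — e.g. between rainy and dry seasons in a dry
thermal valley, where shrub and grass canopies brown and flatten while
deep-rooted trees and bare ground change little. Re-training from scratch
wastes most of what the network already knows. The package implements a
method for choosing, *before* any trial-and-error fine-tuning:

- **TP0** — the transfer point: how many activation layers (counted from the
  input) to freeze, and
- **TDS0** — the transfer dataset size: how many newly labelled samples the
  transfer training needs,

by maximising a per-layer transfer potential index

```
TPI(x) = TPI_WKs(x) / TPI_TP(x)
```

where `TPI_WKs(x) ∈ [0, 1]` scores how class-discriminative the layer-x
features already are on the new data and `TPI_TP(x) ∈ {1..Nlevel}` is a
discrete time-cost level derived from the parameter count that would remain
trainable after freezing at x.

## Weighted segmentation metrics

All evaluation flows through a C×C pixel confusion matrix
(`counts[r, c]` = pixels of true class c predicted as r). Per-class
precision, recall, F1 and IoU are combined with prevalence weights
`pi` (class-i share of ground-truth pixels), giving WPA, WRE, WF1 and WIoU;
a plain 1/C macro average is available via `weighting="macro"` for
comparison. WKs is Cohen's kappa with the standard chance-corrected
denominator, `WKs = (Po − Pe)/(1 − Pe)`; a variant dividing by `(1 − Po)`
is selectable (`denominator="po"`) because some sources print that form.
Agreement bands follow the conventional five intervals (≤0.20 slight, …,
\>0.80 almost perfect). Classes with an empty denominator contribute zero
with a logged warning rather than propagating NaN. A class absent from the
ground truth has `pi = 0` and cannot distort the weighted scores.

## Scene simulator

`scene_sim` generates paired image/label rasters that stand in for 400×400
aerial crops:

- **Geometry.** One Gaussian-smoothed white-noise field per class
  (correlation length `blob_scale`, wrap-around boundaries), biased by a
  fixed-point iteration on per-class offsets until the argmax label honours
  the requested area mix `class_mix` (the iteration targets 0.005 absolute
  deviation; tests allow 0.02). This yields contiguous, canopy-like blobs.
  A class with zero mix is excluded exactly; a mix of 1 fills the raster.
- **Appearance.** Per-class mean RGB plus an oriented sinusoidal texture
  grating (per-class spatial frequency and amplitude, random orientation
  and phase per scene) plus i.i.d. Gaussian pixel noise (`color_sd`),
  clipped to uint8. Tree and shrub share a similar dark-green hue and are
  separated mainly by texture frequency; grass is yellow-green; NVA is
  grey-brown and nearly untextured.
- **Season shift.** A photometric-only transform in HSV space: additive hue
  rotation (degrees), multiplicative saturation and brightness gains, and a
  texture-contrast gain that scales the brightness deviation around each
  class's mean (washing textures out below 1). Only flagged classes are
  shifted; unflagged pixels are copied back bit-exactly, and the identity
  shift returns the image unchanged bit-for-bit. Labels are never touched
  by any photometric operation.

The default study conditions (`configs/default.yaml`) put the task in a
noise-limited regime (`color_sd = 30` on a 0–255 scale) and shift **only
shrub and grass** (hue −35°, brightness ×1.30, saturation ×0.65, texture
contrast ×0.60). This emulates the dry-season phenomenology the method is
aimed at: herbaceous and shrub layers dry toward brown while trees and bare
ground keep their appearance, and dried grass becomes confusable with bare
ground for a colour-reliant classifier. The shift magnitudes were fixed by
a one-off calibration so that the pre-trained network's target-season WKs
falls below the 0.6 transfer threshold while its source-season WKs stays
above the 0.8 skip threshold; they are study conditions, not tunables, and
the tests reference the config rather than repeating the numbers.

Scenes default to 64×64 pixels (`min_size` relaxed below the standard
224-pixel network-input contract; the relaxation is explicit in the config
and mirrors the reduced-size contract of the toy networks).

## Dataset assembly and augmentation

Labels travel on disk as palette PNGs — tree (0,0,255), shrub (0,255,0),
grass (255,0,0), NVA (255,0,255) — with a strict codec: any off-palette
pixel fails decoding with its coordinate. Large rasters are cut into
random fixed-size crops (default 400 px, minimum 224) with identical
image/label windows. Datasets split 4:1:1 into train/validation/test with
the integer remainder assigned to train (15,000 → 10,000/2,500/2,500).

Augmentation expands every sample to `expansion_factor = 6` outputs (the
original plus five variants, the 2,500 → 15,000 expansion). Each variant
composes 1–3 of seven methods drawn uniformly without replacement:
x-symmetry, y-symmetry, panning (±5% of the edge), HSV channel jitter
(×0.9–1.1 per channel), scaling (×0.9–1.1), rotation (±5° about the
centre), and Gaussian noise (mean 0, variance 0.1 **on [0,1]-scaled
intensities** — a variance of 0.1 in raw uint8 units would destroy the
image). Anything moved beyond the frame is cropped and exposed regions are
filled (label → NVA, image → the NVA base colour), so output size never
changes; this fill-and-crop is the "cropping" step of the seven-method
family rather than an independent transform. All selected geometric
methods are composed into a single affine resampling pass — bilinear for
images, nearest-neighbour for labels — and each variant carries a transform
log from which the geometric part can be replayed exactly (the basis of
the image/label congruence tests). Per-sample RNG streams derive from
`(config seed, sample index)`, so augmentation is reproducible and
streamable (`iter_augmented`) without materialising 60,000 rasters. The
hot pixel kernels (affine warp, fused HSV scaling) are numba-compiled.

## Toy segmentation networks

Pure-numpy encoder–decoder CNNs with hand-written backpropagation: a 3×3
stem, `depth` encoder stages (2× max-pool + 3×3 conv, channels doubling up
to 4× base), a mirrored decoder (2× nearest upsample + 3×3 conv) and a 1×1
classification head; ReLU after every convolution. `decoder_channels` can
fix the decoder widths — the default config uses (32, 32), a
non-compressing decoder, so the features feeding the head stay wide. An
optional residual flag adds a skip-connected same-channel convolution per
encoder stage. The toy nets contain no normalisation layers, so the
question of freezing normalisation statistics does not arise.

Every ReLU is an activation layer and defines one transfer point, indexed
1..T from the input. Freezing at TP x pins every convolution up to and
including the one feeding activation x; `LSx` is the parameter count that
remains trainable, `LS0` the total, and `LS(−1)` the head-only count. TP 0
freezes nothing; TP −1 (and, in these toy nets, TP T) leaves only the head
trainable. Frozen parameters are never touched by an optimiser update, so
they are bit-identical after training — a tested contract.

Training minimises class-weighted softmax cross-entropy (weights inversely
proportional to class pixel counts in the training labels, normalised to
sum to C) with plain momentum SGD (lr 0.02 pre-training / 0.01 transfer,
momentum 0.9, batch 4), seeded shuffling, and a convergence rule: stop when
the relative change between the means of the two halves of the trailing
loss window falls below the tolerance. Images are standardised to
[−0.5, 0.5]. Prediction is the per-pixel argmax with ties broken toward
the lower class index. Everything is deterministic given the seeds.

## Feature probing and the TPI curve

`TPI_WKs(x)` asks: *if we kept everything up to layer x, how well do those
features already separate the classes on the new data?* The default probe:

1. capture layer-x activations and upsample them bilinearly to label
   resolution (labels are never resampled);
2. on a calibration subset, assign each channel to the class maximising its
   standardised contrast (mean activation inside the class minus mean
   outside, over the channel's global spread);
3. score each class as the mean of its assigned channels, predict by
   argmax, and compute WKs against the labels on a disjoint evaluation
   subset, clipping negative kappa to zero so the score lies in [0, 1].

A least-squares 1×1 linear read-out over channels is the selectable
alternative (`rule="linear"`). Both are interpretations of per-layer
feature discriminability — the underlying procedure is illustrated in the
source material only by example mappings, not a formula — and the two give
concordant TP rankings on the default setup (tested).

`TPI_TP(x)` bins the **trainable fraction** `LSx/LS0` into
`min(Nlevel, floor(LSx/LS0 × Nlevel) + 1)`, so the cost level falls as
freezing deepens, and the level domain is exactly {1..Nlevel} (default
Nlevel = 10). The alternative reading that bins the frozen fraction
`(LS0−LSx)/LS0` — under which the level *rises* with depth, inverting the
narrative that deeper freezing is cheaper — is available as
`form="literal"` for comparison.

Per-dataset TPI curves are averaged pointwise; `TP0 = argmax TPI` with ties
broken toward the larger x (the cheaper transfer among equals). The curve
on the default setup rises from the shallow TPs and attains its maximum at
the deepest TP, where the cost level collapses to 1 while the probe score
stays high.

**Screening.** Before any transfer, each candidate dataset is screened
against the pre-trained net: WKs ≥ 0.8 → keep the net as is ("skip");
WKs < 0.6 → transfer training ("transfer"); the band between is flagged
"borderline" for the operator, since no rule is defined there.

## The TDS rule

Transfer dataset size follows the linear data-per-parameter rule: the
pre-training demonstrated that `kpre = TDSpre / LSpre` samples per
trainable parameter suffice, so the lowest-error-risk transfer size is
`TDS0 = round(kpre × LS_TP0)`, floored at 1 and capped (with a warning) at
the available transfer pool. `TDSpre` is the size of the *augmented*
training split actually used in pre-training (augmented samples are what
the optimiser consumed), and `LSpre = LS0`. On the default setup
(TDSpre = 960, LS0 = 24,660, head-only LS = 132) this yields TDS0 = 5 of a
160-scene transfer pool — a 97% reduction in newly labelled data.

## Sweep harness

`cmd_sweep` trains every cell of a TP grid (TP0, TP0±1, 0, −1 — clamped to
the catalog) at TDS0, and a TDS grid (a 0.2×–4× ladder around TDS0) at TP0,
over three seeds, recording final WKs and iterations-to-convergence. The
expected qualitative orderings — deeper freezing converges in fewer
iterations with a lower accuracy ceiling; more transfer data reaches higher
final accuracy — are asserted as majority rank orderings over the seeds,
not cell-by-cell inequalities, because individual cells are stochastic.

## Numerical and degenerate-input choices

- Argmax ties (prediction, probe, channel assignment): lowest index wins.
- TPI ties: deepest TP wins.
- Negative probe kappa clips to 0; degenerate single-class matrices define
  kappa as 0 with a warning.
- Geometric fills: label NVA, image NVA base colour; recorded per variant.
- Affine warps use the inverse-map convention with bilinear/nearest
  sampling; coordinates landing exactly on the last row/column are inside.
- Training divergence (non-finite loss) raises with the trace attached.
- All random draws flow from named integer seeds; no global RNG state.

## Problem sizes

The default configuration runs 64×64 scenes, 240-scene surveys per domain
(160 augmented to 960 for pre-training), a ~25k-parameter depth-2 net, and
800–1,500-iteration training budgets — sizes chosen so the full pipeline,
including the sweeps, completes on a single CPU core in minutes while
keeping every qualitative regime of interest (screening straddle, rising
TPI curve, near-parity transfer at a sub-1% trainable fraction). The
augmentation-count checks run at the production 400×400 crop size.

## What the benchmark does and does not show

The simulator emulates: multi-class textured vegetation mosaics with
controllable class balance; a systematic, class-selective photometric
season shift; within-class pixel noise strong enough that the task is
noise-limited (small decision margins, as in hard field imagery). It does
**not** emulate: geometric season changes (canopy growth or loss),
illumination gradients and shadows, orthomosaic stitching artefacts,
inter-scene autocorrelation, label noise, or photorealistic texture. A
passing suite therefore shows the *method* behaves as designed — screening
triggers, the TPI machinery ranks layers sensibly, the TDS rule produces a
small transfer set that recovers near-full accuracy — not that specific
accuracy figures carry over to any real survey. The linear TDS rule itself
is an assumed model (its proportionality constant is inherited from
pre-training); nonlinear data–feature relationships are out of scope.
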