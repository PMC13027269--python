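# Methods

## Problem setting

Small-target crop pests (aphids, thrips, whiteflies, leafhoppers, spider
mites, leaf beetles) occupy a tiny fraction of image pixels — typically well
under 2% — against cluttered foliage, and their occurrence correlates
strongly with the local microclimate. `pestfusion` implements an image-level
six-class recognizer that fuses two modalities: the photograph and the
environmental record (air temperature in °C, relative humidity in %RH,
illumination in lux) taken by a sensor node at the moment of acquisition.

## Preprocessing

Images are bilinearly resampled to a fixed resolution `H0 × W0`. The
sampling grid is half-pixel-centred (the `align_corners=False` convention):
output sample `i` along an axis reads input coordinate
`(i + 0.5)·n_in/n_out − 0.5`, clamped to the valid range. This convention is
pinned by brute-force weight-sum oracles in the tests. Training-time
augmentation magnifies small targets: a random half-open crop window
`[x, x+w_c) × [y, y+h_c)` is rescaled back to the frame, and a random scale
perturbation `α ~ U(α_min, α_max)` (default 0.8–1.2) rescales the image and
restores the frame by centre-cropping (`α > 1`) or edge-replicate padding
(`α < 1`). All augmentations are exact no-ops at their identity parameters.

The sensor stream is cleaned in a fixed order: **outliers → interpolation →
alignment → standardization**.

* Outliers: a record is flagged when `|s_k(t) − μ_k| > λ·σ_k` with `λ = 3`
  by default. `μ_k, σ_k` use the population formula (divide by n) over the
  non-missing records of the channel, computed per acquisition session when
  session ids are available so a level shift between deployment sites is not
  mass-flagged. A constant channel produces no flags and a warning.
* Missing records (including removed outliers) are filled by linear
  interpolation in time; boundary gaps take the nearest observed value,
  where pure interpolation is undefined.
* Each image timestamp `t_i` is matched to the nearest sensor timestamp,
  rejected when the deviation reaches `Δt` (default 600 s, one sampling
  period). Equidistant ties break toward the earlier record — the one that
  was causally available when the photograph was taken.
* Channels are z-scored with statistics fitted **on the training partition
  only** and reused verbatim for validation and test; this leakage guard is
  asserted in the test suite.

## Network

Reference geometry (all printed dimensions hold at scale and width factors
of 1; inputs enter at the level-1 grid, 64×64, through a stride-1 stem):

| level | spatial | channels |
|------:|--------:|---------:|
| 1 | 64×64 | 64 |
| 2 | 32×32 | 128 |
| 3 | 16×16 | 192 |
| 4 | 8×8 | 256 |

The backbone is a hierarchical 3×3-conv/BatchNorm/ReLU stack; the deepest
stage adds a global-average-pooled context vector back onto its map
(global receptive-field modelling). Each level passes a
squeeze-and-excitation channel attention block
`w = σ(W₂ δ(W₁ GAP(F)))` with reduction ratio `r = 4` and sigmoid gates.

**Environmental prior modulation (FiLM-style).** The standardized sensor
vector `ŝ ∈ R³` passes a shared trunk `3 → 32 → 128` (ReLU); per-level
sigmoid heads emit gates `g_i ∈ (0,1)^{C_i}` that multiply the attended maps
channel-wise, `F̃_{h,w,c} = g_c · F_{h,w,c}`. The level-4 head is the
`128 → 256` mapping. Modulation leaves spatial structure untouched; the
per-channel energy ratio equals `g_c` exactly, and the gates `g ≡ 1` / `g ≡ 0`
limits are identities / zero maps — both asserted as laws in the tests.

**Cross-scale fusion.** Each level is 1×1-projected to 256 channels,
bilinearly upsampled to the level-1 grid, and combined convexly,
`F_ms = Σ_l α_l · proj(F̃^{(l)})` with `α = softmax(logits)`, so
`Σ α_l = 1` holds at every training step by construction. A cross-scale
relational unit — a single 3×3 convolution + ReLU over the fused map,
switchable off in the config — models local spatial correspondence across
scales.

**Collaborative head.** A `3 → 32 → 64` sensor encoder produces `u`;
per-level projections form conditional vectors `c_i = P_i u + q_i` that are
broadcast spatially and gate the modulated maps with a residual identity
path, `M_i = F̃_i + φ(F̃_i ⊙ G_i)` where `φ` is a 1×1 convolution + ReLU (a
zero gate leaves `M_i = F̃_i` exactly). The `M_i` are upsampled ×2/×4/×8 to
the level-1 grid, concatenated (640 channels), compressed to 256 by a 1×1
convolution + ReLU, pooled, and classified by a `256 → 128 → 6` softmax
head.

*Design choice — where the fused map lives.* Per-level modulation and the
four-level head leave the convex fusion output `F_ms` without a consumer in
the full model, which would make its weights untrainable dead parameters.
Since `F_ms` and the compressed collaborative map share the shape
`64×64×256`, the full model injects `F_ms` residually before pooling:
`z = GAP(F_cs + F_ms)`. This trains the fusion weights in the full model,
keeps every declared parameter on the gradient path (asserted per variant in
the tests), and makes the ablation that removes the collaborative head a
strict sub-network of the full model.

Activations: `σ` is sigmoid wherever a gate is produced; all other
nonlinearities are ReLU. The backbone is trained from scratch; BatchNorm
uses batch statistics in training and frozen running statistics in eval.

### Ablation variants

| name | contract |
|------|----------|
| `full` | everything |
| `no_multiscale` | classify from the attended, modulated level-4 map only (attention kept; only the multi-scale component is ablated) |
| `no_sensor_prior` | modulation gates fixed at 1; the collaborative head still consumes `ŝ` — only modulation is ablated |
| `no_collab_head` | skip conditional gating; classify from the pooled fused map |
| `concat_fusion` | conditional gating replaced by appending raw `ŝ` to the pooled fused map |
| `vision_only` | `no_sensor_prior` + `no_collab_head` combined; logits provably independent of `ŝ` |

## Training and evaluation protocol

Splitting is group-aware at the plot/session level: a seeded greedy
allocator assigns whole groups to train/val/test targeting 70/15/15 sample
fractions (exact when group sizes divide evenly; otherwise within one
maximal group size), and the training partition is divided into grouped
5-fold cross-validation subsets the same way. No group ever spans
partitions or folds.

The objective is softmax cross-entropy (the natural loss for the softmax
classifier); the optimizer is Adam with defaults `α = 10⁻³`, batch size 16,
with the learning rate halved when validation macro-F1 plateaus (patience
4, floor 10⁻⁵), and the best-validation checkpoint returned. All of these
are config-exposed.

Metrics follow the one-vs-rest confusion-matrix definitions (per-class
Accuracy `(TP+TN)/n`, Precision, Recall, F1). Two aggregation flavours are
reported: **macro** (equal class weights) and **sample-level** (overall
accuracy plus support-weighted P/R/F1 — pure micro-averaging would collapse
P = R = accuracy for single-label multiclass data, so the support-weighted
reading is used for the sample-level flavour). Undefined per-class values
(zero support, or no predicted positives) are reported as NaN and excluded
from macro means with a warning rather than zero-filled. Cross-validated
results are reported fold-mean ± sd.

## Synthetic data generator

The generator emulates the statistical structure of a field campaign
without shipping photographs:

* **Images** (default 64×64): multi-octave value noise in green/brown tones
  plus darker vein polylines form the background; targets are speckled
  ellipses with class-specific colour, elongation and micro-texture, each
  occupying a fraction of the frame drawn from `target_scale_range`
  (default 0.4–2% of pixels). "Sparse" images place 1–3 non-overlapping
  individuals; "dense" images place 5–8 overlapping individuals in an
  aggregation cluster at reduced contrast (mutual burial) and draw 4–7
  foliage-coloured occluders over the colony. The dense regime is
  calibrated so a vision-only classifier measurably degrades from sparse to
  dense held-out images, mirroring how aggregation and occlusion harm
  image-level recognition. A `confusable_pair` renders two classes
  visually identical so only the environment separates them;
  `target_contrast = 0` makes targets invisible.
* **Environment**: diurnal sinusoids (temperature peaking mid-afternoon,
  humidity in anti-phase, illumination clipped at 0 lux at night) sampled
  every 600 s, plus per-class mean shifts applied to records adjacent in
  time to an image (each pest is photographed preferentially under its own
  microclimate), Gaussian channel noise, sensor faults (excursions 8–12
  channel-scale sd from the clean curve, where the channel scale includes
  the diurnal swing — faults are extreme on the physical scale), and missing
  records; image timestamps carry a clock jitter against the sensor grid
  (default ≤ 120 s).
* **Structure**: images are grouped into plot/session groups (default 10
  per group, one density tag per group) on daytime acquisition slots, the
  class-count default follows the campaign's imbalance (roughly
  3 : 2.5 : 2 : 1.5 : 2 : 1), and all injected ground truth (outlier/missing
  masks, target masks, clean curves) is retained for validation.

What the generator does **not** emulate: photorealistic insect morphology,
imaging-chain artefacts (blur, exposure, white balance), correlated sensor
drift, and seasonal/weather nonstationarity. Passing tests therefore show
that the architecture exploits a genuine cross-modal signal and degrades
sensibly when it is removed — not that field accuracy on real collections
is reproduced.

## Desk-scale study conditions

The quantitative studies in the test suite and the acceptance script run
the identical topology at `scale_factor = 1/4` (16×16 inputs, pyramid
16/8/4/2) and `width_factor = 1/4` (channels 16/32/48/64): 360 images (60
per class), grouped 70/15/15 split, 12 epochs, batch 16, five seeds for the
ordering study and three for the negative control. Density-stratified
evaluation uses a freshly generated held-out collection (50% dense,
standardized with the training statistics) so stratum estimates do not rest
on a handful of test images. These sizes are the package's reference
desk-scale conditions; printed-dimension contracts always run at factors
of 1.

## Numerical choices and degenerate inputs

* The compute core is a reverse-mode autodiff engine over numpy arrays
  (im2col convolution, separable bilinear resampling as explicit linear
  operators, log-sum-exp-stabilized softmax); every primitive's backward
  pass is verified against central finite differences. Network weights are
  float32, He-initialised from an explicit seeded generator, so whole
  models are bit-reproducible from a seed.
* Crops are 0-based half-open windows; out-of-bounds windows are rejected
  with the offending coordinates in the message.
* An all-missing sensor channel, a zero-sd channel at standardization, an
  image with no sensor record within `Δt`, and an unknown variant name are
  all hard errors; a constant channel in the outlier rule degrades to a
  warning.
* Fold/partition ties in the greedy allocators break deterministically
  (train > val > test; lowest fold id), making splits pure functions of
  (groups, ratios, seed).

## Known limitations

* Synthetic imagery is far easier than field photographs; absolute
  accuracies here say nothing about field performance.
* The environmental channel is injected at the record level; real
  microclimate–behaviour coupling is slower and noisier.
* Instance counts are not modelled (image-level classification only).
* Temporal dynamics (accumulated temperature, seasonal transitions) are out
  of scope; the environment enters as an instantaneous prior.
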