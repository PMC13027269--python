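# pestfusion

Multi-scale vision–sensor collaborative recognition of small-target crop
pests.

Aphids, thrips, whiteflies and other small arthropods occupy a tiny
fraction of image pixels, hide on cluttered foliage, and occur in tight
dependence on the local microclimate. Purely visual classifiers lose their
features to repeated downsampling and confuse them with background texture.
`pestfusion` is for researchers and practitioners in agricultural
monitoring who want an image-level pest classifier that treats the
environmental record — air temperature (°C), relative humidity (%RH),
illumination (lux) at the moment of acquisition — as an ecological prior
rather than an afterthought.

## The model

For an image `X` and standardized sensor vector `ŝ ∈ R³`:

1. a hierarchical backbone extracts a four-level feature pyramid
   (64², 32², 16², 8² spatial; 64, 128, 192, 256 channels at the reference
   geometry), each level recalibrated by squeeze-and-excitation channel
   attention `w = σ(W₂ δ(W₁ GAP(F)))`;
2. an environmental encoder (3 → 32 → 128 trunk, per-level sigmoid heads)
   emits FiLM-style gates `g_i ∈ (0,1)^{C_i}` applied channel-wise,
   `F̃_{h,w,c} = g_c · F_{h,w,c}` — amplifying visual evidence consistent
   with the current microclimate and suppressing the rest;
3. the levels are fused convexly, `F_ms = Σ_l α_l · proj(F̃^{(l)})`,
   `Σ α_l = 1`, and refined by a cross-scale relational 3×3 convolution;
4. a collaborative head encodes `ŝ` to conditional vectors `c_i = P_i u +
   q_i` that gate each level with a residual identity path,
   `M_i = F̃_i + φ(F̃_i ⊙ G_i)`, upsamples and concatenates the levels
   (640 channels), compresses to 256, and classifies through a
   256 → 128 → 6 softmax head:
   `p = softmax(W₂ ψ(W₁ z + b₁) + b₂)`.

Ablation variants (`no_multiscale`, `no_sensor_prior`, `no_collab_head`,
`concat_fusion`, `vision_only`) remove or replace one component each.
Training uses grouped 70/15/15 splits and grouped 5-fold cross-validation so
images from the same plot/session never straddle partitions; metrics are the
one-vs-rest confusion-matrix Accuracy/Precision/Recall/F1 in macro and
support-weighted sample-level flavours. A synthetic multimodal generator
reproduces the statistical structure of a field campaign — tiny targets on
cluttered backgrounds, sparse scattered individuals versus dense occluded
colonies, class-conditional microclimates, sensor faults, missing records,
clock jitter — so the entire pipeline is testable without any downloads.
The network, including its reverse-mode autodiff core, runs on plain numpy.

See `docs/methods.md` for the complete model description, parameter
defaults and known limitations.

## Worked example

Train the full model and two ablations on the pre-registered desk-scale
study: 360 synthetic images (60 per class) in which classes 2 and 3 are
rendered visually identical and differ only in microclimate preference,
with a fresh held-out collection for density-stratified evaluation:

```python
from pestfusion.studies import ablation_study_config, run_desk_study

for variant in ("full", "no_sensor_prior", "vision_only"):
    r = run_desk_study(variant, ablation_study_config(11), seed=11,
                       eval_cfg=ablation_study_config(1011, density_mix=0.5))
    print(f"{variant:16s} test acc {r['test_accuracy']:.3f}  "
          f"held-out sparse {r['held_out']['sparse_accuracy']:.3f}  "
          f"dense {r['held_out']['dense_accuracy']:.3f}")
```

prints (about 30 s per variant on one CPU core):

```
full             test acc 0.796  held-out sparse 0.878  dense 0.861
no_sensor_prior  test acc 0.741  held-out sparse 0.839  dense 0.822
vision_only      test acc 0.500  held-out sparse 0.472  dense 0.567
```

The full model wins because only the environmental channel separates the
confusable pair, and removing the modulation gates already costs accuracy;
the vision-only variant collapses the pair entirely. Averaged over the five
study seeds (the acceptance suite runs all of them) the full model also
degrades less from sparse to dense colonies than the vision-only variant —
the qualitative ordering the architecture is designed to produce.

The same pipeline is scriptable from the shell:

```bash
pestfusion generate --out data/demo --seed 5
pestfusion train    --data data/demo --out runs/demo --variant full --folds 5
pestfusion ablate   --data data/demo --out runs/ablation --folds 2
```

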