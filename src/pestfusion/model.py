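"""The multi-scale vision-sensor collaborative recognition network.

Architecture, at the reference geometry:

* **Pyramid backbone** — a hierarchical 3x3-conv/BN/ReLU stack producing four
  feature maps at spatial sizes (64, 32, 16, 8)^2 with channel widths
  (64, 128, 192, 256); the deepest stage adds a global-pooling context branch
  (global receptive-field modelling).
* **Channel attention** — per level, squeeze-and-excitation style: global
  average pool -> bottleneck MLP (reduction ratio r) -> sigmoid gates
  w in (0,1)^C multiplying the channels.
* **Environmental prior modulation (FiLM-style)** — the standardized
  three-channel sensor vector (temperature, humidity, illumination) passes a
  3 -> 32 -> 128 trunk; per-level sigmoid heads emit gates g_i in (0,1)^{C_i}
  applied channel-wise to the attended maps. The level-4 head is 128 -> 256.
* **Cross-scale fusion** — each level is 1x1-projected to 256 channels,
  bilinearly upsampled to the level-1 grid and combined convexly with
  softmax-normalised weights (sum alpha_l = 1), then refined by a 3x3
  cross-scale relational convolution.
* **Collaborative head** — a 3 -> 32 -> 64 sensor encoder produces u;
  per-level projections form conditional vectors c_i = P_i u + q_i that gate
  the modulated maps with a residual identity path, M_i = F_i + phi(F_i * G_i)
  (phi = 1x1 conv + ReLU); the M_i are upsampled to the level-1 grid,
  concatenated (640 channels), compressed to 256 by a 1x1 conv + ReLU, and
  the fused multi-scale map is injected residually before global average
  pooling and the 256 -> 128 -> 6 softmax classifier.

Ablation variants remove or replace one component each; ``build_variant``
documents the exact contracts. ``scale_factor`` shrinks spatial sizes and
``width_factor`` channel widths uniformly so the identical topology runs at
desk scale; printed-dimension contracts hold at factors of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

VARIANTS = ("full", "no_multiscale", "no_sensor_prior", "no_collab_head",
            "concat_fusion", "vision_only")

BASE_SIZES = (64, 32, 16, 8)
BASE_CHANNELS = (64, 128, 192, 256)


@dataclass(frozen=True)
class PyramidSpec:
    """Reference geometry of the four-level feature pyramid."""

    scale_factor: float = 1.0
    width_factor: float = 1.0
    attention_ratio: int = 4
    relational_unit: bool = True

    def __post_init__(self):
        if any(s < 1 for s in self.sizes):
            raise ValueError("scale_factor leaves a pyramid level below 1 px")
        if any(c < 1 for c in self.channels):
            raise ValueError("width_factor leaves a level without channels")
        cs = self.channels
        if not all(a < b for a, b in zip(cs, cs[1:])):
            raise ValueError("channel widths must strictly increase")

    @property
    def sizes(self) -> tuple:
        return tuple(int(round(s * self.scale_factor)) for s in BASE_SIZES)

    @property
    def channels(self) -> tuple:
        return tuple(int(round(c * self.width_factor)) for c in BASE_CHANNELS)

    @property
    def input_size(self) -> int:
        """The network ingests images at the level-1 grid (stride-1 entry)."""
        return self.sizes[0]


def _conv_bn_relu(c_in, c_out, rng, stride=1):
    return nn.Sequential(nn.Conv2d(c_in, c_out, 3, rng, stride=stride),
                         nn.BatchNorm2d(c_out), nn.ReLU())


class PyramidBackbone(nn.Module):
    """Hierarchical extractor; level 4 carries a global-context branch."""

    def __init__(self, spec: PyramidSpec, rng):
        super().__init__()
        c1, c2, c3, c4 = spec.channels
        self.spec = spec
        self.stage1 = nn.Sequential(_conv_bn_relu(3, c1, rng),
                                    _conv_bn_relu(c1, c1, rng))
        self.stage2 = _conv_bn_relu(c1, c2, rng, stride=2)
        self.stage3 = _conv_bn_relu(c2, c3, rng, stride=2)
        self.stage4 = _conv_bn_relu(c3, c4, rng, stride=2)
        self.context = nn.Linear(c4, c4, rng)

    def forward(self, x: Tensor) -> list[Tensor]:
        n = x.shape[0]
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"input must be {self.spec.input_size}^2, got {x.shape[2:]}")
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        ctx = self.context(ag.global_avg_pool(f4))
        f4 = ag.relu(f4 + ag.reshape(ctx, (n, -1, 1, 1)))
        return [f1, f2, f3, f4]


class ChannelAttention(nn.Module):
    """Squeeze-and-excitation gating: w = sigmoid(W2 relu(W1 GAP(F)))."""

    def __init__(self, c: int, ratio: int, rng):
        super().__init__()
        hidden = max(c // ratio, 1)
        self.fc1 = nn.Linear(c, hidden, rng)
        self.fc2 = nn.Linear(hidden, c, rng)

    def gates(self, f: Tensor) -> Tensor:
        z = ag.global_avg_pool(f)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(z))))

    def forward(self, f: Tensor) -> Tensor:
        w = self.gates(f)
        return f * ag.reshape(w, (f.shape[0], -1, 1, 1))


class EnvEncoder(nn.Module):
    """Shared 3 -> 32 -> 128 trunk with per-level sigmoid modulation heads."""

    def __init__(self, level_channels, rng, d1=32, d2=128):
        super().__init__()
        self.fc1 = nn.Linear(3, d1, rng)
        self.fc2 = nn.Linear(d1, d2, rng)
        self.heads = [nn.Linear(d2, c, rng) for c in level_channels]

    def forward(self, s: Tensor) -> list[Tensor]:
        if s.shape[-1] != 3:
            raise ValueError(f"sensor vector must have 3 channels, got {s.shape[-1]}")
        e1 = ag.relu(self.fc1(s))
        e2 = ag.relu(self.fc2(e1))
        return [ag.sigmoid(head(e2)) for head in self.heads]


def modulate(f: Tensor, g: Tensor) -> Tensor:
    """Channel-wise broadcast product F~[h,w,c] = g_c * F[h,w,c]."""
    if f.shape[1] != g.shape[-1]:
        raise ValueError(
            f"channel mismatch: feature has {f.shape[1]}, gate has {g.shape[-1]}")
    return f * ag.reshape(g, (f.shape[0], -1, 1, 1))


class MultiScaleFusion(nn.Module):
    """Convex cross-scale fusion plus the relational unit.

    Each level is 1x1-projected to the deepest width, upsampled to the
    level-1 grid and summed with softmax weights alpha (a probability vector
    by construction at every training step).
    """

    def __init__(self, spec: PyramidSpec, rng):
        super().__init__()
        self.spec = spec
        c_out = spec.channels[-1]
        self.proj = [nn.Conv2d(c, c_out, 1, rng, pad=0) for c in spec.channels]
        self.logits = nn.Parameter(np.zeros(len(spec.channels)))
        self.relational = (nn.Conv2d(c_out, c_out, 3, rng)
                           if spec.relational_unit else None)

    def weights(self) -> Tensor:
        return ag.exp(ag.log_softmax(ag.reshape(self.logits, (1, -1))))

    def forward(self, levels: list[Tensor], alpha: Tensor | None = None) -> Tensor:
        size = self.spec.sizes[0]
        if alpha is None:
            alpha = self.weights()                       # (1, L), sums to 1
        maps = []
        for p, f in zip(self.proj, levels):
            m = p(f)
            if m.shape[2] != size:
                m = ag.bilinear_resize(m, size, size)
            maps.append(ag.reshape(m, (1,) + m.shape))
        stack = ag.concat(maps, axis=0)                   # (L, N, C, H, W)
        coeff = ag.reshape(alpha, (-1, 1, 1, 1, 1))
        fused = (stack * coeff).sum(axis=0)
        if self.relational is not None:
            fused = ag.relu(self.relational(fused))
        return fused


class CollabHead(nn.Module):
    """Conditional gating with residual injection, aggregation, classifier."""

    def __init__(self, spec: PyramidSpec, n_classes: int, rng,
                 d_hidden=32, d_shared=64, clf_hidden=128):
        super().__init__()
        self.spec = spec
        cs = spec.channels
        self.enc1 = nn.Linear(3, d_hidden, rng)
        self.enc2 = nn.Linear(d_hidden, d_shared, rng)
        self.proj = [nn.Linear(d_shared, c, rng) for c in cs]       # P_i, q_i
        self.phi = [nn.Conv2d(c, c, 1, rng, pad=0) for c in cs]
        self.compress = nn.Conv2d(sum(cs), cs[-1], 1, rng, pad=0)
        self.clf1 = nn.Linear(cs[-1], clf_hidden, rng)
        self.clf2 = nn.Linear(clf_hidden, n_classes, rng)

    def forward(self, levels: list[Tensor], s: Tensor,
                residual: Tensor | None = None, features: dict | None = None):
        n = s.shape[0]
        u = ag.relu(self.enc2(ag.relu(self.enc1(s))))
        size = self.spec.sizes[0]
        upsampled = []
        for f, proj, phi in zip(levels, self.proj, self.phi):
            c_i = proj(u)                                  # (n, C_i)
            g_map = ag.reshape(c_i, (n, -1, 1, 1))         # spatial broadcast
            m = f + ag.relu(phi(f * g_map))                # residual gating
            if features is not None:
                features.setdefault("gated_maps", []).append(m)
            if m.shape[2] != size:
                m = ag.bilinear_resize(m, size, size)
            upsampled.append(m)
        cat = ag.concat(upsampled, axis=1)
        if features is not None:
            features["concat_channels"] = cat.shape[1]
        fcs = ag.relu(self.compress(cat))
        if residual is not None:
            fcs = fcs + residual
        z = ag.global_avg_pool(fcs)
        if features is not None:
            features["z_dim"] = z.shape[1]
        return self.clf2(ag.relu(self.clf1(z)))


class PooledClassifier(nn.Module):
    """GAP -> (optional raw-sensor concat) -> d -> 128 -> n_classes."""

    def __init__(self, d_in: int, n_classes: int, rng, clf_hidden=128):
        super().__init__()
        self.fc1 = nn.Linear(d_in, clf_hidden, rng)
        self.fc2 = nn.Linear(clf_hidden, n_classes, rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc2(ag.relu(self.fc1(z)))


class PestNet(nn.Module):
    """The recognition network; ``variant`` selects the ablation wiring.

    * ``full`` — everything: attention, per-level environmental modulation,
      cross-scale fusion (injected residually) and the collaborative head.
    * ``no_multiscale`` — classify from the (attended, modulated) level-4
      map alone.
    * ``no_sensor_prior`` — modulation gates fixed at 1; the collaborative
      head still consumes the sensor vector (only modulation is ablated).
    * ``no_collab_head`` — skip conditional gating; classify from the pooled
      fused map.
    * ``concat_fusion`` — conditional gating replaced by appending the raw
      standardized sensor vector to the pooled fused map.
    * ``vision_only`` — no_sensor_prior + no_collab_head combined: the
      forward pass has zero dependence on the sensor vector.
    """

    def __init__(self, spec: PyramidSpec = PyramidSpec(), n_classes: int = 6,
                 variant: str = "full", seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        rng = np.random.default_rng(seed)
        self.spec, self.variant, self.n_classes = spec, variant, n_classes
        self.backbone = PyramidBackbone(spec, rng)
        cs = spec.channels
        if variant == "no_multiscale":
            self.attention = [ChannelAttention(cs[-1], spec.attention_ratio, rng)]
            self.env = EnvEncoder([cs[-1]], rng)
            self.classifier = PooledClassifier(cs[-1], n_classes, rng)
            self.fusion = self.head = None
        else:
            self.attention = [ChannelAttention(c, spec.attention_ratio, rng)
                              for c in cs]
            self.env = (EnvEncoder(cs, rng)
                        if variant not in ("no_sensor_prior", "vision_only")
                        else None)
            self.fusion = MultiScaleFusion(spec, rng)
            if variant in ("full", "no_sensor_prior"):
                # no_sensor_prior ablates only the modulation gates; the
                # collaborative head still consumes the sensor vector
                self.head = CollabHead(spec, n_classes, rng)
                self.classifier = None
            else:
                self.head = None
                extra = 3 if variant == "concat_fusion" else 0
                self.classifier = PooledClassifier(cs[-1] + extra, n_classes, rng)

    @property
    def uses_sensor(self) -> bool:
        return self.variant not in ("vision_only",)

    # -- forward -----------------------------------------------------------
    def forward(self, images: Tensor, sensors: Tensor,
                features: dict | None = None) -> Tensor:
        levels = self.backbone(images)
        if features is not None:
            features["pyramid_shapes"] = [tuple(f.shape[1:]) for f in levels]
        if self.variant == "no_multiscale":
            levels = [levels[-1]]
        levels = [att(f) for att, f in zip(self.attention, levels)]
        if self.env is not None:
            gates = self.env(sensors)
            if features is not None:
                features["modulation_widths"] = [g.shape[-1] for g in gates]
            levels = [modulate(f, g) for f, g in zip(levels, gates)]
        if self.variant == "no_multiscale":
            z = ag.global_avg_pool(levels[0])
            return self.classifier(z)
        fms = self.fusion(levels)
        if self.head is not None:
            return self.head(levels, sensors, residual=fms, features=features)
        z = ag.global_avg_pool(fms)
        if self.variant == "concat_fusion":
            z = ag.concat([z, sensors], axis=1)
        return self.classifier(z)

    # -- numpy conveniences ------------------------------------------------
    @staticmethod
    def _to_tensors(images: np.ndarray, sensors: np.ndarray):
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 4 and x.shape[-1] == 3:          # NHWC -> NCHW
            x = x.transpose(0, 3, 1, 2)
        s = np.asarray(sensors, dtype=np.float32)
        return Tensor(np.ascontiguousarray(x)), Tensor(s)

    def logits(self, images: np.ndarray, sensors: np.ndarray) -> np.ndarray:
        x, s = self._to_tensors(images, sensors)
        return self.forward(x, s).data

    def predict_proba(self, images: np.ndarray, sensors: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Class probabilities (rows sum to 1) in eval mode, batched."""
        was_training = self.training
        self.eval()
        out = []
        n = len(images)
        for lo in range(0, n, batch_size):
            x, s = self._to_tensors(images[lo:lo + batch_size],
                                    sensors[lo:lo + batch_size])
            out.append(ag.softmax(self.forward(x, s)).data)
        self.train(was_training)
        return np.concatenate(out, axis=0)

    def predict(self, images, sensors, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(images, sensors, batch_size).argmax(axis=1)


def build_variant(name: str, spec: PyramidSpec = PyramidSpec(),
                  n_classes: int = 6, seed: int = 0) -> PestNet:
    """Construct one of the named model variants (see :class:`PestNet`)."""
    return PestNet(spec=spec, n_classes=n_classes, variant=name, seed=seed)
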