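"""Synthetic multimodal pest-monitoring data.

Generates paired (image, environment) data with the statistical structure of
field collections from row-crop plots and greenhouses: tiny insect targets
(well under ~2% of image pixels) on cluttered leaf-textured backgrounds, six
pest classes with imbalanced counts, sparse scattered individuals versus
dense aggregated colonies with occlusion, and a three-channel environmental
stream (air temperature degC, relative humidity %RH, illumination lux)
sampled every 10 minutes with class-conditional mean shifts, injected
outliers, missing records, and image/sensor clock mismatch.

Every quantity that downstream stages must recover (outlier mask, missing
mask, target pixel masks, clean sensor values) is retained as ground truth on
the returned dataset, so preprocessing and models can be validated against
what was actually injected. All randomness flows from ``SynthConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .resample import resize_bilinear

# POSIX time origin of the simulated campaign (2023-06-01 00:00 UTC).
CAMPAIGN_START = 1_685_577_600

SENSOR_COLUMNS = ("temperature_c", "humidity_rh", "illumination_lux")
CLASS_NAMES = ("aphid", "thrips", "whitefly", "leafhopper",
               "spider_mite", "leaf_beetle")

# Per-class visual parameters: body colour (RGB in [0,1]), elongation
# (major/minor axis ratio) and speckle micro-texture amplitude.
_CLASS_COLOR = np.array([
    [0.60, 0.78, 0.18],   # aphid: green-yellow
    [0.82, 0.72, 0.12],   # thrips: straw yellow, slender
    [0.95, 0.95, 0.90],   # whitefly: white
    [0.38, 0.80, 0.55],   # leafhopper: pale green
    [0.78, 0.28, 0.18],   # spider mite: rust red
    [0.12, 0.12, 0.20],   # leaf beetle: dark
])
_CLASS_ECC = np.array([1.5, 2.8, 1.3, 2.2, 1.1, 1.7])
_CLASS_SPECKLE = np.array([0.10, 0.15, 0.05, 0.12, 0.20, 0.08])

# Class-conditional microclimate preference offsets (degC, %RH, lux): each
# pest is photographed preferentially under its own local conditions.
_DEFAULT_ENV_SHIFT = np.array([
    [3.0, -6.0, 9000.0],
    [-2.0, 5.0, -6000.0],
    [1.5, 8.0, 4000.0],
    [-1.0, -9.0, -3000.0],
    [4.0, 6.0, -8000.0],
    [-3.5, -3.0, 7000.0],
])


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the package's reference conditions.

    ``n_samples_per_class`` defaults to the field campaign's class imbalance
    (roughly 3:2.5:2:1.5:2:1 across aphid..leaf beetle) at desk scale.
    """

    n_classes: int = 6
    n_samples_per_class: tuple = (64, 49, 40, 31, 37, 22)
    image_size: tuple = (64, 64)
    target_scale_range: tuple = (0.004, 0.02)
    density_mix: float = 0.3            # fraction of groups tagged "dense"
    env_class_shift: np.ndarray = field(
        default_factory=lambda: _DEFAULT_ENV_SHIFT.copy())
    env_noise_sd: tuple = (1.5, 5.0, 4000.0)
    outlier_rate: float = 0.01          # per channel per record
    missing_rate: float = 0.01          # per channel per record
    sensor_period: float = 600.0        # seconds between sensor records
    clock_jitter: float = 120.0         # max |image - slot| offset, seconds
    confusable_pair: tuple | None = None
    target_contrast: float = 1.0        # 0 blends targets invisibly
    group_size: int = 10                # images per plot/session group
    span_seconds: float | None = None   # optional hard cap on campaign span
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.n_samples_per_class) != self.n_classes:
            raise ValueError("n_samples_per_class length must equal n_classes")
        for name in ("density_mix", "outlier_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.target_scale_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("target_scale_range must lie inside (0, 1)")
        if self.sensor_period <= 0:
            raise ValueError("sensor_period must be positive")
        if self.confusable_pair is not None:
            a, b = self.confusable_pair
            if not (0 <= a < self.n_classes and 0 <= b < self.n_classes):
                raise ValueError("confusable_pair ids out of range")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SynthDataset:
    """In-memory multimodal dataset plus injected ground truth."""

    images: list                 # uint8 H x W x 3 arrays
    labels: np.ndarray           # int class ids
    groups: np.ndarray           # int group (plot/session) ids
    density_tags: list           # "sparse" | "dense" per image
    timestamps: np.ndarray       # POSIX seconds per image
    sensors: pd.DataFrame        # timestamp + 3 channels, NaN = missing
    target_masks: list           # bool H x W visible-target masks
    truth: dict                  # clean sensor values, outlier/missing masks
    config: SynthConfig

    def __len__(self):
        return len(self.images)

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "filename": [f"images/{CLASS_NAMES[l]}/{g}_{i}.png"
                         for i, (l, g) in enumerate(zip(self.labels, self.groups))],
            "label": self.labels,
            "group": self.groups,
            "density": self.density_tags,
            "timestamp": self.timestamps,
        })


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _value_noise(rng: np.random.Generator, shape, octaves=(4, 8, 16)) -> np.ndarray:
    """Perlin-style multi-octave value noise in [0, 1]."""
    h, w = shape
    out = np.zeros(shape)
    amp, total = 1.0, 0.0
    for n in octaves:
        coarse = rng.random((n, n))
        out += amp * resize_bilinear(coarse[..., None], h, w)[..., 0]
        total += amp
        amp *= 0.55
    return out / total


def _background(rng: np.random.Generator, shape) -> np.ndarray:
    """Cluttered leaf surface: green/brown value noise plus vein line fields."""
    h, w = shape
    n1 = _value_noise(rng, shape)
    n2 = _value_noise(rng, shape)
    img = np.empty((h, w, 3))
    img[..., 0] = 0.18 + 0.30 * n1                 # R: brownish patches
    img[..., 1] = 0.30 + 0.35 * n2                 # G: foliage
    img[..., 2] = 0.10 + 0.18 * n1 * n2            # B: low
    # leaf veins: a few darker polylines
    for _ in range(rng.integers(4, 8)):
        x0, y0 = rng.random(2) * [w - 1, h - 1]
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.4, 1.2) * max(h, w)
        steps = int(length)
        dx, dy = np.cos(ang), np.sin(ang)
        for s in range(steps):
            x = int(x0 + dx * s + 2 * np.sin(s / 7.0))
            y = int(y0 + dy * s)
            if 0 <= x < w and 0 <= y < h:
                img[y, x] *= 0.75
    return np.clip(img, 0, 1)


def _ellipse_mask(shape, cx, cy, a, b, theta) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _visual_class(class_id: int, cfg: SynthConfig) -> int:
    """Confusable pairs share one set of visual parameters."""
    if cfg.confusable_pair is not None and class_id in cfg.confusable_pair:
        return min(cfg.confusable_pair)
    return class_id


def _draw_target(img, mask_acc, rng, class_id, cfg, center=None,
                 alpha_scale=1.0):
    h, w, _ = img.shape
    vid = _visual_class(class_id, cfg) % len(_CLASS_COLOR)
    lo, hi = cfg.target_scale_range
    area = rng.uniform(lo, hi) * h * w
    ecc = _CLASS_ECC[vid]
    b = np.sqrt(area / (np.pi * ecc))
    a = ecc * b
    if center is None:
        cx, cy = rng.uniform(a, w - a), rng.uniform(a, h - a)
    else:
        cx, cy = center
    theta = rng.uniform(0, np.pi)
    m = _ellipse_mask((h, w), cx, cy, a, b, theta)
    speckle = 1.0 + _CLASS_SPECKLE[vid] * rng.standard_normal((h, w, 1))
    color = _CLASS_COLOR[vid][None, None, :] * speckle
    alpha = cfg.target_contrast * alpha_scale
    img[m] = (1 - alpha) * img[m] + alpha * np.clip(color, 0, 1)[m]
    mask_acc |= m
    return m, (cx, cy, a, b)


def render_image(class_id: int, density: str, rng: np.random.Generator,
                 cfg: SynthConfig):
    """Render one labelled image; returns (uint8 image, visible-target mask).

    "sparse" places 1-3 non-overlapping individuals; "dense" places >=5
    overlapping individuals in an aggregation cluster and then draws
    foliage-coloured occluders over the colony, emulating mutual occlusion.
    """
    if class_id < 0 or class_id >= cfg.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    if density not in ("sparse", "dense"):
        raise ValueError(f"invalid density tag: {density!r}")
    h, w = cfg.image_size
    img = _background(rng, (h, w))
    mask = np.zeros((h, w), dtype=bool)
    if density == "sparse":
        n = int(rng.integers(1, 4))
        for _ in range(n):
            for _attempt in range(20):
                scratch = img.copy()
                trial = np.zeros_like(mask)
                m, _ = _draw_target(scratch, trial, rng, class_id, cfg)
                if not (m & mask).any():
                    img, mask = scratch, mask | m
                    break
    else:
        n = int(rng.integers(5, 9))
        ccx, ccy = rng.uniform(0.3 * w, 0.7 * w), rng.uniform(0.3 * h, 0.7 * h)
        spread = 0.08 * max(h, w)
        for _ in range(n):
            cx = np.clip(ccx + rng.normal(0, spread), 2, w - 3)
            cy = np.clip(ccy + rng.normal(0, spread), 2, h - 3)
            # crowded bodies partially bury each other: reduced contrast
            _draw_target(img, mask, rng, class_id, cfg, center=(cx, cy),
                         alpha_scale=rng.uniform(0.35, 0.7))
        # frequent occlusion: leaf-coloured strips drawn over the colony
        for _ in range(rng.integers(4, 8)):
            ox = np.clip(ccx + rng.normal(0, spread), 2, w - 3)
            oy = np.clip(ccy + rng.normal(0, spread), 2, h - 3)
            om = _ellipse_mask((h, w), ox, oy, rng.uniform(3, 0.18 * w),
                               rng.uniform(1.5, 5.0), rng.uniform(0, np.pi))
            leaf = np.array([0.25, 0.45, 0.15]) * rng.uniform(0.8, 1.2)
            img[om] = np.clip(leaf, 0, 1)
            mask &= ~om
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8), mask


# ---------------------------------------------------------------------------
# environmental stream
# ---------------------------------------------------------------------------

# Population sd of each clean diurnal channel (cycle + measurement noise):
# sensor faults (stuck values, spikes) are extreme on this physical scale.
_CHANNEL_SCALE = np.array([5.9, 11.7, 22500.0])


def _diurnal_base(t: np.ndarray) -> np.ndarray:
    """Clean diurnal curves at POSIX times t -> (len(t), 3) array."""
    hour = ((np.asarray(t, dtype=float) - CAMPAIGN_START) % 86400.0) / 3600.0
    temp = 18.0 + 8.0 * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
    hum = 65.0 - 15.0 * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
    illum = 60000.0 * np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)
    return np.stack([temp, hum, illum], axis=-1)


def sample_environment(class_id: int | None, t: float,
                       rng: np.random.Generator, cfg: SynthConfig):
    """One sensor record at time t.

    Returns (values, outlier_flags, missing_flags, clean) where ``clean`` is
    the noiseless class-shifted base curve. Outliers emulate sensor faults:
    the value is replaced by an excursion 8-12 channel-scale sd away from
    the clean curve. Missing channels are NaN. Illumination is clipped at
    0 lux (night).
    """
    clean = _diurnal_base(np.array([t]))[0]
    if class_id is not None:
        clean = clean + np.asarray(cfg.env_class_shift[class_id], dtype=float)
    sd = np.asarray(cfg.env_noise_sd, dtype=float)
    values = clean + rng.normal(0, sd)
    values[2] = max(values[2], 0.0)
    outlier = rng.random(3) < cfg.outlier_rate
    if outlier.any():
        sign = rng.choice([-1.0, 1.0], size=3)
        excur = clean + sign * rng.uniform(8.0, 12.0, size=3) * _CHANNEL_SCALE
        values = np.where(outlier, excur, values)
    missing = rng.random(3) < cfg.missing_rate
    values = np.where(missing, np.nan, values)
    return values, outlier, missing, clean


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Build the full multimodal dataset from a config.

    Images are laid out on acquisition slots (daytime 08:00-18:00, one slot
    per 3 sensor periods) grouped into plot/session groups; each group
    carries one density tag. The sensor stream covers the whole campaign at
    ``sensor_period`` spacing; records adjacent in time to an image acquire
    that image's class-conditional mean shift.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(np.arange(cfg.n_classes),
                       np.asarray(cfg.n_samples_per_class))
    n = len(labels)
    rng.shuffle(labels)

    n_groups = int(np.ceil(n / cfg.group_size))
    if n_groups < 3:
        n_groups = min(3, n)
    group_of = np.repeat(np.arange(n_groups), cfg.group_size)[:n]
    n_dense = int(round(cfg.density_mix * n_groups))
    dense_groups = set(rng.choice(n_groups, size=n_dense, replace=False).tolist())
    density = ["dense" if g in dense_groups else "sparse" for g in group_of]

    # acquisition slots: daytime only, spaced 3 sensor periods apart
    slot_step = 3.0 * cfg.sensor_period
    day_start, day_len = 8 * 3600.0, 10 * 3600.0
    per_day = max(int(day_len // slot_step), 1)
    slots = np.array([
        CAMPAIGN_START + (i // per_day) * 86400.0 + day_start
        + (i % per_day) * slot_step
        for i in range(n)
    ])
    span = slots[-1] + 86400.0 - CAMPAIGN_START
    if cfg.span_seconds is not None and cfg.span_seconds < span:
        raise ValueError(
            f"span_seconds={cfg.span_seconds} too short for {n} samples "
            f"(need >= {span:.0f} s)")
    jitter = rng.uniform(-cfg.clock_jitter, cfg.clock_jitter, size=n)
    timestamps = slots + jitter

    images, masks = [], []
    for lab, dens in zip(labels, density):
        img, m = render_image(int(lab), dens, rng, cfg)
        images.append(img)
        masks.append(m)

    # sensor stream over the full span
    ts = np.arange(CAMPAIGN_START, CAMPAIGN_START + span + cfg.sensor_period,
                   cfg.sensor_period)
    order = np.argsort(timestamps)
    img_times = timestamps[order]
    img_labels = labels[order]
    idx = np.searchsorted(img_times, ts)
    values = np.empty((len(ts), 3))
    clean = np.empty((len(ts), 3))
    outlier_mask = np.zeros((len(ts), 3), dtype=bool)
    missing_mask = np.zeros((len(ts), 3), dtype=bool)
    for i, t in enumerate(ts):
        cands = []
        if idx[i] < len(img_times):
            cands.append(idx[i])
        if idx[i] > 0:
            cands.append(idx[i] - 1)
        cid = None
        if cands:
            j = min(cands, key=lambda k: abs(img_times[k] - t))
            if abs(img_times[j] - t) <= cfg.sensor_period:
                cid = int(img_labels[j])
        values[i], outlier_mask[i], missing_mask[i], clean[i] = \
            sample_environment(cid, float(t), rng, cfg)

    sensors = pd.DataFrame({"timestamp": ts})
    for k, col in enumerate(SENSOR_COLUMNS):
        sensors[col] = values[:, k]

    truth = {
        "clean_sensor_values": clean,
        "outlier_mask": outlier_mask,
        "missing_mask": missing_mask,
        "env_class_shift": np.asarray(cfg.env_class_shift, dtype=float).copy(),
    }
    return SynthDataset(images=images, labels=labels, groups=group_of,
                        density_tags=density, timestamps=timestamps,
                        sensors=sensors, target_masks=masks, truth=truth,
                        config=cfg)


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def save_dataset(ds: SynthDataset, outdir: str | Path) -> Path:
    """Write images/<class>/<group>_<idx>.png, sensors.csv, manifest.csv."""
    outdir = Path(outdir)
    manifest = ds.manifest
    for fname, img in zip(manifest["filename"], ds.images):
        path = outdir / fname
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(path)
    ds.sensors.to_csv(outdir / "sensors.csv", index=False)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir


def load_dataset(indir: str | Path) -> SynthDataset:
    """Read a dataset written by :func:`save_dataset` (ground truth absent)."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    sensors = pd.read_csv(indir / "sensors.csv")
    images = [np.asarray(Image.open(indir / f).convert("RGB"))
              for f in manifest["filename"]]
    return SynthDataset(
        images=images,
        labels=manifest["label"].to_numpy(),
        groups=manifest["group"].to_numpy(),
        density_tags=list(manifest["density"]),
        timestamps=manifest["timestamp"].to_numpy(dtype=float),
        sensors=sensors,
        target_masks=[None] * len(images),
        truth={},
        config=SynthConfig(n_samples_per_class=tuple(
            np.bincount(manifest["label"], minlength=6))),
    )
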