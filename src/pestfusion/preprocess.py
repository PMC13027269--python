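"""Multimodal preprocessing: image normalisation and small-target
augmentation, sensor cleaning, temporal alignment and standardization.

The sensor pipeline order is fixed: outlier removal -> linear interpolation
of missing records -> nearest-timestamp alignment to each image -> z-score
standardization with statistics fitted on the training partition only.

Conventions (pinned by tests):

* crops are 0-based half-open windows ``[x, x+w) x [y, y+h)``;
* image resampling is bilinear with half-pixel-centred sampling
  (see :mod:`pestfusion.resample`);
* the outlier rule uses the population standard deviation (divide by n);
* equidistant alignment ties break toward the earlier timestamp, the record
  that was causally available when the image was taken;
* boundary missing values are filled by nearest-value extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .resample import resize_bilinear
from .synth import SENSOR_COLUMNS


class AlignmentError(RuntimeError):
    """No sensor record close enough in time to an image."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Image geometry, augmentation bounds and sensor-cleaning thresholds.

    ``lam`` is the outlier threshold in units of the per-channel standard
    deviation (default 3); ``delta_t`` is the maximum tolerated image-sensor
    timestamp deviation in seconds (default 600, one sampling period).
    """

    H0: int = 64
    W0: int = 64
    crop_w: int = 48
    crop_h: int = 48
    alpha_min: float = 0.8
    alpha_max: float = 1.2
    lam: float = 3.0
    delta_t: float = 600.0

    def __post_init__(self):
        if not (0 < self.alpha_min <= self.alpha_max):
            raise ValueError("need 0 < alpha_min <= alpha_max")
        if self.lam <= 0 or self.delta_t <= 0:
            raise ValueError("lam and delta_t must be positive")
        if self.crop_w > self.W0 or self.crop_h > self.H0:
            raise ValueError("crop extent exceeds target resolution")


@dataclass
class SensorStats:
    """Per-channel mean and population standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "SensorStats":
        values = np.asarray(values, dtype=float)
        return cls(mu=values.mean(axis=0), sigma=values.std(axis=0))


@dataclass
class AlignedSample:
    """The unit the model consumes: image + standardized sensor vector."""

    image: np.ndarray        # H0 x W0 x 3 float in [0, 1]
    sensor: np.ndarray       # standardized, length 3
    label: int
    group: int
    density: str
    timestamp: float


# ---------------------------------------------------------------------------
# image operations
# ---------------------------------------------------------------------------

def to_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def resize_image(img: np.ndarray, H0: int, W0: int) -> np.ndarray:
    """Bilinear resample to H0 x W0; channel count preserved."""
    if H0 < 1 or W0 < 1:
        raise ValueError("target resolution must be >= 1")
    img = to_float(img)
    if img.size == 0:
        raise ValueError("empty image")
    return resize_bilinear(img, H0, W0)


def crop_and_rescale(img: np.ndarray, x: int, y: int, w_c: int, h_c: int) -> np.ndarray:
    """Crop the half-open window [x, x+w_c) x [y, y+h_c), rescale back.

    Enlarges the relative pixel footprint of small targets inside the
    window by the ratio of full frame to crop area.
    """
    img = to_float(img)
    h, w, _ = img.shape
    if x < 0 or y < 0 or x + w_c > w or y + h_c > h or w_c < 1 or h_c < 1:
        raise ValueError(
            f"crop window x={x}, y={y}, w={w_c}, h={h_c} out of bounds "
            f"for a {h}x{w} image")
    return resize_bilinear(img[y:y + h_c, x:x + w_c], h, w)


def random_scale_perturbation(img: np.ndarray, rng: np.random.Generator,
                              alpha_min: float, alpha_max: float) -> np.ndarray:
    """Rescale by alpha ~ U(alpha_min, alpha_max), restore the frame size.

    After rescaling, the image is centre-cropped (alpha > 1) or
    edge-replicate padded (alpha < 1) back to its original size so batch
    shapes stay constant. alpha_min = alpha_max = 1 is an exact no-op.
    """
    if not (0 < alpha_min <= alpha_max):
        raise ValueError("need 0 < alpha_min <= alpha_max")
    img = to_float(img)
    h, w, _ = img.shape
    alpha = float(rng.uniform(alpha_min, alpha_max))
    nh, nw = max(int(round(h * alpha)), 1), max(int(round(w * alpha)), 1)
    if (nh, nw) == (h, w):
        return img.copy()
    scaled = resize_bilinear(img, nh, nw)
    if nh >= h:
        top, left = (nh - h) // 2, (nw - w) // 2
        return scaled[top:top + h, left:left + w]
    pt, pl = (h - nh) // 2, (w - nw) // 2
    return np.pad(scaled, ((pt, h - nh - pt), (pl, w - nw - pl), (0, 0)),
                  mode="edge")


def augment(img: np.ndarray, rng: np.random.Generator,
            cfg: PreprocessConfig) -> np.ndarray:
    """Training-time small-target augmentation: random local crop
    magnification followed by random scale perturbation."""
    img = to_float(img)
    h, w, _ = img.shape
    if rng.random() < 0.5:
        x = int(rng.integers(0, w - cfg.crop_w + 1))
        y = int(rng.integers(0, h - cfg.crop_h + 1))
        img = crop_and_rescale(img, x, y, cfg.crop_w, cfg.crop_h)
    return random_scale_perturbation(img, rng, cfg.alpha_min, cfg.alpha_max)


# ---------------------------------------------------------------------------
# sensor cleaning
# ---------------------------------------------------------------------------

def _channel_values(series: pd.DataFrame) -> np.ndarray:
    return series[list(SENSOR_COLUMNS)].to_numpy(dtype=float)


def detect_outliers(series: pd.DataFrame, lam: float,
                    session: np.ndarray | None = None) -> np.ndarray:
    """Flag records with |s_k - mu_k| > lam * sigma_k per channel.

    mu_k and sigma_k (population formula) are computed from the non-missing
    records of each channel, per acquisition session when ``session`` ids
    are given, so a level shift between deployment sites is not mass-flagged.
    A constant channel (sigma = 0) yields no flags and a warning.
    """
    values = _channel_values(series)
    mask = np.zeros_like(values, dtype=bool)
    if session is None:
        session = np.zeros(len(values), dtype=int)
    session = np.asarray(session)
    for sid in np.unique(session):
        rows = session == sid
        for k, name in enumerate(SENSOR_COLUMNS):
            v = values[rows, k]
            ok = ~np.isnan(v)
            if ok.sum() < 2:
                raise ValueError(
                    f"channel {name}: need >=2 non-missing records")
            mu, sigma = v[ok].mean(), v[ok].std()
            if sigma == 0:
                warnings.warn(f"channel {name}: constant within session "
                              f"{sid}, no outliers flagged")
                continue
            flag = np.zeros_like(v, dtype=bool)
            flag[ok] = np.abs(v[ok] - mu) > lam * sigma
            mask[rows, k] = flag
    return mask


def interpolate_missing(series: pd.DataFrame) -> pd.DataFrame:
    """Fill missing records by linear interpolation in time; boundary gaps
    take the nearest observed value. An all-missing channel is an error."""
    out = series.copy()
    t = series["timestamp"].to_numpy(dtype=float)
    for name in SENSOR_COLUMNS:
        v = series[name].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if not ok.any():
            raise ValueError(f"channel {name} has no observed values")
        out[name] = np.interp(t, t[ok], v[ok])
    return out


def clean_series(series: pd.DataFrame, lam: float,
                 session: np.ndarray | None = None) -> pd.DataFrame:
    """Outlier removal then interpolation: the fixed cleaning order."""
    mask = detect_outliers(series, lam, session=session)
    marked = series.copy()
    vals = _channel_values(marked)
    vals[mask] = np.nan
    marked[list(SENSOR_COLUMNS)] = vals
    return interpolate_missing(marked)


def align_sensor_to_image(t_i: float, series: pd.DataFrame,
                          delta_t: float) -> tuple[np.ndarray, float]:
    """Return the sensor record nearest in time to t_i.

    Fails with :class:`AlignmentError` when the nearest record deviates by
    delta_t or more. Equidistant ties go to the earlier record.
    """
    t = series["timestamp"].to_numpy(dtype=float)
    dev = np.abs(t - t_i)
    j = int(np.argmin(dev))          # argmin returns the first (earlier) tie
    if dev[j] >= delta_t:
        raise AlignmentError(
            f"no sensor record within {delta_t} s of image timestamp {t_i} "
            f"(nearest deviates by {dev[j]:.1f} s)")
    return _channel_values(series)[j], float(t[j])


def standardize(values: np.ndarray, stats: SensorStats) -> np.ndarray:
    """Z-score values with the supplied (train-fitted) statistics."""
    bad = np.flatnonzero(stats.sigma <= 0)
    if bad.size:
        names = ", ".join(SENSOR_COLUMNS[k] for k in bad)
        raise ValueError(f"zero standard deviation for channel(s): {names}")
    return (np.asarray(values, dtype=float) - stats.mu) / stats.sigma


# ---------------------------------------------------------------------------
# dataset-level assembly
# ---------------------------------------------------------------------------

def align_dataset(ds, cfg: PreprocessConfig):
    """Clean the sensor stream and align one raw record to every image.

    Returns (images, raw_sensor_vectors, matched_timestamps): images resized
    to (H0, W0) in [0, 1], sensors not yet standardized (that requires the
    train split; see :func:`pestfusion.train.build_samples`).
    """
    cleaned = clean_series(ds.sensors, cfg.lam)
    images = np.stack([resize_image(im, cfg.H0, cfg.W0) for im in ds.images])
    vectors = np.empty((len(ds), 3))
    matched = np.empty(len(ds))
    for i, t_i in enumerate(ds.timestamps):
        vectors[i], matched[i] = align_sensor_to_image(t_i, cleaned, cfg.delta_t)
    return images, vectors, matched
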