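"""Group-aware splitting, cross-validation, the optimization loop and the
ablation grid.

Splitting is always at the level of acquisition groups (plot/session) so
images that share a location and time period never straddle partitions; the
same rule partitions the training set into cross-validation folds.
Standardization statistics for the sensor channels are fitted on the
training partition only and reused verbatim elsewhere — a hard leakage
guard, asserted in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autograd as ag
from . import nn
from .metrics import EvalReport, aggregate_reports
from .model import PestNet, PyramidSpec, build_variant
from .preprocess import (AlignedSample, PreprocessConfig, SensorStats,
                         align_dataset, crop_and_rescale,
                         random_scale_perturbation, standardize)

PARTITIONS = ("train", "val", "test")

log = logging.getLogger("pestfusion.train")


# ---------------------------------------------------------------------------
# group-aware splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Sample-level partition labels plus the group-level assignment."""

    partition: np.ndarray          # "train" | "val" | "test" per sample
    group_partition: dict          # group id -> partition
    ratios: tuple

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.partition == part)


def make_split(groups, labels=None, ratios=(0.70, 0.15, 0.15),
               seed: int = 0) -> SplitPlan:
    """Greedy group-level allocation targeting sample-count ratios.

    Groups are shuffled (seeded), processed largest first, and each is
    assigned to the partition with the largest remaining sample deficit
    (ties break train > val > test). With equal-size groups whose count is
    divisible by the ratios this realizes the target fractions exactly; in
    general the realized fraction is within one maximal group size of the
    target.
    """
    groups = np.asarray(groups)
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    uniq, counts = np.unique(groups, return_counts=True)
    n_parts = sum(r > 0 for r in ratios)
    if len(uniq) < n_parts:
        raise ValueError(
            f"need at least {n_parts} groups to honor all partitions, "
            f"got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    order = order[np.argsort(-counts[order], kind="stable")]
    deficits = np.array(ratios, dtype=float) * len(groups)
    assigned = {}
    for gi in order:
        p = int(np.argmax(deficits))           # first max: train > val > test
        assigned[uniq[gi]] = PARTITIONS[p]
        deficits[p] -= counts[gi]
    partition = np.array([assigned[g] for g in groups])
    for part, r in zip(PARTITIONS, ratios):
        if r > 0 and not (partition == part).any():
            raise ValueError(f"partition {part} received no groups")
    return SplitPlan(partition=partition, group_partition=assigned,
                     ratios=tuple(ratios))


def make_folds(groups, k: int = 5, seed: int = 0) -> np.ndarray:
    """Group-level k-fold assignment for the training samples.

    Returns a fold id in 0..k-1 per sample; every group lands in exactly
    one fold and fold sizes are balanced greedily (largest group first to
    the currently smallest fold).
    """
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < k:
        raise ValueError(f"need at least {k} groups for {k} folds, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    order = order[np.argsort(-counts[order], kind="stable")]
    sizes = np.zeros(k)
    fold_of_group = {}
    for gi in order:
        f = int(np.argmin(sizes))
        fold_of_group[uniq[gi]] = f
        sizes[f] += counts[gi]
    return np.array([fold_of_group[g] for g in groups])


# ---------------------------------------------------------------------------
# sample assembly
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Preprocessed samples ready for the network."""

    images: np.ndarray            # (N, H0, W0, 3) float in [0, 1]
    sensors: np.ndarray           # (N, 3) standardized
    labels: np.ndarray
    groups: np.ndarray
    density: np.ndarray
    timestamps: np.ndarray

    def __len__(self):
        return len(self.labels)

    def subset(self, idx) -> "SampleSet":
        return SampleSet(self.images[idx], self.sensors[idx], self.labels[idx],
                         self.groups[idx], self.density[idx], self.timestamps[idx])

    def to_aligned_samples(self) -> list[AlignedSample]:
        return [AlignedSample(image=self.images[i], sensor=self.sensors[i],
                              label=int(self.labels[i]), group=self.groups[i],
                              density=str(self.density[i]),
                              timestamp=float(self.timestamps[i]))
                for i in range(len(self))]


def build_samples(ds, pcfg: PreprocessConfig, plan: SplitPlan):
    """Preprocess a synthetic/loaded dataset into per-partition SampleSets.

    Sensor statistics are fitted on the raw aligned vectors of the training
    partition only and applied to every partition.
    """
    images, vectors, matched = align_dataset(ds, pcfg)
    train_idx = plan.indices("train")
    stats = SensorStats.fit(vectors[train_idx])
    std_vectors = standardize(vectors, stats)
    density = np.asarray(ds.density_tags)
    out = {}
    for part in PARTITIONS:
        idx = plan.indices(part)
        out[part] = SampleSet(
            images=images[idx].astype(np.float32),
            sensors=std_vectors[idx].astype(np.float32),
            labels=np.asarray(ds.labels)[idx],
            groups=np.asarray(ds.groups)[idx],
            density=density[idx],
            timestamps=np.asarray(ds.timestamps)[idx],
        )
    return out, stats


def build_eval_set(ds, pcfg: PreprocessConfig, stats: SensorStats) -> SampleSet:
    """Preprocess a whole dataset as one evaluation set using externally
    fitted (training) standardization statistics — e.g. a freshly generated
    held-out collection for density-stratified evaluation."""
    images, vectors, _ = align_dataset(ds, pcfg)
    return SampleSet(
        images=images.astype(np.float32),
        sensors=standardize(vectors, stats).astype(np.float32),
        labels=np.asarray(ds.labels),
        groups=np.asarray(ds.groups),
        density=np.asarray(ds.density_tags),
        timestamps=np.asarray(ds.timestamps),
    )


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer settings: Adam with plateau lr-decay keyed to validation
    macro-F1, returning the best-validation checkpoint."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    augment: bool = True
    lr_factor: float = 0.5
    lr_patience: int = 4
    min_lr: float = 1e-5

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) < 0:
            raise ValueError("learning_rate, batch_size, epochs must be >= 0")


def _augment_batch(images: np.ndarray, rng, pcfg: PreprocessConfig) -> np.ndarray:
    out = np.empty_like(images)
    for i, img in enumerate(images):
        a = img.astype(np.float64)
        if rng.random() < 0.5:
            x = int(rng.integers(0, pcfg.W0 - pcfg.crop_w + 1))
            y = int(rng.integers(0, pcfg.H0 - pcfg.crop_h + 1))
            a = crop_and_rescale(a, x, y, pcfg.crop_w, pcfg.crop_h)
        a = random_scale_perturbation(a, rng, pcfg.alpha_min, pcfg.alpha_max)
        out[i] = a.astype(images.dtype)
    return out


def train(model: PestNet, train_set: SampleSet, val_set: SampleSet | None,
          cfg: TrainConfig, pcfg: PreprocessConfig | None = None):
    """Fit the model; returns (model, history).

    History records per-epoch training loss, training accuracy, validation
    macro-F1 and the learning rate. The best-validation weights are restored
    at the end (or the final weights when no validation set is supplied).
    """
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"loss": [], "train_acc": [], "val_f1": [], "lr": []}
    best_f1, best_state, since_best = -np.inf, None, 0
    n = len(train_set)
    if pcfg is None:
        h = train_set.images.shape[1]
        c = max(3 * h // 4, 1)
        pcfg = PreprocessConfig(H0=h, W0=train_set.images.shape[2],
                                crop_w=c, crop_h=c)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            imgs = train_set.images[idx]
            if cfg.augment:
                imgs = _augment_batch(imgs, rng, pcfg)
            x, s = model._to_tensors(imgs, train_set.sensors[idx])
            logits = model.forward(x, s)
            loss = ag.softmax_cross_entropy(logits, train_set.labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}: "
                    f"loss={loss.data!r}, lr={opt.lr}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == train_set.labels[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)
        history["lr"].append(opt.lr)
        if val_set is not None and len(val_set):
            report = evaluate(model, val_set)
            f1 = report.macro["f1"]
            history["val_f1"].append(f1)
            if f1 > best_f1 + 1e-12:
                best_f1, best_state, since_best = f1, model.state_dict(), 0
            else:
                since_best += 1
                if since_best >= cfg.lr_patience and opt.lr > cfg.min_lr:
                    opt.lr = max(opt.lr * cfg.lr_factor, cfg.min_lr)
                    since_best = 0
        else:
            history["val_f1"].append(np.nan)
        log.debug("epoch %d: loss=%.4f train_acc=%.3f val_f1=%s lr=%.2e",
                  epoch, history["loss"][-1], history["train_acc"][-1],
                  f"{history['val_f1'][-1]:.3f}", opt.lr)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def evaluate(model: PestNet, sample_set: SampleSet) -> EvalReport:
    """Confusion matrix and all metric flavours on a labelled sample set."""
    pred = model.predict(sample_set.images, sample_set.sensors)
    return EvalReport.from_predictions(sample_set.labels, pred, model.n_classes)


def density_stratified_eval(model: PestNet, sample_set: SampleSet) -> dict:
    """Separate reports for the sparse and dense strata plus metric deltas.

    A stratum with no samples is reported as None; if both are empty the
    input is rejected.
    """
    out = {}
    for tag in ("sparse", "dense"):
        idx = np.flatnonzero(sample_set.density == tag)
        out[tag] = evaluate(model, sample_set.subset(idx)) if len(idx) else None
    if out["sparse"] is None and out["dense"] is None:
        raise ValueError("no density tags present in the evaluation set")
    if out["sparse"] is not None and out["dense"] is not None:
        out["delta"] = {m: out["sparse"].overall[m] - out["dense"].overall[m]
                        for m in out["sparse"].overall}
    else:
        out["delta"] = None
    return out


# ---------------------------------------------------------------------------
# cross-validation and the ablation grid
# ---------------------------------------------------------------------------

def cross_validate(variant: str, sets: dict, folds: np.ndarray | None,
                   cfg: TrainConfig, spec: PyramidSpec,
                   n_classes: int = 6) -> list[EvalReport]:
    """Train per fold on the shared split; evaluate each run on the test set.

    ``folds=None`` runs a single holdout fit using the validation partition.
    """
    train_all = sets["train"]
    reports = []
    if folds is None:
        model = build_variant(variant, spec, n_classes=n_classes, seed=cfg.seed)
        model, _ = train(model, train_all, sets.get("val"), cfg)
        return [evaluate(model, sets["test"])]
    for f in np.unique(folds):
        tr = train_all.subset(folds != f)
        va = train_all.subset(folds == f)
        model = build_variant(variant, spec, n_classes=n_classes,
                              seed=cfg.seed + int(f))
        model, _ = train(model, tr, va, cfg)
        reports.append(evaluate(model, sets["test"]))
    return reports


def run_ablation_grid(variants, sets: dict, folds: np.ndarray | None,
                      cfg: TrainConfig, spec: PyramidSpec,
                      n_classes: int = 6) -> pd.DataFrame:
    """Fold-mean +/- sd of every metric for each model variant.

    All variants share the same split plan and folds so differences are
    attributable to architecture, not partitioning.
    """
    if len(variants) < 1:
        raise ValueError("need at least one variant")
    rows = []
    for v in variants:
        reports = cross_validate(v, sets, folds, cfg, spec, n_classes)
        row = {"variant": v}
        row.update(aggregate_reports(reports, "overall"))
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
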