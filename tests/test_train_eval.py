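"""Group-aware splitting, metrics against brute-force and sklearn oracles,
leakage guards, and the training loop's contracts."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from pestfusion import (EvalReport, PreprocessConfig, PyramidSpec, SampleSet,
                        SynthConfig, TrainConfig, build_samples, build_variant,
                        density_stratified_eval, generate_dataset, make_folds,
                        make_split, run_ablation_grid, train)
from pestfusion.metrics import (binary_counts, macro_metrics,
                                overall_metrics, per_class_metrics)
from pestfusion.preprocess import SensorStats, align_dataset

DESK = PyramidSpec(scale_factor=0.25, width_factor=0.25)
PREP = PreprocessConfig(H0=16, W0=16, crop_w=12, crop_h=12)


# -- splitting ---------------------------------------------------------------

def test_split_exact_ratios_on_equal_groups():
    groups = np.repeat(np.arange(100), 10)
    labels = np.tile(np.arange(10), 100)
    plan = make_split(groups, labels, (0.70, 0.15, 0.15), seed=3)
    n = len(groups)
    assert (plan.partition == "train").sum() == 0.70 * n
    assert (plan.partition == "val").sum() == 0.15 * n
    assert (plan.partition == "test").sum() == 0.15 * n


def test_split_has_zero_group_leakage():
    rng = np.random.default_rng(5)
    groups = rng.integers(0, 40, size=500)
    plan = make_split(groups, seed=1)
    for g in np.unique(groups):
        parts = np.unique(plan.partition[groups == g])
        assert len(parts) == 1


def test_split_deterministic_and_validates():
    groups = np.repeat(np.arange(10), 4)
    a = make_split(groups, seed=9)
    b = make_split(groups, seed=9)
    assert np.array_equal(a.partition, b.partition)
    with pytest.raises(ValueError, match="at least 3 groups"):
        make_split(np.array([0, 0, 1, 1]))
    with pytest.raises(ValueError, match="sum to 1"):
        make_split(groups, ratios=(0.5, 0.2, 0.2))


def test_split_unequal_groups_within_greedy_bound():
    rng = np.random.default_rng(11)
    for trial in range(10):
        sizes = rng.integers(1, 30, size=30)
        groups = np.repeat(np.arange(30), sizes)
        plan = make_split(groups, seed=trial)
        n = len(groups)
        realized = (plan.partition == "train").sum() / n
        assert abs(realized - 0.70) <= sizes.max() / n


def test_folds_partition_training_groups():
    groups = np.repeat(np.arange(5), 3)
    folds = make_folds(groups, k=5, seed=0)
    assert set(folds) == set(range(5))
    for g in np.unique(groups):
        assert len(np.unique(folds[groups == g])) == 1  # one fold per group
    # union of folds = all samples; pairwise disjoint by construction
    assert len(folds) == len(groups)
    with pytest.raises(ValueError, match="at least 5 groups"):
        make_folds(np.array([0, 1, 2, 3]), k=5)


def test_folds_balance_on_many_groups():
    rng = np.random.default_rng(2)
    sizes = rng.integers(5, 15, size=50)
    groups = np.repeat(np.arange(50), sizes)
    folds = make_folds(groups, k=5, seed=4)
    counts = np.bincount(folds, minlength=5)
    assert np.ptp(counts) <= sizes.max()


# -- metrics -----------------------------------------------------------------

def bruteforce_metrics(conf):
    """Independent enumeration of TP/TN/FP/FN and the four metrics."""
    n_classes = conf.shape[0]
    n = conf.sum()
    out = {}
    for c in range(n_classes):
        tp = conf[c, c]
        fp = sum(conf[r, c] for r in range(n_classes) if r != c)
        fn = sum(conf[c, r] for r in range(n_classes) if r != c)
        tn = n - tp - fp - fn
        acc = (tp + tn) / (tp + tn + fp + fn)
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = (2 * prec * rec / (prec + rec)
              if np.isfinite(prec) and np.isfinite(rec) and prec + rec > 0
              else (0.0 if np.isfinite(prec) and np.isfinite(rec) else np.nan))
        out[c] = (acc, prec, rec, f1)
    return out


def test_worked_three_class_example():
    conf = np.array([[8, 1, 1], [2, 7, 1], [0, 2, 8]])
    per = per_class_metrics(conf)
    assert per.loc[0, "precision"] == pytest.approx(0.8)
    assert per.loc[0, "recall"] == pytest.approx(0.8)
    assert per.loc[0, "f1"] == pytest.approx(0.8)
    tp, fp, fn, tn = binary_counts(conf, 0)
    assert (tp, fp, fn, tn) == (8, 2, 2, 18)
    assert per.loc[0, "accuracy"] == pytest.approx(26 / 30)


def test_metrics_match_bruteforce_and_sklearn(rng):
    for _ in range(50):
        k = int(rng.integers(2, 7))
        conf = rng.integers(0, 12, size=(k, k))
        if conf.sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per = per_class_metrics(conf)
            overall = overall_metrics(conf)
        ref = bruteforce_metrics(conf)
        for c in range(k):
            for name, val in zip(("accuracy", "precision", "recall", "f1"), ref[c]):
                mine = per.loc[c, name]
                assert (np.isnan(val) and np.isnan(mine)) or mine == pytest.approx(val, abs=1e-12)
        # sklearn cross-check on expanded label vectors
        y_true = np.repeat(np.arange(k), conf.sum(axis=1))
        y_pred = np.concatenate([np.repeat(np.arange(k), conf[r])
                                 for r in range(k)])
        if len(y_true) == 0 or set(y_true) != set(range(k)):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="weighted", zero_division=np.nan)
        if not (np.isnan(p) or np.isnan(overall["precision"])):
            assert overall["precision"] == pytest.approx(p, abs=1e-9)
        assert overall["recall"] == pytest.approx(r, abs=1e-9)


def test_macro_bounded_by_per_class_extremes(rng):
    conf = rng.integers(1, 20, size=(6, 6))
    per = per_class_metrics(conf)
    mac = macro_metrics(per)
    for m in ("accuracy", "precision", "recall", "f1"):
        assert per[m].min() - 1e-12 <= mac[m] <= per[m].max() + 1e-12


def test_absent_class_reported_undefined_with_warning():
    y_true = [0, 0, 1, 1]
    y_pred = [0, 0, 1, 1]
    with pytest.warns(UserWarning, match="absent"):
        report = EvalReport.from_predictions(y_true, y_pred, n_classes=3)
    assert np.isnan(report.per_class.loc[2, "recall"])
    assert report.macro["recall"] == pytest.approx(1.0)  # NaN excluded


def test_perfect_predictions_score_one():
    y = np.repeat(np.arange(6), 4)
    report = EvalReport.from_predictions(y, y, n_classes=6)
    for flavour in (report.macro, report.overall):
        for m in ("accuracy", "precision", "recall", "f1"):
            assert flavour[m] == pytest.approx(1.0)
    assert report.confusion.sum() == report.n == 24


def test_f1_is_harmonic_mean_of_own_p_and_r(rng):
    conf = rng.integers(0, 15, size=(6, 6)) + np.eye(6, dtype=int)
    per = per_class_metrics(conf)
    for c in range(6):
        p, r = per.loc[c, "precision"], per.loc[c, "recall"]
        if np.isfinite(p) and np.isfinite(r) and p + r > 0:
            assert per.loc[c, "f1"] == pytest.approx(2 * p * r / (p + r))


# -- training loop -----------------------------------------------------------

class _StubModel:
    """Duck-typed predictor for evaluation-only tests."""

    n_classes = 6

    def __init__(self, preds):
        self._preds = np.asarray(preds)

    def predict(self, images, sensors, batch_size=64):
        return self._preds[:len(images)]


def _tiny_sets(seed=0, n_per_class=6):
    cfg = SynthConfig(n_samples_per_class=(n_per_class,) * 6, group_size=4,
                      seed=seed)
    ds = generate_dataset(cfg)
    plan = make_split(ds.groups, ds.labels, seed=seed)
    sets, stats = build_samples(ds, PREP, plan)
    return ds, plan, sets, stats


def test_standardization_fit_on_training_partition_only():
    ds, plan, sets, stats = _tiny_sets(seed=1)
    _, vectors, _ = align_dataset(ds, PREP)
    expect = SensorStats.fit(vectors[plan.indices("train")])
    assert np.allclose(stats.mu, expect.mu)
    assert np.allclose(stats.sigma, expect.sigma)
    # train-partition standardized vectors have zero mean / unit sd
    assert np.allclose(sets["train"].sensors.mean(axis=0), 0, atol=1e-5)
    assert np.allclose(sets["train"].sensors.std(axis=0), 1, atol=1e-5)
    # and the test partition was standardized with the SAME stats
    got = sets["test"].sensors
    manual = (vectors[plan.indices("test")] - stats.mu) / stats.sigma
    assert np.allclose(got, manual, atol=1e-5)


def test_zero_learning_rate_leaves_parameters_unchanged():
    _, _, sets, _ = _tiny_sets(seed=2)
    model = build_variant("vision_only", DESK, seed=0)
    before = {k: v.copy() for k, v in model.state_dict().items()
              if not k.endswith(("running_mean", "running_var"))}
    cfg = TrainConfig(learning_rate=0.0, epochs=1, seed=0, augment=False)
    train(model, sets["train"], None, cfg)
    after = model.state_dict()
    for k, v in before.items():
        assert np.array_equal(v, after[k]), k


def test_training_is_deterministic_under_seed():
    _, _, sets, _ = _tiny_sets(seed=3)
    cfg = TrainConfig(epochs=2, seed=5)
    results = []
    for _ in range(2):
        m = build_variant("vision_only", DESK, seed=7)
        m, hist = train(m, sets["train"], sets["val"], cfg)
        results.append((m.state_dict(), hist["loss"]))
    assert results[0][1] == results[1][1]
    for k in results[0][0]:
        assert np.array_equal(results[0][0][k], results[1][0][k]), k


def test_sanity_fit_memorizes_small_strong_signal_set():
    """With a strong visual signal the model reaches high training accuracy."""
    cfg = SynthConfig(n_samples_per_class=(10,) * 6, group_size=5, seed=4)
    ds = generate_dataset(cfg)
    plan = make_split(ds.groups, ds.labels, seed=4)
    sets, _ = build_samples(ds, PREP, plan)
    model = build_variant("full", DESK, seed=0)
    tcfg = TrainConfig(epochs=20, seed=0, augment=False)
    model, hist = train(model, sets["train"], None, tcfg)
    assert max(hist["train_acc"]) > 0.9


def test_nonfinite_loss_aborts_with_diagnostics():
    _, _, sets, _ = _tiny_sets(seed=6)
    model = build_variant("vision_only", DESK, seed=0)
    model.classifier.fc2.weight.data[...] = np.inf
    with pytest.raises(RuntimeError, match="non-finite loss"):
        train(model, sets["train"], None, TrainConfig(epochs=1, seed=0))


def test_density_stratified_eval_contracts():
    labels = np.repeat(np.arange(6), 4)
    n = len(labels)
    base = SampleSet(images=np.zeros((n, 4, 4, 3), dtype=np.float32),
                     sensors=np.zeros((n, 3), dtype=np.float32),
                     labels=labels, groups=np.zeros(n, dtype=int),
                     density=np.array(["sparse"] * n),
                     timestamps=np.zeros(n))
    stub = _StubModel(labels)
    out = density_stratified_eval(stub, base)
    assert out["dense"] is None and out["delta"] is None
    assert out["sparse"].overall["accuracy"] == 1.0
    # identical predictions in identically composed strata -> zero delta
    half = np.array(["sparse", "dense"] * (n // 2))
    mixed = SampleSet(base.images, base.sensors, labels, base.groups,
                      half, base.timestamps)
    out = density_stratified_eval(_StubModel(labels), mixed)
    assert out["delta"]["accuracy"] == pytest.approx(0.0)
    empty = SampleSet(base.images[:0], base.sensors[:0], labels[:0],
                      base.groups[:0], np.array([]), base.timestamps[:0])
    with pytest.raises(ValueError):
        density_stratified_eval(stub, empty)


def test_ablation_grid_single_variant_single_fold():
    _, _, sets, _ = _tiny_sets(seed=8)
    cfg = TrainConfig(epochs=1, seed=0, augment=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = run_ablation_grid(["vision_only"], sets, None, cfg, DESK)
    assert list(table.index) == ["vision_only"]
    expect_cols = {f"{m}_{s}" for m in ("accuracy", "precision", "recall", "f1")
                   for s in ("mean", "sd")}
    assert expect_cols == set(table.columns)
    assert table.loc["vision_only", "accuracy_sd"] == 0.0  # single fold


# -- property tests ----------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st

from pestfusion.metrics import confusion_matrix, overall_metrics


@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                min_size=1, max_size=200))
@settings(derandomize=True, deadline=None, max_examples=50)
def test_overall_accuracy_equals_direct_fraction(pairs):
    y_true, y_pred = map(np.array, zip(*pairs))
    conf = confusion_matrix(y_true, y_pred, 6)
    assert conf.sum() == len(pairs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        overall = overall_metrics(conf)
    assert overall["accuracy"] == pytest.approx((y_true == y_pred).mean())
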