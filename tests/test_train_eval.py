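"""Schedule, folds, confusion metrics, training loop, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegmrcnn.data import EpochSet
from eegmrcnn.models import ModelSpec, build_model
from eegmrcnn.nn import Tensor
from eegmrcnn.train_eval import (
    ConfusionCounts,
    TrainConfig,
    confusion,
    cross_validate,
    evaluate,
    kfold_split,
    lr_at,
    metrics,
    seed_replicate_ttest,
    train,
)


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------


class TestSchedule:
    def test_anchor_values_exact(self):
        cfg = TrainConfig()
        assert lr_at(cfg, 0) == pytest.approx(5e-5, abs=0)
        assert lr_at(cfg, 20) == pytest.approx(1e-3, abs=0)
        assert lr_at(cfg, 200) == pytest.approx(5e-4, rel=1e-12)

    def test_monotone_up_then_down(self):
        cfg = TrainConfig()
        lrs = [lr_at(cfg, e) for e in range(cfg.max_epochs + 1)]
        warm = lrs[: cfg.warmup_epochs + 1]
        decay = lrs[cfg.warmup_epochs :]
        assert all(a <= b for a, b in zip(warm, warm[1:]))
        assert all(a >= b for a, b in zip(decay, decay[1:]))

    def test_continuous_at_warmup_boundary(self):
        cfg = TrainConfig()
        eps = 1e-6
        assert lr_at(cfg, cfg.warmup_epochs - eps) == pytest.approx(
            lr_at(cfg, cfg.warmup_epochs + eps), rel=1e-4
        )

    def test_out_of_range_epoch_rejected(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            lr_at(cfg, -1)
        with pytest.raises(ValueError):
            lr_at(cfg, 201)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_init=1e-3, lr_peak=1e-3)
        with pytest.raises(ValueError):
            TrainConfig(warmup_epochs=300)
        with pytest.raises(ValueError):
            TrainConfig(n_folds=1)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def toy_epochs(n=100, frac_dd=0.6, n_subjects=10, seed=0):
    rng = np.random.default_rng(seed)
    n_dd = int(n * frac_dd)
    labels = np.array(["DD"] * n_dd + ["HC"] * (n - n_dd))
    subjects = np.empty(n, dtype=object)
    dd_subj = [f"d{i}" for i in range(n_subjects // 2)]
    hc_subj = [f"h{i}" for i in range(n_subjects // 2)]
    subjects[:n_dd] = [dd_subj[i % len(dd_subj)] for i in range(n_dd)]
    subjects[n_dd:] = [hc_subj[i % len(hc_subj)] for i in range(n - n_dd)]
    data = rng.standard_normal((n, 2, 8))
    return EpochSet(data, labels, subjects.astype(str), 4.0, 2.0)


class TestKFold:
    def test_partition_arithmetic(self):
        ep = toy_epochs(100)
        splits = kfold_split(ep, TrainConfig(seed=0))
        all_test = np.concatenate([te for _, te in splits])
        assert len(all_test) == 100
        assert len(np.unique(all_test)) == 100
        for tr, te in splits:
            assert len(te) == 20
            assert set(tr) | set(te) == set(range(100))
            assert not set(tr) & set(te)

    def test_stratification_within_one(self):
        ep = toy_epochs(100, frac_dd=0.6)
        for _, te in kfold_split(ep, TrainConfig(seed=1)):
            n_dd = int(np.sum(ep.labels[te] == "DD"))
            assert abs(n_dd - 12) <= 1

    def test_subject_level_whole_subjects(self):
        ep = toy_epochs(100, frac_dd=0.5, n_subjects=10)
        cfg = TrainConfig(fold_unit="subject_level", seed=0)
        for tr, te in kfold_split(ep, cfg):
            assert not set(ep.subject_ids[tr]) & set(ep.subject_ids[te])
            assert len(set(ep.subject_ids[te])) == 2

    def test_subject_level_no_leakage_many_seeds(self):
        ep = toy_epochs(120, frac_dd=0.5, n_subjects=12)
        for seed in range(100):
            cfg = TrainConfig(fold_unit="subject_level", seed=seed)
            for tr, te in kfold_split(ep, cfg):
                assert not set(ep.subject_ids[tr]) & set(ep.subject_ids[te])

    def test_class_missing_from_train_rejected(self):
        # a single subject per class collapses one fold's train set
        ep = toy_epochs(12, frac_dd=11 / 12, n_subjects=2)
        cfg = TrainConfig(fold_unit="subject_level", n_folds=2, seed=0)
        with pytest.raises(ValueError, match="absent"):
            kfold_split(ep, cfg)


# ---------------------------------------------------------------------------
# Confusion + metrics
# ---------------------------------------------------------------------------


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion(["DD"] * 5, ["DD"] * 5, positive_class="DD")
        assert (c.TP, c.FP, c.FN, c.TN) == (5, 0, 0, 0)

    def test_hand_enumerated_example(self):
        c = confusion(["DD", "DD", "HC", "HC"], ["DD", "HC", "DD", "HC"], "DD")
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 1)

    def test_swapping_positive_class(self):
        pred = ["DD", "DD", "HC", "DD", "HC"]
        act = ["DD", "HC", "HC", "DD", "DD"]
        c_dd = confusion(pred, act, "DD")
        c_hc = confusion(pred, act, "HC")
        assert (c_dd.TP, c_dd.FP, c_dd.FN, c_dd.TN) == (
            c_hc.TN, c_hc.FN, c_hc.FP, c_hc.TP)
        s = c_dd.swapped()
        assert (s.TP, s.FP, s.FN, s.TN) == (c_hc.TP, c_hc.FP, c_hc.FN, c_hc.TN)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="XX"):
            confusion(["DD", "XX"], ["DD", "HC"])
        with pytest.raises(ValueError, match="length"):
            confusion(["DD"], ["DD", "HC"])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(50, 0, 0, 50))
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0

    def test_worked_example(self):
        m = metrics(ConfusionCounts(TP=3, FP=1, FN=2, TN=4))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 3 / (2 * 3 + 1 + 2))

    def test_zero_denominator_sentinel(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, FN=0, TN=10))
        assert m.precision == 0.0 and "precision" in m.undefined
        assert m.accuracy == 1.0
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.integers(0, 500), st.integers(1, 500)))
    def test_matches_sklearn_oracle(self, counts):
        """Dual route: our formulas vs sklearn's metric functions."""
        from sklearn.metrics import (accuracy_score, f1_score,
                                     precision_score, recall_score)

        tp, fp, fn, tn = counts
        actual = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        m = metrics(ConfusionCounts(tp, fp, fn, tn))
        assert m.accuracy == pytest.approx(accuracy_score(actual, pred))
        if tp + fp:
            assert m.precision == pytest.approx(
                precision_score(actual, pred, zero_division=0))
        if tp + fn:
            assert m.recall == pytest.approx(
                recall_score(actual, pred, zero_division=0))
        if 2 * tp + fp + fn:
            assert m.f1 == pytest.approx(f1_score(actual, pred, zero_division=0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(1, 500), st.integers(1, 500),
                     st.integers(1, 500), st.integers(1, 500)))
    def test_f1_is_harmonic_mean_identity(self, counts):
        m = metrics(ConfusionCounts(*counts))
        harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert m.f1 == pytest.approx(harmonic, rel=1e-12)


# ---------------------------------------------------------------------------
# Training loop + cross-validation
# ---------------------------------------------------------------------------


class _MajorityStub:
    """Deterministic stand-in model: always predicts the majority class."""

    def __init__(self, majority_idx=0):
        self.idx = majority_idx

    def eval(self):
        return self

    def __call__(self, x):
        logits = np.zeros((len(x), 2), dtype=np.float32)
        logits[:, self.idx] = 10.0
        return Tensor(logits)


def tiny_model_spec():
    return ModelSpec(conv_filters=(4, 4, 4), se_reduction=4, in_samples=64)


def tiny_epochs(n=60, seed=0, separation=3.0):
    rng = np.random.default_rng(seed)
    labels = np.array(["DD", "HC"] * (n // 2))
    data = rng.standard_normal((n, 6, 64)).astype(np.float64)
    data[labels == "HC"] *= separation
    subjects = np.array([f"s{i % 6}" for i in range(n)])
    return EpochSet(data, labels, subjects, 4.0, 16.0)


class TestTraining:
    def test_lr_trace_matches_schedule(self):
        ep = tiny_epochs()
        cfg = TrainConfig(seed=0, batch_size=16)
        model = build_model(tiny_model_spec(), seed=0)
        _, trace = train(model, ep, cfg, n_epochs=5)
        assert trace["lr"] == [lr_at(cfg, e) for e in range(5)]
        assert len(trace["loss"]) == 5

    def test_separable_data_learned(self):
        ep = tiny_epochs(n=80, separation=4.0)
        cfg = TrainConfig(seed=0, batch_size=16)
        model = build_model(tiny_model_spec(), seed=0)
        _, trace = train(model, ep, cfg, n_epochs=15)
        assert trace["final_train_accuracy"] >= 0.95

    def test_deterministic_loss_trace(self):
        ep = tiny_epochs()
        cfg = TrainConfig(seed=7, batch_size=16)
        traces = []
        for _ in range(2):
            model = build_model(tiny_model_spec(), seed=7)
            _, trace = train(model, ep, cfg, n_epochs=3)
            traces.append(trace["loss"])
        assert traces[0] == traces[1]

    def test_too_many_epochs_rejected(self):
        ep = tiny_epochs()
        model = build_model(tiny_model_spec(), seed=0)
        with pytest.raises(ValueError, match="max_epochs"):
            train(model, ep, TrainConfig(), n_epochs=300)


class TestCrossValidate:
    def test_majority_stub_on_imbalanced_data(self):
        ep = toy_epochs(100, frac_dd=0.6)
        ep.data = np.zeros((100, 6, 64))
        ep = EpochSet(ep.data, ep.labels, ep.subject_ids, 4.0, 16.0)
        cfg = TrainConfig(seed=0)
        rep = cross_validate(
            ep, None, cfg,
            model_factory=lambda seed: _MajorityStub(0),  # always "DD"
            fit_fn=lambda m, d, c: None,
        )
        assert rep.mean["accuracy"] == pytest.approx(0.6)
        assert rep.sd["accuracy"] == pytest.approx(0.0)
        assert rep.mean["recall"] == pytest.approx(1.0)

    def test_fold_confusions_cover_dataset_once(self):
        ep = toy_epochs(100)
        rep = cross_validate(
            ep, None, TrainConfig(seed=0),
            model_factory=lambda seed: _MajorityStub(0),
            fit_fn=lambda m, d, c: None,
        )
        assert sum(c.total for c in rep.fold_confusions) == 100

    def test_same_seed_reproduces_report(self):
        ep = tiny_epochs(n=60)
        cfg = TrainConfig(seed=5, batch_size=16, n_folds=3)
        reps = [
            cross_validate(ep, tiny_model_spec(), cfg, n_epochs=2)
            for _ in range(2)
        ]
        assert reps[0].as_dict() == reps[1].as_dict()


def test_seed_replicate_ttest_detects_difference():
    t, p = seed_replicate_ttest([0.9, 0.91, 0.92], [0.5, 0.52, 0.51])
    assert p < 0.01 and t > 0
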