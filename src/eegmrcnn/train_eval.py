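"""Training protocol, cross-validation, and confusion-matrix metrics.

The training recipe: mini-batches of 32, up to 200 epochs, AdamW with
decoupled weight decay 1e-3, and a warmup learning-rate schedule that ramps
linearly from 5e-5 to 1e-3 over the first 20 epochs and then decays along a
cosine to 5e-4 at the final epoch. Classification quality is assessed by
stratified 5-fold cross-validation; metrics are reported per fold and as
mean +/- SD across folds.

Fold unit matters: ``epoch_level`` folds split individual 4 s epochs (so the
same subject contributes to both train and test — optimistic, matching the
sample-count regime of typical within-cohort studies), while
``subject_level`` folds keep whole subjects together and measure
generalization to unseen people. Epoch-level mode logs a leakage warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .data import EpochSet
from .models import ModelSpec, build_model, predict_proba
from .nn import AdamW
from .nn.layers import cross_entropy

__all__ = [
    "TrainConfig",
    "lr_at",
    "kfold_split",
    "train",
    "evaluate",
    "confusion",
    "metrics",
    "cross_validate",
    "ConfusionCounts",
    "MetricSet",
    "MetricsReport",
    "seed_replicate_ttest",
]

logger = logging.getLogger(__name__)

CLASSES = ("DD", "HC")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 200
    lr_init: float = 5e-5
    lr_peak: float = 1e-3
    warmup_epochs: int = 20
    lr_final: float = 5e-4
    weight_decay: float = 1e-3
    n_folds: int = 5
    fold_unit: str = "epoch_level"  # or "subject_level"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_init < self.lr_peak:
            raise ValueError("lr_init must be < lr_peak")
        if not self.lr_final <= self.lr_peak:
            raise ValueError("lr_final must be <= lr_peak")
        if not 0 < self.warmup_epochs < self.max_epochs:
            raise ValueError("warmup_epochs must be in (0, max_epochs)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.fold_unit not in ("epoch_level", "subject_level"):
            raise ValueError(f"unknown fold_unit {self.fold_unit!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def lr_at(config: TrainConfig, epoch: int | float) -> float:
    """Learning rate at a given training epoch.

    Linear ramp lr_init -> lr_peak over the warmup epochs, then cosine decay
    lr_peak -> lr_final over the remaining epochs. Hits all three anchors
    exactly and is continuous at the warmup boundary.
    """
    if not 0 <= epoch <= config.max_epochs:
        raise ValueError(
            f"epoch {epoch} outside [0, max_epochs={config.max_epochs}]"
        )
    if epoch == 0:
        return config.lr_init
    if epoch == config.warmup_epochs:
        return config.lr_peak
    if epoch == config.max_epochs:
        return config.lr_final
    if epoch < config.warmup_epochs:
        frac = epoch / config.warmup_epochs
        return config.lr_init + (config.lr_peak - config.lr_init) * frac
    span = config.max_epochs - config.warmup_epochs
    frac = (epoch - config.warmup_epochs) / span
    return config.lr_final + (config.lr_peak - config.lr_final) * 0.5 * (
        1.0 + np.cos(np.pi * frac)
    )


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


def kfold_split(
    epochs: EpochSet, config: TrainConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint stratified (train, test) index partitions.

    ``epoch_level`` stratifies individual epochs by class;
    ``subject_level`` assigns whole subjects to folds (stratified by the
    subject's class), so no subject appears in both train and test of any
    fold.
    """
    labels = np.asarray(epochs.labels)
    n = len(labels)
    if config.fold_unit == "epoch_level":
        logger.warning(
            "epoch_level folds: epochs of the same subject can appear in both "
            "train and test; use subject_level folds to measure "
            "generalization to unseen subjects"
        )
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        splits = [
            (np.asarray(tr), np.asarray(te))
            for tr, te in skf.split(np.zeros(n), labels)
        ]
    else:
        subj = np.asarray(epochs.subject_ids)
        uniq, first = np.unique(subj, return_index=True)
        subj_label = {s: labels[i] for s, i in zip(uniq, first)}
        rng = np.random.default_rng(config.seed)
        fold_of: dict[str, int] = {}
        for cls in np.unique(list(subj_label.values())):
            members = sorted(s for s, l in subj_label.items() if l == cls)
            rng.shuffle(members)
            for i, s in enumerate(members):
                fold_of[s] = i % config.n_folds
        splits = []
        for f in range(config.n_folds):
            test_mask = np.array([fold_of[s] == f for s in subj])
            splits.append((np.where(~test_mask)[0], np.where(test_mask)[0]))
    for f, (tr, te) in enumerate(splits):
        missing = set(np.unique(labels)) - set(labels[tr])
        if missing:
            raise ValueError(f"class(es) {missing} absent from fold {f}'s train set")
    return splits


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def encode_labels(labels: np.ndarray, classes: tuple[str, ...] = CLASSES) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[l] for l in labels], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} outside classes {classes}") from exc


def train(
    model: nn.Module,
    train_epochs: EpochSet,
    config: TrainConfig,
    n_epochs: int | None = None,
    classes: tuple[str, ...] = CLASSES,
) -> tuple[nn.Module, dict]:
    """Mini-batch optimization with the warmup/cosine schedule and AdamW.

    Returns the trained model and a trace with per-epoch mean loss, the
    learning rate actually applied each epoch, and the final training
    accuracy. ``n_epochs`` (<= max_epochs) shortens the run; the schedule is
    still evaluated at the true epoch index. A non-finite loss aborts.
    """
    n_epochs = config.max_epochs if n_epochs is None else n_epochs
    if n_epochs > config.max_epochs:
        raise ValueError(f"n_epochs {n_epochs} exceeds max_epochs {config.max_epochs}")
    x = np.asarray(train_epochs.data, dtype=np.float32)
    y = encode_labels(train_epochs.labels, classes)
    opt = AdamW(model.parameters(), lr=config.lr_init, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    trace: dict = {"loss": [], "lr": []}
    model.train()
    for epoch in range(n_epochs):
        lr = lr_at(config, epoch)
        opt.lr = lr
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model(x[idx])
            loss = cross_entropy(logits, y[idx])
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss ({val}) at epoch {epoch}, batch {i // config.batch_size}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(val)
        trace["loss"].append(float(np.mean(losses)))
        trace["lr"].append(lr)
    proba = predict_proba(model, x)
    trace["final_train_accuracy"] = float((proba.argmax(axis=1) == y).mean())
    return model, trace


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN with respect to a declared positive class."""

    TP: int
    FP: int
    FN: int
    TN: int
    positive_class: str = "DD"

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def swapped(self) -> "ConfusionCounts":
        """Counts with the other class treated as positive."""
        other = [c for c in CLASSES if c != self.positive_class]
        return ConfusionCounts(
            TP=self.TN, FP=self.FN, FN=self.FP, TN=self.TP,
            positive_class=other[0] if other else self.positive_class,
        )


def confusion(
    pred_labels,
    actual_labels,
    positive_class: str = "DD",
    classes: tuple[str, ...] = CLASSES,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN from predicted and actual label sequences."""
    pred = np.asarray(pred_labels)
    actual = np.asarray(actual_labels)
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in {classes}")
    for arr, name in ((pred, "pred"), (actual, "actual")):
        bad = set(arr.tolist()) - set(classes)
        if bad:
            raise ValueError(f"{name} labels contain {bad}, outside classes {classes}")
    pos_p = pred == positive_class
    pos_a = actual == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_p & pos_a)),
        FP=int(np.sum(pos_p & ~pos_a)),
        FN=int(np.sum(~pos_p & pos_a)),
        TN=int(np.sum(~pos_p & ~pos_a)),
        positive_class=positive_class,
    )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, precision, recall and F1 as fractions in [0, 1].

    Metrics whose denominator was zero are reported as 0.0 and named in
    ``undefined``.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def metrics(c: ConfusionCounts) -> MetricSet:
    """accuracy=(TP+TN)/total, precision=TP/(TP+FP), recall=TP/(TP+FN),
    f1=2TP/(2TP+FP+FN)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (c.TP + c.TN) / c.total
    prec = ratio(c.TP, c.TP + c.FP, "precision")
    rec = ratio(c.TP, c.TP + c.FN, "recall")
    f1 = ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "f1")
    return MetricSet(acc, prec, rec, f1, tuple(undefined))


def evaluate(
    model: nn.Module,
    epochs: EpochSet,
    positive_class: str = "DD",
    classes: tuple[str, ...] = CLASSES,
) -> tuple[ConfusionCounts, MetricSet]:
    """Predict every epoch and derive the confusion-matrix metric suite."""
    proba = predict_proba(model, np.asarray(epochs.data, dtype=np.float32))
    pred = np.array([classes[i] for i in proba.argmax(axis=1)])
    c = confusion(pred, epochs.labels, positive_class, classes)
    return c, metrics(c)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold metrics with mean and population SD (n_folds denominator)."""

    per_fold: list[MetricSet]
    fold_confusions: list[ConfusionCounts]
    mean: dict[str, float]
    sd: dict[str, float]
    n_folds: int
    positive_class: str
    band: str
    config: dict
    traces: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_fold": [m.as_dict() for m in self.per_fold],
            "fold_confusions": [asdict(c) for c in self.fold_confusions],
            "mean": self.mean,
            "sd": self.sd,
            "n_folds": self.n_folds,
            "positive_class": self.positive_class,
            "band": self.band,
            "config": self.config,
        }


def cross_validate(
    dataset: EpochSet,
    model_spec: ModelSpec | None,
    config: TrainConfig,
    n_epochs: int | None = None,
    positive_class: str = "DD",
    model_factory=None,
    fit_fn=None,
    keep_traces: bool = False,
) -> MetricsReport:
    """k-fold cross-validation of an architecture on an epoch set.

    Each fold builds a fresh model (seeded ``config.seed + fold``), trains it
    on the fold's train split and evaluates on the held-out split. The
    default model comes from ``model_spec``; ``model_factory(seed)`` and
    ``fit_fn(model, train_set, config)`` allow substituting either step
    (e.g. a deterministic stub classifier in tests).
    """
    splits = kfold_split(dataset, config)
    factory = model_factory or (lambda seed: build_model(model_spec, seed=seed))
    fit = fit_fn if fit_fn is not None else (
        lambda m, d, c: train(m, d, c, n_epochs=n_epochs)[1]
    )
    per_fold: list[MetricSet] = []
    confusions: list[ConfusionCounts] = []
    traces: list[dict] = []
    for f, (tr, te) in enumerate(splits):
        model = factory(config.seed + f)
        trace = fit(model, dataset.subset(tr), config)
        c, m = evaluate(model, dataset.subset(te), positive_class)
        per_fold.append(m)
        confusions.append(c)
        if keep_traces and isinstance(trace, dict):
            traces.append(trace)
    names = ("accuracy", "precision", "recall", "f1")
    values = {k: np.array([getattr(m, k) for m in per_fold]) for k in names}
    return MetricsReport(
        per_fold=per_fold,
        fold_confusions=confusions,
        mean={k: float(v.mean()) for k, v in values.items()},
        sd={k: float(v.std(ddof=0)) for k, v in values.items()},
        n_folds=config.n_folds,
        positive_class=positive_class,
        band=str(dataset.band),
        config=asdict(config),
        traces=traces,
    )


def format_report_table(reports: dict[str, MetricsReport]) -> str:
    """Band x metric text table (mean +/- SD per cell)."""
    names = ("accuracy", "f1", "precision", "recall")
    header = f"{'Data':<12}" + "".join(f"{n.capitalize():>20}" for n in names)
    lines = [header, "-" * len(header)]
    for band, rep in reports.items():
        cells = "".join(
            f"{100 * rep.mean[n]:>12.2f} ± {100 * rep.sd[n]:4.2f}%" for n in names
        )
        lines.append(f"{band:<12}" + cells)
    return "\n".join(lines)


def seed_replicate_ttest(acc_a, acc_b):
    """Paired t-test across seed replicates of two conditions; returns
    (t, p). A convenience for comparing e.g. band-wise accuracies."""
    from scipy import stats

    t, p = stats.ttest_rel(np.asarray(acc_a), np.asarray(acc_b))
    return float(t), float(p)
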