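"""Gradient-boosted binary stress classifiers over twelve predictor sets.

Twelve model variants are evaluated: each of the four base signals
(infrared and red log relaxation time, chlorophyll fluorescence,
respiration-rate derivative) alone, with apple mass, and with mass,
firmness and soluble-solids content.  Performance is estimated by
repeated random subsampling — 20 independent stratified 70/30 splits —
reporting mean test and train accuracy, precision, recall and F1 (stress
is the positive class) and mean normalized gain-style importance per
feature.

The boosting backend is scikit-learn's ``GradientBoostingClassifier``
configured to 500 rounds, at most 6 leaves per tree, learning rate 0.05
and the log-loss objective; the backend name is recorded in each report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .timeseries import LABEL_STRESS

__all__ = [
    "BASE_SIGNALS",
    "ALL_PREDICTORS",
    "ModelVariant",
    "ClassifierReport",
    "default_variants",
    "confusion_metrics",
    "make_splits",
    "train_evaluate",
    "run_variant_suite",
]

BASE_SIGNALS = ("tau_star_ir", "tau_star_red", "cf", "d_respiration")
ALL_PREDICTORS = BASE_SIGNALS + ("mass", "firmness", "ssc")

N_ROUNDS = 500
MAX_LEAVES = 6
LEARNING_RATE = 0.05
BACKEND = "sklearn.GradientBoostingClassifier"


@dataclass(frozen=True)
class ModelVariant:
    """One row of the variant registry: an ordered predictor set."""

    variant_id: int
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.variant_id <= 12:
            raise ValueError(f"variant_id must be 1..12, got {self.variant_id}")
        unknown = set(self.predictors) - set(ALL_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictor(s): {sorted(unknown)}")
        n_base = sum(p in BASE_SIGNALS for p in self.predictors)
        if n_base != 1:
            raise ValueError("each variant must contain exactly one base signal")
        extras = tuple(p for p in self.predictors if p not in BASE_SIGNALS)
        tier = (self.variant_id - 1) // 4
        want = {0: (), 1: ("mass",), 2: ("mass", "firmness", "ssc")}[tier]
        if extras != want:
            raise ValueError(
                f"variant {self.variant_id} must carry extra predictors {want}, got {extras}"
            )


def default_variants() -> list[ModelVariant]:
    """The twelve-variant registry: base signal x {none, +mass, +mass/firmness/ssc}."""
    variants = []
    for tier, extras in enumerate([(), ("mass",), ("mass", "firmness", "ssc")]):
        for i, signal in enumerate(BASE_SIGNALS):
            variants.append(ModelVariant(tier * 4 + i + 1, (signal, *extras)))
    return variants


@dataclass(frozen=True)
class ClassifierReport:
    """Mean split-level performance and importances for one variant."""

    variant_id: int
    predictors: tuple[str, ...]
    accuracy: tuple[float, float]  # (test, train)
    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    gain: dict[str, float]
    n_splits: int
    seed: int
    backend: str = BACKEND
    split_metrics: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.gain.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gain values must sum to 1, got {total}")
        for name in ("accuracy", "precision", "recall", "f1"):
            pair = getattr(self, name)
            if not all(0 <= v <= 1 for v in pair):
                raise ValueError(f"{name} values must lie in [0, 1]: {pair}")

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "predictors": list(self.predictors),
            "accuracy_test": self.accuracy[0],
            "accuracy_train": self.accuracy[1],
            "precision_test": self.precision[0],
            "precision_train": self.precision[1],
            "recall_test": self.recall[0],
            "recall_train": self.recall[1],
            "f1_test": self.f1[0],
            "f1_train": self.f1[1],
            "gain": dict(self.gain),
            "n_splits": self.n_splits,
            "seed": self.seed,
            "backend": self.backend,
        }


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Zero-denominator ratios return 0 and set the ``degenerate`` flag.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("all counts are zero")
    degenerate = False
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if degenerate:
        warnings.warn("zero denominator in confusion metrics; reported as 0", stacklevel=2)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "degenerate": degenerate,
    }


def make_splits(
    y: np.ndarray,
    n_splits: int = 20,
    seed: int = 0,
    test_fraction: float = 0.3,
    stratify: bool = True,
    groups: np.ndarray | None = None,
    max_retries: int = 10,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded repeated random 70/30 splits shared across variants.

    Stratified by class by default.  With ``groups`` given, whole groups
    (apples) are assigned to train or test instead of single rows.  A
    split whose training set contains a single class is resampled (up to
    ``max_retries`` times, then an error is raised).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    n = y.size
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_splits):
        for attempt in range(max_retries + 1):
            if groups is not None:
                unique = np.unique(groups)
                shuffled = rng.permutation(unique)
                n_test_groups = max(1, int(round(test_fraction * unique.size)))
                test_groups = set(shuffled[:n_test_groups])
                test_mask = np.array([g in test_groups for g in groups])
            elif stratify:
                test_mask = np.zeros(n, dtype=bool)
                for cls in np.unique(y):
                    idx = np.flatnonzero(y == cls)
                    k = int(round(test_fraction * idx.size))
                    test_mask[rng.permutation(idx)[:k]] = True
            else:
                test_mask = np.zeros(n, dtype=bool)
                test_mask[rng.permutation(n)[: int(round(test_fraction * n))]] = True
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            if np.unique(y[train_idx]).size >= 2 and test_idx.size and train_idx.size:
                break
        else:
            raise RuntimeError("could not draw a two-class training set after retries")
        splits.append((train_idx, test_idx))
    return splits


def _binary_labels(labels: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == LABEL_STRESS).astype(int)
    return arr.astype(int)


def _split_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return confusion_metrics(tp, fp, fn, tn)


def train_evaluate(
    records: pd.DataFrame,
    variant: ModelVariant,
    seed: int = 0,
    n_splits: int = 20,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    stratify: bool = True,
    group_by_apple: bool = False,
    n_rounds: int = N_ROUNDS,
    max_leaf_nodes: int = MAX_LEAVES,
    learning_rate: float = LEARNING_RATE,
) -> ClassifierReport:
    """Train and evaluate one variant over repeated 70/30 splits.

    ``records`` must carry a ``label`` column (strings or 0/1; stress is
    positive) and every predictor of the variant.  Decision threshold is
    0.5 on the predicted stress probability.  Gain importances are
    normalized impurity-gain contributions averaged across splits.
    Fully reproducible from ``seed``.
    """
    missing = sorted(set(variant.predictors) - set(records.columns))
    if missing:
        raise ValueError(f"missing predictor column(s): {', '.join(missing)}")
    if "label" not in records.columns:
        raise ValueError("records must carry a 'label' column")
    y = _binary_labels(records["label"])
    if np.unique(y).size < 2:
        raise ValueError("need both classes present in the labels")
    X = records.loc[:, list(variant.predictors)].to_numpy(dtype=float)

    if splits is None:
        groups = records["apple_id"].to_numpy() if group_by_apple else None
        splits = make_splits(y, n_splits=n_splits, seed=seed, stratify=stratify, groups=groups)

    rows = []
    gains = np.zeros(len(variant.predictors))
    for split_no, (train_idx, test_idx) in enumerate(splits):
        model = GradientBoostingClassifier(
            n_estimators=n_rounds,
            max_leaf_nodes=max_leaf_nodes,
            learning_rate=learning_rate,
            random_state=split_no,  # deterministic given the split sequence
        )
        model.fit(X[train_idx], y[train_idx])
        pred_test = (model.predict_proba(X[test_idx])[:, 1] >= 0.5).astype(int)
        pred_train = (model.predict_proba(X[train_idx])[:, 1] >= 0.5).astype(int)
        m_test = _split_confusion(y[test_idx], pred_test)
        m_train = _split_confusion(y[train_idx], pred_train)
        rows.append(
            {
                "split": split_no,
                **{f"{k}_test": m_test[k] for k in ("accuracy", "precision", "recall", "f1")},
                **{f"{k}_train": m_train[k] for k in ("accuracy", "precision", "recall", "f1")},
            }
        )
        importance = model.feature_importances_
        total = importance.sum()
        if total > 0:
            gains += importance / total
        else:  # no split ever used a feature: fall back to uniform
            gains += np.full(len(variant.predictors), 1.0 / len(variant.predictors))

    split_metrics = pd.DataFrame(rows)
    gains /= len(splits)
    gains /= gains.sum()
    mean = split_metrics.mean()
    return ClassifierReport(
        variant_id=variant.variant_id,
        predictors=variant.predictors,
        accuracy=(float(mean["accuracy_test"]), float(mean["accuracy_train"])),
        precision=(float(mean["precision_test"]), float(mean["precision_train"])),
        recall=(float(mean["recall_test"]), float(mean["recall_train"])),
        f1=(float(mean["f1_test"]), float(mean["f1_train"])),
        gain={p: float(g) for p, g in zip(variant.predictors, gains)},
        n_splits=len(splits),
        seed=seed,
        split_metrics=split_metrics,
    )


def run_variant_suite(
    records: pd.DataFrame,
    seed: int = 0,
    n_splits: int = 20,
    variants: list[ModelVariant] | None = None,
    stratify: bool = True,
    group_by_apple: bool = False,
    n_rounds: int = N_ROUNDS,
) -> list[ClassifierReport]:
    """Evaluate all twelve variants with split assignments shared across them.

    The same seed yields the same splits for every variant, enabling
    paired comparisons of per-split metrics.
    """
    variants = variants if variants is not None else default_variants()
    missing = sorted(set(ALL_PREDICTORS) - set(records.columns))
    if missing:
        raise ValueError(f"records missing candidate predictor(s): {', '.join(missing)}")
    y = _binary_labels(records["label"])
    groups = records["apple_id"].to_numpy() if group_by_apple else None
    splits = make_splits(y, n_splits=n_splits, seed=seed, stratify=stratify, groups=groups)
    return [
        train_evaluate(records, v, seed=seed, n_splits=n_splits, splits=splits, n_rounds=n_rounds)
        for v in variants
    ]
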