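"""Seeded train/test splitting and confusion-matrix performance metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .dataset import ExpressionDataset

log = logging.getLogger(__name__)


@runtime_checkable
class Classifier(Protocol):
    """Anything with a label-returning predict over a dataset."""

    def predict(self, ds: ExpressionDataset) -> Sequence[str]:  # pragma: no cover
        ...


@dataclass(frozen=True)
class SplitSpec:
    """A seeded random holdout split.

    ``train_fraction`` is 0.7 for model screens and 0.8 for triplet screens.
    Stratified splitting (the default) keeps both classes in both parts.
    """

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split(
    ds: ExpressionDataset, spec: SplitSpec
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Partition samples into train/test, deterministically for a given seed.

    The train size is round(train_fraction * n); under stratification the
    per-class counts are apportioned by largest remainder, then clamped so
    both classes appear in both parts.
    """
    rng = np.random.default_rng(spec.seed)
    n = ds.n_samples
    n_train_total = int(round(spec.train_fraction * n))
    n_train_total = min(max(n_train_total, 1), n - 1)

    if not spec.stratified:
        perm = rng.permutation(n)
        train_idx = sorted(perm[:n_train_total].tolist())
        test_idx = sorted(perm[n_train_total:].tolist())
        return ds.subset_samples(train_idx), ds.subset_samples(test_idx)

    classes = sorted(set(ds.labels))
    by_class = {c: [i for i, l in enumerate(ds.labels) if l == c] for c in classes}
    for c, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has < 2 samples; cannot stratify")

    # largest-remainder apportionment of n_train_total across classes
    quotas = {c: spec.train_fraction * len(by_class[c]) for c in classes}
    counts = {c: int(np.floor(quotas[c])) for c in classes}
    leftover = n_train_total - sum(counts.values())
    for c in sorted(classes, key=lambda c: (-(quotas[c] - counts[c]), c)):
        if leftover <= 0:
            break
        counts[c] += 1
        leftover -= 1
    # keep both classes represented on both sides
    for c in classes:
        counts[c] = min(max(counts[c], 1), len(by_class[c]) - 1)

    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = np.array(by_class[c])
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[: counts[c]]].tolist())
        test_idx.extend(idx[perm[counts[c] :]].tolist())
    return ds.subset_samples(sorted(train_idx)), ds.subset_samples(sorted(test_idx))


@dataclass(frozen=True)
class PerformanceMetrics:
    """Confusion counts and the derived accuracy / precision / recall.

    Precision is None when TP+FP = 0 and recall is None when TP+FN = 0
    (undefined denominators are reported as missing, never as 0 or 1).
    """

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.n

    @property
    def balanced_accuracy(self) -> float | None:
        """Mean of per-class recalls; None if a class is absent."""
        if self.TP + self.FN == 0 or self.TN + self.FP == 0:
            return None
        return 0.5 * (self.TP / (self.TP + self.FN) + self.TN / (self.TN + self.FP))

    @property
    def precision(self) -> float | None:
        d = self.TP + self.FP
        return self.TP / d if d > 0 else None

    @property
    def recall(self) -> float | None:
        d = self.TP + self.FN
        return self.TP / d if d > 0 else None

    def metric(self, name: str) -> float | None:
        if name not in {"accuracy", "precision", "recall", "balanced_accuracy"}:
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)

    @classmethod
    def from_predictions(
        cls,
        true_labels: Sequence[str],
        predicted_labels: Sequence[str],
        positive_class: str,
    ) -> "PerformanceMetrics":
        if len(true_labels) != len(predicted_labels):
            raise ValueError("label sequences differ in length")
        tp = fp = fn = tn = 0
        for t, p in zip(true_labels, predicted_labels):
            if p == positive_class:
                if t == positive_class:
                    tp += 1
                else:
                    fp += 1
            else:
                if t == positive_class:
                    fn += 1
                else:
                    tn += 1
        return cls(TP=tp, FP=fp, FN=fn, TN=tn)


def evaluate(model: Classifier, test: ExpressionDataset) -> PerformanceMetrics:
    """Score a fitted classifier on a held-out dataset."""
    if test.n_samples == 0:
        raise ValueError("test set is empty")
    predicted = list(model.predict(test))
    return PerformanceMetrics.from_predictions(
        test.labels, predicted, test.positive_class
    )
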