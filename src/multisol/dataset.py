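"""Labeled two-group expression matrix, the universal input of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class ExpressionDataset:
    """A features x samples real matrix with exactly two sample classes.

    Parameters
    ----------
    feature_ids : sequence of str
        Unique row identifiers (probes, genes).
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray of shape (n_features, n_samples)
        Expression values; log-intensity scale assumed but not enforced.
    labels : sequence of str
        Per-sample class label; exactly two distinct values must occur.
    positive_class : str
        Which of the two labels counts as "positive" for confusion-matrix
        metrics.
    check_classes : bool
        Whether to enforce the two-classes-with->=2-samples invariant.
        True for loaded/generated datasets; sample subsets (train/test
        partitions) relax it, since a small holdout may hold one sample
        of a class.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: list[str]
    positive_class: str
    check_classes: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        self._validate()

    # -- invariants ------------------------------------------------------
    def _validate(self) -> None:
        n_feat, n_samp = len(self.feature_ids), len(self.sample_ids)
        if self.values.ndim != 2 or self.values.shape != (n_feat, n_samp):
            raise DatasetError(
                f"matrix shape {self.values.shape} does not match "
                f"({n_feat} features, {n_samp} samples)"
            )
        if len(self.labels) != n_samp:
            raise DatasetError(
                f"{len(self.labels)} labels for {n_samp} samples"
            )
        dup = _first_duplicate(self.feature_ids)
        if dup is not None:
            raise DatasetError(f"duplicate feature id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise DatasetError(f"duplicate sample id {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DatasetError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        classes = sorted(set(self.labels))
        if len(classes) > 2:
            raise DatasetError(
                f"expected exactly two classes, found {len(classes)}: {classes}"
            )
        if self.check_classes:
            if len(classes) != 2:
                raise DatasetError(
                    f"expected exactly two classes, found {len(classes)}: {classes}"
                )
            if self.positive_class not in classes:
                raise DatasetError(
                    f"positive_class {self.positive_class!r} not among labels {classes}"
                )
            for c in classes:
                if self.labels.count(c) < 2:
                    raise DatasetError(f"class {c!r} has fewer than 2 samples")

    # -- convenience accessors -------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> tuple[str, str]:
        """(negative_class, positive_class)."""
        others = [c for c in sorted(set(self.labels)) if c != self.positive_class]
        if len(others) != 1:
            raise DatasetError("dataset does not contain exactly two classes")
        return others[0], self.positive_class

    @property
    def y(self) -> np.ndarray:
        """Binary target vector: 1 for positive_class samples, else 0."""
        return np.array([1 if l == self.positive_class else 0 for l in self.labels])

    def class_mask(self, label: str) -> np.ndarray:
        return np.array([l == label for l in self.labels])

    # -- restriction -----------------------------------------------------
    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given features, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise DatasetError(f"unknown feature ids: {missing}")
        rows = [index[f] for f in feature_ids]
        return ExpressionDataset(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            labels=list(self.labels),
            positive_class=self.positive_class,
            check_classes=self.check_classes,
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = list(indices)
        return ExpressionDataset(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=[self.labels[i] for i in idx],
            positive_class=self.positive_class,
            check_classes=False,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.labels == other.labels
            and self.positive_class == other.positive_class
            and np.array_equal(self.values, other.values)
        )


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
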