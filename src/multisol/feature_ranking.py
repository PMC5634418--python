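"""Per-feature two-sample t-test ranking and top-k selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset

log = logging.getLogger(__name__)


class FeatureRank(NamedTuple):
    feature_id: str
    t_statistic: float
    p_value: float
    rank: int  # 1-based, rank 1 = smallest p-value


@dataclass(frozen=True)
class RankedFeatures:
    """Features ordered by ascending t-test p-value.

    Ranks are the integers 1..m with no gaps; ties in p-value are broken by
    input feature order (stable sort), so rankings are deterministic.
    """

    entries: tuple[FeatureRank, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FeatureRank]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> FeatureRank:
        return self.entries[i]

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def rank_of(self, feature_id: str) -> int:
        for e in self.entries:
            if e.feature_id == feature_id:
                return e.rank
        raise KeyError(feature_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=FeatureRank._fields)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def rank_features(
    ds: ExpressionDataset, equal_var: bool = False
) -> RankedFeatures:
    """Rank every feature by two-sample t-test p-value (ascending).

    Welch's unequal-variance test by default; ``equal_var=True`` switches to
    Student's pooled-variance test.  A feature with zero variance in both
    classes gets t = 0, p = 1 (logged), not an error.
    """
    neg, pos = ds.classes
    a = ds.values[:, ds.class_mask(pos)]
    b = ds.values[:, ds.class_mask(neg)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each class needs >= 2 samples for a t-test")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        log.info(
            "%d features with undefined t-test (zero variance in both classes); "
            "p set to 1",
            int(degenerate.sum()),
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0

    order = np.argsort(p, kind="stable")  # ties -> input feature order
    entries = tuple(
        FeatureRank(ds.feature_ids[i], float(t[i]), float(p[i]), rank)
        for rank, i in enumerate(order, start=1)
    )
    return RankedFeatures(entries)


def top_k(rf: RankedFeatures, k: int) -> RankedFeatures:
    """First k entries of the ranking, ranks preserved."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(rf):
        raise ValueError(f"k={k} exceeds the number of features ({len(rf)})")
    return RankedFeatures(rf.entries[:k])
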