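"""Exhaustive screening of all 3-feature subsets of the top-ranked features.

Every unordered triplet drawn from the k smallest-p-value features is used
as the sole input of a seeded ELM, trained and scored on one shared 80/20
holdout split.  Census counts per metric use >= cutoff; the ten best
triplets per metric summarize how dispersed the good solutions are in rank
space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .dataset import ExpressionDataset
from .elm_classifier import ELMConfig, fit_elm
from .feature_ranking import RankedFeatures, top_k
from .splits_metrics import PerformanceMetrics, SplitSpec, evaluate, split

METRICS = ("accuracy", "precision", "recall")


@dataclass(frozen=True)
class TripletRecord:
    feature_ids: tuple[str, str, str]
    ranks: tuple[int, int, int]  # x <= y <= z, t-test ranks within top-k
    metrics: PerformanceMetrics

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != 3:
            raise ValueError(f"triplet features must be distinct: {self.feature_ids}")
        x, y, z = self.ranks
        if not x <= y <= z:
            raise ValueError(f"ranks must satisfy x <= y <= z: {self.ranks}")

    @property
    def mean_rank(self) -> float:
        return sum(self.ranks) / 3.0


@dataclass(frozen=True)
class Best10:
    """The ten best records for one metric, with their mean-rank span."""

    metric: str
    records: tuple[TripletRecord, ...]
    min_mean_rank: float
    max_mean_rank: float
    complete: bool  # False when fewer than 10 defined records existed


@dataclass
class TripletScreenReport:
    records: list[TripletRecord]
    k: int
    cutoffs: dict[str, float]
    census: dict[str, int]  # per metric: count with metric >= cutoff
    n_undefined: dict[str, int]  # per metric: records with undefined value
    split_seed: int
    elm_base_seed: int

    def best10(self, metric: str) -> Best10:
        return best10(self, metric)

    def summary_rows(self) -> list[tuple[str, object]]:
        rows: list[tuple[str, object]] = [
            ("k", self.k),
            ("n_triplets", len(self.records)),
            ("split_seed", self.split_seed),
            ("elm_base_seed", self.elm_base_seed),
        ]
        for m in METRICS:
            rows.append((f"cutoff_{m}", self.cutoffs[m]))
            rows.append((f"census_{m}", self.census[m]))
            rows.append((f"undefined_{m}", self.n_undefined[m]))
            try:
                b = self.best10(m)
            except ValueError:  # no defined records for this metric
                rows.extend(
                    (f"best10_{m}_{suffix}", None)
                    for suffix in (
                        "min_value", "max_value", "min_mean_rank", "max_mean_rank"
                    )
                )
                continue
            vmin, vmax = _min_max_vals(b, m)
            rows.append((f"best10_{m}_min_value", vmin))
            rows.append((f"best10_{m}_max_value", vmax))
            rows.append((f"best10_{m}_min_mean_rank", b.min_mean_rank))
            rows.append((f"best10_{m}_max_mean_rank", b.max_mean_rank))
        return rows

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "feature_1": r.feature_ids[0],
                    "feature_2": r.feature_ids[1],
                    "feature_3": r.feature_ids[2],
                    "x": r.ranks[0],
                    "y": r.ranks[1],
                    "z": r.ranks[2],
                    "mean_rank": r.mean_rank,
                    "accuracy": r.metrics.accuracy,
                    "precision": r.metrics.precision,
                    "recall": r.metrics.recall,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path


def _min_max_vals(b: Best10, metric: str):
    vals = [r.metrics.metric(metric) for r in b.records]
    return min(vals), max(vals)


def enumerate_triplets(rf: RankedFeatures) -> list[tuple[int, int, int]]:
    """All unordered rank triplets (x < y < z), lexicographic, exactly once."""
    k = len(rf)
    if k < 3:
        raise ValueError(f"need >= 3 ranked features, got {k}")
    ranks = [e.rank for e in rf]
    return list(itertools.combinations(ranks, 3))


def screen_triplets(
    ds: ExpressionDataset,
    rf: RankedFeatures,
    k: int = 50,
    cutoffs: dict[str, float] | None = None,
    elm_config: ELMConfig | None = None,
    split_spec: SplitSpec | None = None,
    per_triplet_split: bool = False,
) -> TripletScreenReport:
    """Fit and score one ELM per 3-subset of the top-k ranked features.

    One 80/20 split is drawn once (seeded) and shared by every triplet, so
    metrics are comparable across triplets; ``per_triplet_split=True``
    redraws the split for each triplet (sensitivity mode).  The ELM seed
    for triplet i is ``elm_config.seed + i``.  Undefined precision/recall
    values are excluded from the census and counted separately.
    """
    if cutoffs is None:
        cutoffs = {m: 0.8 for m in METRICS}
    cutoffs = {m: cutoffs.get(m, 0.8) for m in METRICS}
    if elm_config is None:
        elm_config = ELMConfig(n_hidden=150)
    if split_spec is None:
        split_spec = SplitSpec(train_fraction=0.8)

    selected = top_k(rf, k)
    by_rank = {e.rank: e.feature_id for e in selected}
    restricted = ds.subset_features(selected.feature_ids)

    shared = None if per_triplet_split else split(restricted, split_spec)

    records: list[TripletRecord] = []
    for i, ranks in enumerate(enumerate_triplets(selected)):
        ids = tuple(by_rank[r] for r in ranks)
        if shared is not None:
            train, test = shared
        else:
            train, test = split(
                restricted, replace(split_spec, seed=split_spec.seed + i)
            )
        cfg = replace(elm_config, seed=elm_config.seed + i)
        try:
            model = fit_elm(train.subset_features(list(ids)), cfg)
        except Exception as exc:
            raise RuntimeError(f"triplet {ids} failed: {exc}") from exc
        metrics = evaluate(model, test.subset_features(list(ids)))
        records.append(TripletRecord(ids, ranks, metrics))

    census: dict[str, int] = {}
    n_undefined: dict[str, int] = {}
    for m in METRICS:
        vals = [r.metrics.metric(m) for r in records]
        n_undefined[m] = sum(v is None for v in vals)
        census[m] = sum(v is not None and v >= cutoffs[m] for v in vals)

    return TripletScreenReport(
        records=records,
        k=k,
        cutoffs=cutoffs,
        census=census,
        n_undefined=n_undefined,
        split_seed=split_spec.seed,
        elm_base_seed=elm_config.seed,
    )


def best10(report: TripletScreenReport, metric: str) -> Best10:
    """Top 10 records by a metric; ties broken by smaller mean_rank, then
    lexicographic ranks.  Fewer than 10 defined records -> all, flagged."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    defined = [r for r in report.records if r.metrics.metric(metric) is not None]
    ordered = sorted(
        defined,
        key=lambda r: (-r.metrics.metric(metric), r.mean_rank, r.ranks),
    )
    chosen = tuple(ordered[:10])
    if not chosen:
        raise ValueError(f"no records with defined {metric}")
    mean_ranks = [r.mean_rank for r in chosen]
    return Best10(
        metric=metric,
        records=chosen,
        min_mean_rank=min(mean_ranks),
        max_mean_rank=max(mean_ranks),
        complete=len(chosen) == 10,
    )


def single_feature_accuracy(
    ds: ExpressionDataset,
    feature_id: str,
    elm_config: ELMConfig | None = None,
    split_spec: SplitSpec | None = None,
) -> PerformanceMetrics:
    """Score one feature alone under the triplet-screen protocol.

    Supports complementarity analysis: a triplet can classify far better
    than any of its members individually.
    """
    if feature_id not in ds.feature_ids:
        raise KeyError(f"unknown feature id {feature_id!r}")
    if elm_config is None:
        elm_config = ELMConfig(n_hidden=150)
    if split_spec is None:
        split_spec = SplitSpec(train_fraction=0.8)
    train, test = split(ds, split_spec)
    model = fit_elm(train.subset_features([feature_id]), elm_config)
    return evaluate(model, test.subset_features([feature_id]))
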