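"""Repeated seeded model fits on a fixed feature set, with a cutoff census.

The model-level experiment: many ELMs differing only in their random hidden
layer are trained on the same data, the test accuracy of each run is
recorded, and the number of runs strictly above a cutoff is counted.  The
two best runs can then be refitted and compared weight-by-weight to show
that equally accurate models are genuinely different.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .dataset import ExpressionDataset
from .elm_classifier import ELMConfig, ELMModel, fit_elm
from .feature_ranking import rank_features, top_k
from .splits_metrics import Classifier, SplitSpec, evaluate, split

MODES = ("Top20Features", "AllFeatures")
DEFAULT_N_HIDDEN = {"Top20Features": 150, "AllFeatures": 290}


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of one model screen.

    ``mode`` selects the feature set (t-test top 20 vs all features) and
    the default hidden-layer width (150 vs 290).  By default the split is
    drawn once and shared across runs, so run-to-run randomness comes from
    the hidden weights alone; ``resplit_per_run=True`` instead redraws the
    split each run (the scheme used for deterministic baseline
    classifiers).
    """

    mode: str = "Top20Features"
    n_runs: int = 10_000
    cutoff: float = 0.8
    elm_config: ELMConfig | None = None
    split_spec: SplitSpec = field(default_factory=lambda: SplitSpec(train_fraction=0.7))
    base_seed: int = 0
    resplit_per_run: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")

    def resolved_elm_config(self) -> ELMConfig:
        if self.elm_config is not None:
            return self.elm_config
        return ELMConfig(n_hidden=DEFAULT_N_HIDDEN[self.mode])


@dataclass
class ScreenReport:
    """Census of runs above the cutoff, plus everything needed to refit."""

    config: ScreenConfig
    feature_ids: list[str]
    per_run_log: list[tuple[int, float]]  # (seed, test accuracy) per run
    n_above_cutoff: int
    min_acc_above: float | None
    max_acc_above: float | None
    _refit: Callable[[int], Classifier] | None = field(
        default=None, repr=False, compare=False
    )

    def summary_rows(self) -> list[tuple[str, object]]:
        return [
            ("mode", self.config.mode),
            ("n_runs", self.config.n_runs),
            ("cutoff", self.config.cutoff),
            ("n_features", len(self.feature_ids)),
            ("n_above_cutoff", self.n_above_cutoff),
            ("min_acc_above", self.min_acc_above),
            ("max_acc_above", self.max_acc_above),
            ("base_seed", self.config.base_seed),
        ]

    def refit(self, seed: int) -> Classifier:
        """Re-train the model of a recorded run (deterministic by seed)."""
        if self._refit is None:
            raise ValueError("report carries no refit closure")
        return self._refit(seed)


def _census(
    accuracies: list[float], cutoff: float, strict: bool
) -> tuple[int, float | None, float | None]:
    above = [a for a in accuracies if (a > cutoff if strict else a >= cutoff)]
    if not above:
        return 0, None, None
    return len(above), min(above), max(above)


def _screen(
    ds: ExpressionDataset,
    feature_ids: list[str],
    make_classifier: Callable[[ExpressionDataset, int], Classifier],
    config: ScreenConfig,
) -> ScreenReport:
    restricted = ds.subset_features(feature_ids)
    shared = (
        None
        if config.resplit_per_run
        else split(restricted, config.split_spec)
    )

    log: list[tuple[int, float]] = []
    fitted_cache: dict[int, ExpressionDataset] = {}

    def parts_for(seed: int):
        if shared is not None:
            return shared
        return split(restricted, replace(config.split_spec, seed=seed))

    def refit(seed: int) -> Classifier:
        train, _ = parts_for(seed)
        return make_classifier(train, seed)

    for i in range(config.n_runs):
        seed = config.base_seed + i
        train, test = parts_for(seed)
        try:
            model = make_classifier(train, seed)
        except Exception as exc:
            raise RuntimeError(f"run {i} (seed {seed}) failed: {exc}") from exc
        acc = evaluate(model, test).accuracy
        log.append((seed, acc))

    n_above, lo, hi = _census([a for _, a in log], config.cutoff, strict=True)
    return ScreenReport(
        config=config,
        feature_ids=feature_ids,
        per_run_log=log,
        n_above_cutoff=n_above,
        min_acc_above=lo,
        max_acc_above=hi,
        _refit=refit,
    )


def run_screen(ds: ExpressionDataset, config: ScreenConfig) -> ScreenReport:
    """Run the ELM screen: n_runs seeded fits, census with strict acc > cutoff.

    Run i uses ELM seed = base_seed + i.  In Top20Features mode the feature
    set is the t-test top 20; AllFeatures uses every feature.
    """
    if config.mode == "Top20Features":
        if ds.n_features < 20:
            raise ValueError("Top20Features mode needs >= 20 features")
        feature_ids = top_k(rank_features(ds), 20).feature_ids
    else:
        feature_ids = list(ds.feature_ids)

    template = config.resolved_elm_config()

    def make(train: ExpressionDataset, seed: int) -> ELMModel:
        return fit_elm(train, replace(template, seed=seed))

    return _screen(ds, feature_ids, make, config)


def baseline_screen(
    ds: ExpressionDataset,
    classifier_factory: Callable[[int], "FittableClassifier"],
    config: ScreenConfig,
) -> ScreenReport:
    """Screen an arbitrary fit/predict classifier with the same census machinery.

    ``classifier_factory(seed)`` must return an unfitted object exposing
    ``fit(train_ds)`` and ``predict(ds)``.  Deterministic classifiers ignore
    the seed, in which case the per-run randomness should come from
    resplitting (set ``config.resplit_per_run=True``, the default policy for
    baselines in the CLI).
    """
    if config.mode == "Top20Features":
        if ds.n_features < 20:
            raise ValueError("Top20Features mode needs >= 20 features")
        feature_ids = top_k(rank_features(ds), 20).feature_ids
    else:
        feature_ids = list(ds.feature_ids)

    def make(train: ExpressionDataset, seed: int) -> Classifier:
        clf = classifier_factory(seed)
        clf.fit(train)
        return clf

    return _screen(ds, feature_ids, make, config)


def best_pair(
    report: ScreenReport, tiebreak_seed: int = 0
) -> tuple[ELMModel, ELMModel]:
    """Refit the two top-accuracy runs; ties resolved uniformly at random
    (seeded), mirroring the random choice among tied-best models."""
    if len(report.per_run_log) < 2:
        raise ValueError("need at least 2 recorded runs")
    best_acc = max(a for _, a in report.per_run_log)
    tied = [s for s, a in report.per_run_log if a == best_acc]
    if len(tied) >= 2:
        rng = np.random.default_rng(tiebreak_seed)
        chosen = sorted(rng.choice(len(tied), size=2, replace=False).tolist())
        seeds = (tied[chosen[0]], tied[chosen[1]])
    else:
        # unique best: pair it with the runner-up
        runner = max(
            (a for _, a in report.per_run_log if a < best_acc), default=None
        )
        second = next(s for s, a in report.per_run_log if a == runner)
        seeds = (tied[0], second)
    return report.refit(seeds[0]), report.refit(seeds[1])


# ---------------------------------------------------------------------------
# Baseline adapters (established implementations, not re-implemented)
# ---------------------------------------------------------------------------


class SklearnAdapter:
    """Wrap a scikit-learn estimator behind the dataset fit/predict contract.

    Inputs are standardized with train-set statistics, matching the ELM
    preprocessing, so comparisons are like for like.
    """

    def __init__(self, estimator):
        self._est = estimator
        self._mu = None
        self._sd = None
        self._feature_ids: list[str] | None = None
        self._classes: tuple[str, str] | None = None

    def fit(self, train: ExpressionDataset) -> "SklearnAdapter":
        self._feature_ids = list(train.feature_ids)
        self._mu = train.values.mean(axis=1)
        sd = train.values.std(axis=1, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        X = ((train.values - self._mu[:, None]) / self._sd[:, None]).T
        self._est.fit(X, train.y)
        self._classes = train.classes
        return self

    def predict(self, ds: ExpressionDataset) -> list[str]:
        if self._feature_ids is None:
            raise ValueError("classifier is not fitted")
        sub = ds.subset_features(self._feature_ids)
        X = ((sub.values - self._mu[:, None]) / self._sd[:, None]).T
        neg, pos = self._classes
        return [pos if y == 1 else neg for y in self._est.predict(X)]


def svm_factory(seed: int) -> SklearnAdapter:
    from sklearn.svm import SVC

    return SklearnAdapter(SVC(kernel="rbf", random_state=seed))


def nbayes_factory(seed: int) -> SklearnAdapter:
    from sklearn.naive_bayes import GaussianNB

    return SklearnAdapter(GaussianNB())


class MajorityClassifier:
    """Predicts the majority training label; a chance-level control."""

    def __init__(self) -> None:
        self._label: str | None = None

    def fit(self, train: ExpressionDataset) -> "MajorityClassifier":
        counts: dict[str, int] = {}
        for l in train.labels:
            counts[l] = counts.get(l, 0) + 1
        self._label = max(sorted(counts), key=lambda l: counts[l])
        return self

    def predict(self, ds: ExpressionDataset) -> list[str]:
        if self._label is None:
            raise ValueError("classifier is not fitted")
        return [self._label] * ds.n_samples


BASELINE_FACTORIES = {
    "svm": svm_factory,
    "nbayes": nbayes_factory,
    "majority": lambda seed: MajorityClassifier(),
}
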