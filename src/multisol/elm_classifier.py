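"""Extreme Learning Machine binary classifier.

A single hidden layer of random, frozen weights maps the (standardized)
inputs to hidden activations; only the linear readout is fitted, as the
minimum-norm least-squares solution onto {0, 1} labels.  The random hidden
weight matrix (n_hidden x m) is the object compared between models: two
equally accurate models with different hidden layers are genuinely distinct
solutions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataset import ExpressionDataset

_ACTIVATIONS = {
    "tanh": np.tanh,
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
}

# relative tolerance on singular values for the pseudoinverse readout
_PINV_RTOL = 1e-10


@dataclass(frozen=True)
class ELMConfig:
    """Hyperparameters of one ELM draw.

    ``n_hidden`` follows the screening modes (150 for a 20-feature input,
    290 for all features); ``seed`` fully determines the hidden layer.
    """

    n_hidden: int = 150
    activation: str = "tanh"
    weight_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"activation must be one of {sorted(_ACTIVATIONS)}"
            )
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be > 0")


@dataclass
class ELMModel:
    """A fitted ELM: frozen random hidden layer + least-squares readout."""

    input_weights: np.ndarray  # (n_hidden, m)
    biases: np.ndarray  # (n_hidden,)
    readout_weights: np.ndarray  # (n_hidden,)
    readout_intercept: float
    feature_ids: list[str]
    feature_means: np.ndarray  # train standardization
    feature_sds: np.ndarray
    config: ELMConfig
    positive_class: str
    negative_class: str
    threshold: float = 0.5

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    # -- prediction ------------------------------------------------------
    def decision_scores(self, ds: ExpressionDataset) -> np.ndarray:
        """Continuous readout per sample (aligned to this model's features)."""
        sub = ds.subset_features(self.feature_ids)
        X = (sub.values - self.feature_means[:, None]) / self.feature_sds[:, None]
        H = _ACTIVATIONS[self.config.activation](
            self.input_weights @ X + self.biases[:, None]
        )
        return self.readout_weights @ H + self.readout_intercept

    def predict(self, ds: ExpressionDataset) -> list[str]:
        """Per-sample labels: positive iff score >= threshold."""
        scores = self.decision_scores(ds)
        return [
            self.positive_class if s >= self.threshold else self.negative_class
            for s in scores
        ]

    # -- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Flat numeric archive: JSON header line + whitespace arrays."""
        path = Path(path)
        header = {
            "config": asdict(self.config),
            "feature_ids": self.feature_ids,
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "threshold": self.threshold,
            "readout_intercept": self.readout_intercept,
            "n_hidden": self.n_hidden,
            "n_features": self.n_features,
        }
        flat = np.concatenate([
            self.input_weights.ravel(),
            self.biases,
            self.readout_weights,
            self.feature_means,
            self.feature_sds,
        ])
        with path.open("w") as fh:
            fh.write(json.dumps(header) + "\n")
            np.savetxt(fh, flat, fmt="%.17g")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ELMModel":
        with Path(path).open() as fh:
            header = json.loads(fh.readline())
            data = np.loadtxt(fh).ravel()
        n, m = header["n_hidden"], header["n_features"]
        parts = np.split(data, np.cumsum([n * m, n, n, m]))
        return cls(
            input_weights=parts[0].reshape(n, m),
            biases=parts[1],
            readout_weights=parts[2],
            readout_intercept=float(header["readout_intercept"]),
            feature_ids=list(header["feature_ids"]),
            feature_means=parts[3],
            feature_sds=parts[4],
            config=ELMConfig(**header["config"]),
            positive_class=header["positive_class"],
            negative_class=header["negative_class"],
            threshold=float(header["threshold"]),
        )


def fit_elm(ds_train: ExpressionDataset, config: ELMConfig) -> ELMModel:
    """Fit an ELM on a training dataset.

    The hidden weights and biases are drawn uniformly on
    (-weight_scale, +weight_scale) from a generator seeded with
    ``config.seed``; refitting with identical data and config reproduces
    them bit-exactly.  Inputs are standardized with train-set mean/sd.
    The readout is the minimum-norm least-squares map from hidden
    activations (plus intercept) to {0, 1} labels; rank deficiency is
    handled by the pseudoinverse tolerance, not treated as an error.
    """
    y = ds_train.y
    if y.min() == y.max():
        raise ValueError("training data contain a single class")

    m = ds_train.n_features
    mu = ds_train.values.mean(axis=1)
    sd = ds_train.values.std(axis=1, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through centered
    X = (ds_train.values - mu[:, None]) / sd[:, None]

    rng = np.random.default_rng(config.seed)
    W = rng.uniform(-config.weight_scale, config.weight_scale, size=(config.n_hidden, m))
    b = rng.uniform(-config.weight_scale, config.weight_scale, size=config.n_hidden)

    H = _ACTIVATIONS[config.activation](W @ X + b[:, None])  # (n_hidden, n)
    design = np.hstack([H.T, np.ones((ds_train.n_samples, 1))])
    beta = np.linalg.pinv(design, rcond=_PINV_RTOL) @ y.astype(float)

    neg, pos = ds_train.classes
    return ELMModel(
        input_weights=W,
        biases=b,
        readout_weights=beta[:-1],
        readout_intercept=float(beta[-1]),
        feature_ids=list(ds_train.feature_ids),
        feature_means=mu,
        feature_sds=sd,
        config=config,
        positive_class=pos,
        negative_class=neg,
    )


@dataclass(frozen=True)
class DifferenceMatrix:
    """Elementwise |A - B| of two models' hidden weight matrices."""

    values: np.ndarray
    max_difference: float

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t", fmt="%.17g")
        return path


def weight_difference(a: ELMModel, b: ELMModel) -> DifferenceMatrix:
    """Compare two models' hidden layers; requires matching shape/features."""
    if a.input_weights.shape != b.input_weights.shape:
        raise ValueError(
            f"shape mismatch: {a.input_weights.shape} vs {b.input_weights.shape}"
        )
    if a.feature_ids != b.feature_ids:
        raise ValueError("models were trained on different feature orders")
    diff = np.abs(a.input_weights - b.input_weights)
    return DifferenceMatrix(values=diff, max_difference=float(diff.max()))
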