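"""Synthetic two-group expression data with planted signal and redundancy.

The generator emulates the structure of small two-class microarray studies:
thousands of features, tens of samples, a minority of class-informative
features whose effect size tunes "easy" vs "difficult" separability, and
optional blocks of correlated informative features that plant multiple
interchangeable solutions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import ExpressionDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the between-class mean shift on informative features,
    in units of ``noise_sd``.  Features inside a redundant block share a
    latent factor giving pairwise correlation ~ ``within_block_correlation``.
    """

    n_features: int = 2000
    n_samples_per_class: tuple[int, int] = (30, 30)
    n_informative: int = 10
    effect_size: float = 1.5
    n_redundant_blocks: int = 0
    block_size: int = 3
    within_block_correlation: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if any(n <= 0 for n in self.n_samples_per_class):
            raise ValueError("n_samples_per_class entries must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_redundant_blocks < 0 or self.block_size <= 0:
            raise ValueError("invalid redundant-block parameters")
        if self.n_redundant_blocks * self.block_size > self.n_informative:
            raise ValueError(
                "n_redundant_blocks * block_size must not exceed n_informative"
            )
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError("within_block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def informative_ids(self) -> list[str]:
        """Feature ids the generator plants signal on (first n_informative)."""
        return [_feature_id(i, self) for i in range(self.n_informative)]

    def block_members(self, block: int) -> list[str]:
        """Feature ids of one redundant block (0-based block index)."""
        if not 0 <= block < self.n_redundant_blocks:
            raise ValueError(f"no such block: {block}")
        lo = block * self.block_size
        return [_feature_id(i, self) for i in range(lo, lo + self.block_size)]


def _feature_id(i: int, spec: SyntheticSpec) -> str:
    width = max(4, len(str(spec.n_features)))
    if i < spec.n_redundant_blocks * spec.block_size:
        b, j = divmod(i, spec.block_size)
        return f"sig_b{b}_{j:0{width}d}"
    if i < spec.n_informative:
        return f"sig_{i:0{width}d}"
    return f"bg_{i:0{width}d}"


def generate(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw one dataset; identical spec + seed give bit-identical output.

    Uninformative features are i.i.d. N(0, noise_sd^2) in both classes.
    Informative features receive a +effect_size*noise_sd mean shift in the
    positive class.  Block members mix a per-sample latent factor with
    independent noise so pairwise within-block correlation is
    ~ within_block_correlation.
    """
    rng = np.random.default_rng(spec.seed)
    n_neg, n_pos = spec.n_samples_per_class
    n = n_neg + n_pos
    m = spec.n_features
    sd = spec.noise_sd

    values = rng.normal(0.0, sd, size=(m, n))

    # correlated blocks: x = sqrt(rho) * latent + sqrt(1-rho) * noise
    rho = spec.within_block_correlation
    for b in range(spec.n_redundant_blocks):
        lo = b * spec.block_size
        latent = rng.normal(0.0, sd, size=n)
        values[lo : lo + spec.block_size, :] = (
            np.sqrt(rho) * latent
            + np.sqrt(1.0 - rho) * values[lo : lo + spec.block_size, :]
        )

    labels = ["neg"] * n_neg + ["pos"] * n_pos
    shift = spec.effect_size * sd
    values[: spec.n_informative, n_neg:] += shift

    feature_ids = [_feature_id(i, spec) for i in range(m)]
    sample_ids = [f"s{j:03d}" for j in range(n)]
    return ExpressionDataset(feature_ids, sample_ids, values, labels, "pos")


# ---------------------------------------------------------------------------
# Presets mirroring the easy / difficult dataset regimes
# ---------------------------------------------------------------------------

PRESETS: dict[str, SyntheticSpec] = {
    # strongly separable, with redundant blocks so that disjoint well-performing
    # feature triplets exist by construction
    "easy": SyntheticSpec(
        n_features=1000,
        n_samples_per_class=(30, 30),
        n_informative=12,
        effect_size=2.5,
        n_redundant_blocks=3,
        block_size=3,
        within_block_correlation=0.8,
        noise_sd=1.0,
        seed=0,
    ),
    # weak signal, small cohort
    "difficult": SyntheticSpec(
        n_features=2000,
        n_samples_per_class=(17, 17),
        n_informative=10,
        effect_size=0.8,
        n_redundant_blocks=0,
        block_size=1,
        within_block_correlation=0.0,
        noise_sd=1.0,
        seed=0,
    ),
}


def preset(name: str, seed: int | None = None) -> SyntheticSpec:
    """Fetch a named preset, optionally overriding its seed."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec
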