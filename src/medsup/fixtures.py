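"""Synthetic imbalanced two-class tabular fixtures.

Two fixture families emulate the shapes of the study data: an
expression-like set (100 training instances split 86/14 plus a 62-instance
test set split 51/11, positive continuous features) and a larger protein
physicochemical-feature set (2635 instances, 126 features, 1589/1046).
Features are drawn from per-class Gaussians truncated below at a value
floor; the minority class sits below the pooled per-feature medians, so
median-scaled supplements land in minority territory. These fixtures test
mechanics and direction properties, not real-data covariance structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular import LabeledTable

__all__ = ["FixtureSpec", "simulate_table", "her2_like_pair", "subcellular_like"]


@dataclass(frozen=True)
class FixtureSpec:
    """Generative recipe for one imbalanced two-class table.

    Class-conditional features are independent Gaussians: class means are
    given per class (scalar or per-feature vector), with a shared
    within-class standard deviation; draws are clipped from below at
    ``floor`` (0 for expression-like, non-negative data).
    """

    n_major: int
    n_minor: int
    n_features: int
    major_means: np.ndarray | float
    minor_means: np.ndarray | float
    sd: np.ndarray | float
    floor: float = 0.0
    major_label: str = "Negative"
    minor_label: str = "Positive"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_major >= self.n_minor >= 1):
            raise ValueError("need n_major >= n_minor >= 1")
        if self.n_features < 1:
            raise ValueError("need n_features >= 1")
        if np.any(np.asarray(self.sd) <= 0):
            raise ValueError("within-class sd must be positive")
        if self.major_label == self.minor_label:
            raise ValueError("class labels must differ")


def _broadcast(v, p: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(v, dtype=float), (p,))
    return np.array(arr)


def simulate_table(spec: FixtureSpec) -> LabeledTable:
    """Draw one labelled table from the spec; pure function of the spec."""
    p = spec.n_features
    mu_major = _broadcast(spec.major_means, p)
    mu_minor = _broadcast(spec.minor_means, p)
    sd = _broadcast(spec.sd, p)
    rng = np.random.default_rng(spec.seed)
    major = rng.normal(mu_major, sd, size=(spec.n_major, p))
    minor = rng.normal(mu_minor, sd, size=(spec.n_minor, p))
    values = np.clip(np.vstack([major, minor]), spec.floor, None)
    labels = np.asarray(
        [spec.major_label] * spec.n_major + [spec.minor_label] * spec.n_minor,
        dtype=object,
    )
    names = [f"attr_{j + 1}" for j in range(p)]
    return LabeledTable(names, values, labels, label_name="class")


def _her2_like_params(rng: np.random.Generator, p: int):
    """Expression-like per-feature scales.

    Minority means sit at ~half the majority level — the region where a
    median-scaled uniform supplement centres — and the within-class sd is
    35% of the majority mean, comparable to the spread such a supplement
    implies (median/sqrt(12) ~ 0.29 x median).
    """
    base = rng.uniform(100.0, 400.0, size=p)
    return base, 0.48 * base, 0.35 * base


def her2_like_pair(seed: int, n_features: int = 10) -> tuple[LabeledTable, LabeledTable]:
    """An 86/14 training table and a 51/11 test table, disjoint draws.

    Both are drawn from the same per-feature parameters; minority-class
    means sit below the pooled per-feature medians of the training table,
    so a median-scaled supplement falls in the minority region.
    """
    param_seq, train_seq, test_seq = np.random.SeedSequence(seed).spawn(3)
    base, minor_mu, sd = _her2_like_params(np.random.default_rng(param_seq), n_features)
    train = simulate_table(
        FixtureSpec(
            86, 14, n_features, base, minor_mu, sd,
            seed=int(train_seq.generate_state(1)[0] % 2**31),
        )
    )
    test = simulate_table(
        FixtureSpec(
            51, 11, n_features, base, minor_mu, sd,
            seed=int(test_seq.generate_state(1)[0] % 2**31),
        )
    )
    return train, test


def subcellular_like(
    seed: int, n_instances: int | None = None, n_features: int = 126
) -> LabeledTable:
    """A protein-localization-like table: 2635 x 126, split 1589/1046.

    Features mimic bounded physicochemical summaries (percent compositions,
    transition frequencies): positive, moderate scale, weaker per-feature
    class separation than the expression-like family but many informative
    features. ``n_instances`` scales the table down proportionally while
    keeping the 1589:1046 imbalance ratio.
    """
    if n_instances is None:
        n_major, n_minor = 1589, 1046
    else:
        n_major = round(n_instances * 1589 / 2635)
        n_minor = n_instances - n_major
    param_seq, draw_seq = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(param_seq)
    base = rng.uniform(2.0, 30.0, size=n_features)
    return simulate_table(
        FixtureSpec(
            n_major,
            n_minor,
            n_features,
            base,
            0.8 * base,
            0.6 * base,
            major_label="plasma-membrane",
            minor_label="nucleus",
            seed=int(draw_seq.generate_state(1)[0] % 2**31),
        )
    )
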