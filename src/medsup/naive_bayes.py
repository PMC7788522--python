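"""Gaussian naive Bayes backend for binary classification.

The posterior of class C_j given an attribute vector G is proportional to
P(C_j) * prod_i P(g_i | C_j): attributes are treated as conditionally
independent given the class, each modelled as a univariate Gaussian with
class-specific mean and standard deviation. The evidence term P(G) is
common to both classes and never computed. All arithmetic is done in log
space; normalized posteriors come from log-sum-exp.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .tabular import LabeledTable, TabularError, UnlabeledTable

__all__ = ["NBModel", "fit_nb", "nb_log_posterior", "nb_posterior", "predict_nb"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class NBModel:
    """Per-class priors and per-class per-attribute Gaussian parameters.

    ``sds`` are floored at ``scale_floor`` so constant attributes keep the
    densities finite. Priors sum to 1.
    """

    class_levels: tuple[str, str]
    attribute_names: list[str]
    priors: np.ndarray  # (2,)
    means: np.ndarray  # (2, n)
    sds: np.ndarray  # (2, n)
    scale_floor: float

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        if np.any(self.sds < self.scale_floor) or self.scale_floor <= 0:
            raise ValueError("all scales must be >= scale_floor > 0")

    @property
    def n_attributes(self) -> int:
        return self.means.shape[1]

    def to_text(self) -> str:
        """Human-readable key-value serialization."""
        doc = {
            "model": "gaussian_naive_bayes",
            "class_levels": list(self.class_levels),
            "attribute_names": list(self.attribute_names),
            "scale_floor": self.scale_floor,
            "priors": {c: p for c, p in zip(self.class_levels, self.priors.tolist())},
            "means": {c: row for c, row in zip(self.class_levels, self.means.tolist())},
            "sds": {c: row for c, row in zip(self.class_levels, self.sds.tolist())},
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_text(cls, text: str) -> "NBModel":
        doc = json.loads(text)
        if doc.get("model") != "gaussian_naive_bayes":
            raise ValueError("not a serialized naive Bayes model")
        levels = tuple(doc["class_levels"])
        return cls(
            class_levels=levels,
            attribute_names=list(doc["attribute_names"]),
            priors=np.array([doc["priors"][c] for c in levels]),
            means=np.array([doc["means"][c] for c in levels]),
            sds=np.array([doc["sds"][c] for c in levels]),
            scale_floor=float(doc["scale_floor"]),
        )


def fit_nb(table: LabeledTable, scale_floor: float | None = None) -> NBModel:
    """Fit priors and per-class Gaussian parameters from a labelled table.

    Priors are the empirical class frequencies; per class and attribute the
    mean and unbiased (n-1 divisor) standard deviation are estimated, then
    floored at ``scale_floor``. The default floor,
    ``1e-9 * (pooled attribute variance + 1)``, keeps densities finite on
    constant attributes without perturbing informative ones.
    """
    table.require_binary()
    if scale_floor is None:
        scale_floor = 1e-9 * (float(np.var(table.values)) + 1.0)
    if scale_floor <= 0:
        raise ValueError("scale_floor must be positive")
    levels = table.class_levels
    priors, means, sds = [], [], []
    for level in levels:
        rows = table.values[table.labels == level]
        if rows.shape[0] < 2:
            raise TabularError(
                f"class {level!r} has {rows.shape[0]} instance(s); at least 2 "
                "are needed to estimate a scale"
            )
        priors.append(rows.shape[0] / table.n_instances)
        means.append(rows.mean(axis=0))
        sds.append(np.maximum(rows.std(axis=0, ddof=1), scale_floor))
    return NBModel(
        class_levels=(levels[0], levels[1]),
        attribute_names=list(table.attribute_names),
        priors=np.array(priors),
        means=np.vstack(means),
        sds=np.vstack(sds),
        scale_floor=float(scale_floor),
    )


def _instances_matrix(model: NBModel, instances) -> np.ndarray:
    if isinstance(instances, UnlabeledTable):
        x = instances.values
    else:
        x = np.atleast_2d(np.asarray(instances, dtype=float))
    if x.shape[1] != model.n_attributes:
        raise TabularError(
            f"instance has {x.shape[1]} attributes; model expects "
            f"{model.n_attributes}"
        )
    return x


def nb_log_posterior(model: NBModel, instances) -> np.ndarray:
    """Unnormalized per-class log posterior scores, shape (k, 2).

    score_j = log P(C_j) + sum_i log N(g_i; mean_ji, sd_ji). The evidence
    P(G) is omitted: it is identical for the two classes and cancels in the
    posterior comparison.
    """
    x = _instances_matrix(model, instances)
    # (k, 2, n) standardized residuals
    z = (x[:, np.newaxis, :] - model.means[np.newaxis, :, :]) / model.sds
    log_dens = -0.5 * z**2 - np.log(model.sds)[np.newaxis, :, :] - _LOG_SQRT_2PI
    return np.log(model.priors)[np.newaxis, :] + log_dens.sum(axis=2)


def nb_posterior(model: NBModel, instances) -> np.ndarray:
    """Normalized posteriors P(C_j | G), rows summing to 1."""
    scores = nb_log_posterior(model, instances)
    return np.exp(scores - logsumexp(scores, axis=1, keepdims=True))


def predict_nb(model: NBModel, instances) -> np.ndarray:
    """Argmax-posterior class per instance.

    Exact posterior ties go to the lexicographically first class level,
    which is position 0 of ``class_levels``.
    """
    scores = nb_log_posterior(model, instances)
    idx = np.argmax(scores, axis=1)  # first max wins ties
    return np.asarray([model.class_levels[i] for i in idx], dtype=object)
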