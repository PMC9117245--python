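"""Fusion of softmax score and uncertainty into a 2D classification score.

The classification task is lifted to two dimensions — the single-model
softmax score ``s`` and an uncertainty measure ``u`` — and collapsed back to
one score by the power-mean-style fusion

    f(u, s) = ((u / P_u)^y + s^y)^(1/y)

where ``P_u`` normalises the uncertainty range (the 99th percentile of the
uncertainty values by default) and the exponent ``y`` controls the shape of
the decision boundary ``f(u, s) = t``: circular in the ``(u/P_u, s)`` plane
at ``y = 2``, approaching the square ``max(u/P_u, s) = t`` as ``y`` grows.
The fixed shape exponent used throughout is ``y = 10``; the decision
threshold ``t`` remains free and is swept by the evaluation module.

A prediction is positive when ``f(u, s) > t`` (strictly).  Because
``f(0, s) = s``, inputs with zero uncertainty are classified exactly as the
softmax alone would classify them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import MeanScoreVector, UncertaintyVector
from .samplers import SampleMatrix

__all__ = [
    "CombinerConfig",
    "CombinedScoreVector",
    "fit_normaliser",
    "combined_score",
    "predict_combined",
    "mean_aggregate_predict",
]

DEFAULT_EXPONENT = 10.0
DEFAULT_PERCENTILE = 99.0


@dataclass(frozen=True)
class CombinerConfig:
    """Shape exponent ``y``, normaliser ``P_u`` and the percentile used to
    derive it."""

    exponent: float = DEFAULT_EXPONENT
    normaliser: float = 1.0
    percentile: float = DEFAULT_PERCENTILE

    def __post_init__(self) -> None:
        if self.exponent < 1.0:
            raise ValueError("exponent must be >= 1")
        if self.normaliser <= 0.0:
            raise ValueError("normaliser P_u must be positive")
        if not 0.0 < self.percentile <= 100.0:
            raise ValueError("percentile must lie in (0, 100]")


@dataclass(frozen=True)
class CombinedScoreVector:
    """Fused scores ``f(u, s) >= 0`` with the config that produced them."""

    values: np.ndarray
    config: CombinerConfig

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.size and v.min() < 0.0:
            raise ValueError("combined scores must be non-negative")
        object.__setattr__(self, "values", v)


def fit_normaliser(uncertainty: UncertaintyVector,
                   percentile: float = DEFAULT_PERCENTILE,
                   exponent: float = DEFAULT_EXPONENT) -> CombinerConfig:
    """Set ``P_u`` to the given percentile of the observed uncertainty values
    (linear-interpolation percentile definition).

    Raises when the percentile is zero — for all-certain data the fusion
    degenerates and softmax-only scoring should be used instead.
    """
    vals = np.asarray(uncertainty.values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("cannot fit a normaliser on an empty uncertainty vector")
    p_u = float(np.percentile(vals, percentile))
    if p_u <= 0.0:
        raise ValueError(
            "uncertainty percentile is 0; the combined score is undefined — "
            "use softmax-only scoring for this data")
    return CombinerConfig(exponent=exponent, normaliser=p_u, percentile=percentile)


def combined_score(uncertainty: UncertaintyVector,
                   softmax: MeanScoreVector,
                   config: CombinerConfig) -> CombinedScoreVector:
    """Element-wise ``((u/P_u)^y + s^y)^(1/y)``.

    Computed by factoring out the larger argument, which is numerically
    stable for large ``y`` and makes the axis cases exact:
    ``f(0, s) = s`` and ``f(u, 0) = u/P_u`` to the last bit.
    """
    u = np.asarray(uncertainty.values, dtype=np.float64)
    s = np.asarray(softmax.values, dtype=np.float64)
    if u.shape != s.shape:
        raise ValueError("uncertainty and softmax vectors differ in length")
    if u.size and u.min() < 0.0:
        raise ValueError("uncertainty values must be non-negative")
    if s.size and s.min() < 0.0:
        raise ValueError("softmax scores must be non-negative")
    a = u / config.normaliser
    y = config.exponent
    m = np.maximum(a, s)
    f = np.zeros_like(m)
    nz = m > 0.0
    f[nz] = m[nz] * ((a[nz] / m[nz]) ** y + (s[nz] / m[nz]) ** y) ** (1.0 / y)
    return CombinedScoreVector(f, config)


def predict_combined(scores: CombinedScoreVector, threshold: float) -> np.ndarray:
    """Binary predictions: 1 where ``f(u, s) > t`` (strict), else 0."""
    if threshold < 0.0:
        raise ValueError("threshold must be non-negative")
    return (scores.values > threshold).astype(np.int64)


def mean_aggregate_predict(samples: SampleMatrix, threshold: float) -> np.ndarray:
    """Traditional ensembling comparator: threshold the row-mean score."""
    return (samples.samples.mean(axis=1) > threshold).astype(np.int64)


def rescaled(config: CombinerConfig, normaliser: float) -> CombinerConfig:
    """A copy of ``config`` with a frozen, externally chosen ``P_u`` (for
    scoring a new dataset with a normaliser fitted elsewhere)."""
    return replace(config, normaliser=normaliser)
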