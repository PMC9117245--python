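"""Uncertainty metrics over prediction-sample matrices.

Given the ``N × T`` tumour-softmax samples of a :class:`~uqpath.samplers.SampleMatrix`,
each metric reduces every row to a single scalar uncertainty:

* ``sample_mean_uncertainty`` — ``u_s = 1 − 2(s̄ − 0.5)²`` on the row mean
  ``s̄``; maximal (1.0) at ``s̄ = 0.5`` and 0.5 at the endpoints.
* ``sample_variance`` — population variance of the ``T`` samples.
* ``entropy`` — Shannon entropy (nats) of the mean predictive distribution;
  for two classes this is the binary entropy of ``s̄``.
* ``mutual_information`` — entropy of the mean minus the mean per-sample
  entropy; measures *disagreement* among the ``T`` samples and vanishes for
  constant rows.

``baseline_uncertainty`` applies the ``u_s`` transform to a single-model
softmax score and is the no-extra-compute comparator for misprediction
detection.  All logs are natural; evaluation downstream is rank-based, so
the base is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .samplers import SampleMatrix

__all__ = [
    "MeanScoreVector",
    "UncertaintyVector",
    "mean_score",
    "sample_mean_uncertainty",
    "baseline_uncertainty",
    "sample_variance",
    "entropy",
    "mutual_information",
    "METRICS",
    "LN2",
]

LN2 = float(np.log(2.0))
_EPS = 1e-12       # probability clamp inside logs
_MI_TOL = 1e-9     # tolerated numerical undershoot below zero


@dataclass(frozen=True)
class MeanScoreVector:
    """Per-input mean softmax score ``s̄``, in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class UncertaintyVector:
    """One uncertainty score per input, under a named metric."""

    values: np.ndarray
    metric: str
    range: tuple[float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        lo, hi = self.range
        if v.size and (v.min() < lo - 1e-12 or v.max() > hi + 1e-12):
            raise ValueError(
                f"{self.metric} values escape the valid range [{lo}, {hi}]")
        object.__setattr__(self, "values", v)


def mean_score(samples: SampleMatrix) -> MeanScoreVector:
    """Row-wise arithmetic mean of the ``T`` samples (the classical
    ensembling aggregation)."""
    return MeanScoreVector(samples.samples.mean(axis=1))


def _u_transform(s: np.ndarray) -> np.ndarray:
    return 1.0 - 2.0 * (s - 0.5) ** 2


def sample_mean_uncertainty(samples: SampleMatrix) -> UncertaintyVector:
    """``u_s = 1 − 2(s̄ − 0.5)²`` per row; in [0, 1], peaking at ``s̄ = 0.5``."""
    return UncertaintyVector(_u_transform(mean_score(samples).values),
                             metric="sample_mean_uncertainty", range=(0.0, 1.0))


def baseline_uncertainty(single_scores: MeanScoreVector) -> UncertaintyVector:
    """``u_base = 1 − 2(s − 0.5)²`` on a single-model softmax score.

    Identical to :func:`sample_mean_uncertainty` on a ``T = 1`` matrix.
    """
    return UncertaintyVector(_u_transform(single_scores.values),
                             metric="baseline", range=(0.0, 1.0))


def sample_variance(samples: SampleMatrix) -> UncertaintyVector:
    """Row-wise population variance (divide by ``T``) of the samples.

    Requires ``T >= 2``: a single sample carries no spread information.
    """
    if samples.T < 2:
        raise ValueError("sample_variance needs T >= 2")
    return UncertaintyVector(samples.samples.var(axis=1, ddof=0),
                             metric="sample_variance", range=(0.0, 0.25))


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    h = -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))
    # exact zeros for degenerate inputs rather than clamp residue
    return np.where((p <= _EPS) | (p >= 1.0 - _EPS), 0.0, h)


def entropy(samples: SampleMatrix) -> UncertaintyVector:
    """Predictive entropy of the mean distribution, in nats.

    For two classes the approximation
    ``−Σ_c (1/T) Σ_t P(ŷ=c|W_t) · log((1/T) Σ_t P(ŷ=c|W_t))``
    reduces algebraically to the binary entropy of the row mean ``s̄``,
    which is what is computed here (with the convention ``0·log 0 = 0``).
    """
    return UncertaintyVector(_binary_entropy(mean_score(samples).values),
                             metric="entropy", range=(0.0, LN2))


def mutual_information(samples: SampleMatrix) -> UncertaintyVector:
    """``MI ≈ H(mean prediction) − mean(per-sample entropies)``, in nats.

    Non-negative by Jensen's inequality; tiny negative values from floating
    point (within 1e-9) are set to exactly 0, larger ones raise.
    """
    h_of_mean = _binary_entropy(mean_score(samples).values)
    mean_of_h = _binary_entropy(samples.samples).mean(axis=1)
    mi = h_of_mean - mean_of_h
    if mi.size and mi.min() < -_MI_TOL:
        raise ArithmeticError(
            f"mutual information fell below -{_MI_TOL}: min={mi.min()}")
    mi = np.where(mi < 0.0, 0.0, mi)
    return UncertaintyVector(mi, metric="mutual_information", range=(0.0, LN2))


#: Registry of the sample-based metrics, keyed by canonical name.
METRICS = {
    "sample_mean_uncertainty": sample_mean_uncertainty,
    "sample_variance": sample_variance,
    "entropy": entropy,
    "mutual_information": mutual_information,
}
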