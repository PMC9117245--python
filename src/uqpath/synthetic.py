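"""Synthetic prediction samples and toy histology patches.

Every other module is exercisable without a trained network or any image
download.  Two generators are provided:

* :func:`generate_samples` draws an ``N × T`` sample matrix from a two-level
  model: a latent per-input "true" score on the logit scale, class-
  conditionally Gaussian, pushed through a sigmoid; then ``T`` Beta samples
  around that score whose concentration encodes how much the passes of an
  uncertainty method disagree.  Inputs near the decision boundary get extra
  dispersion, mirroring how a real classifier's errors concentrate where its
  confidence is lowest.  Two domain-shift modes degrade the latent
  separation: ``centre`` (both classes drift toward the boundary, as when a
  model meets data from another lab) and ``subtype`` (only the tumour class
  weakens, emulating a cancer subtype with a subtler appearance that is
  under-represented in training).
* :func:`generate_patches` paints toy H&E-like tiles — dark nuclear blobs on
  a pink background, dense for tumour and sparse for healthy tissue — which,
  together with :func:`analytic_predictor`, give the samplers a fully
  synthetic but honest prediction pipeline to run against.

The healthy class sits further from, and tighter around, its mean than the
tumour class (logit means at −0.6/+0.4 of the separation, SDs 1.0 vs 2.8):
for a well-trained metastasis detector, healthy tissue is the easy class,
while tumour patches vary with how much tumour they contain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .samplers import FunctionPredictor, Patch, Predictor, SampleMatrix

__all__ = [
    "SyntheticSpec",
    "ToyPatchSpec",
    "generate_samples",
    "generate_patches",
    "analytic_predictor",
    "stochastic_predictor",
    "REFERENCE_SPEC",
]

# class-conditional geometry on the logit scale (see module docstring)
_HEALTHY_FRAC = 0.6
_TUMOUR_FRAC = 0.4
_SD_HEALTHY = 1.0
_SD_TUMOUR = 2.8
_BOUNDARY_WIDTH = 0.15  # width (in score units) of the extra-dispersion bump
_MU_CLIP = 1e-6


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for prediction-sample matrices.

    Parameters
    ----------
    n_per_class
        Inputs per class (healthy first, then tumour).
    T
        Samples per input (passes / ensemble members / augmentations).
    separation
        Distance between the class-conditional mean logits; 0 makes the
        classes indistinguishable, the default 8 yields a strong classifier
        (single-model ROC-AUC ≈ 0.99) comparable to a well-trained
        metastasis detector.
    dispersion
        Beta concentration of the ``T`` samples around the latent score
        (larger = more agreement).  ``inf`` collapses each row to a point
        mass.
    mispredict_dispersion_boost
        Dispersion multiplier (≥ 1) for inputs whose latent score lies near
        0.5, concentrating sample disagreement on boundary cases.
    shift
        ``"none"``, ``"centre"`` (both class means pulled toward the
        boundary) or ``"subtype"`` (tumour mean pulled toward the healthy
        class only).
    shift_severity
        0 disables the shift; 1 collapses the affected mean(s) onto the
        opposing value.
    """

    n_per_class: int = 2000
    T: int = 50
    separation: float = 8.0
    dispersion: float = 60.0
    mispredict_dispersion_boost: float = 6.0
    shift: str = "none"
    shift_severity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        if self.mispredict_dispersion_boost < 1:
            raise ValueError("mispredict_dispersion_boost must be >= 1")
        if self.shift not in ("none", "centre", "subtype"):
            raise ValueError("shift must be 'none', 'centre' or 'subtype'")
        if self.shift_severity < 0:
            raise ValueError("shift_severity must be >= 0")


#: The documented reference scenario used by the end-to-end pipeline.
REFERENCE_SPEC = SyntheticSpec()


def generate_samples(spec: SyntheticSpec) -> SampleMatrix:
    """Draw a fully reproducible :class:`SampleMatrix` from ``spec``.

    The matrix is labelled ``method="ensemble"``: it emulates the samples an
    ensemble (or any other multi-pass method) would have produced.  Column 0
    doubles as the "single model" score where one is needed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    labels = np.concatenate([np.zeros(n, dtype=np.int64),
                             np.ones(n, dtype=np.int64)])
    mean = np.where(labels == 1, _TUMOUR_FRAC * spec.separation,
                    -_HEALTHY_FRAC * spec.separation)
    sd = np.where(labels == 1, _SD_TUMOUR, _SD_HEALTHY)
    z = rng.normal(mean, sd)
    if spec.shift == "centre":
        z = z - spec.shift_severity * mean
    elif spec.shift == "subtype":
        z = z - spec.shift_severity * np.where(labels == 1, spec.separation, 0.0)
    mu = np.clip(expit(z), _MU_CLIP, 1.0 - _MU_CLIP)

    if math.isinf(spec.dispersion):
        samples = np.tile(mu[:, None], (1, spec.T))
    else:
        boost = 1.0 + (spec.mispredict_dispersion_boost - 1.0) * np.exp(
            -((mu - 0.5) / _BOUNDARY_WIDTH) ** 2)
        kappa = (spec.dispersion / boost)[:, None]
        samples = rng.beta(mu[:, None] * kappa, (1.0 - mu[:, None]) * kappa,
                           size=(2 * n, spec.T))
        samples = np.clip(samples, 0.0, 1.0)
    method = "ensemble" if spec.T > 1 else "single"
    ids = tuple(f"syn_{i:06d}" for i in range(2 * n))
    return SampleMatrix(samples, labels, method=method, ids=ids)


@dataclass(frozen=True)
class ToyPatchSpec:
    """Parameters for toy H&E-like tiles: dark hematoxylin-stained blobs on
    an eosin-pink background, with per-class blob coverage."""

    size: int = 64
    tumour_blob_density: float = 0.45
    healthy_blob_density: float = 0.08
    stain_palette: tuple[tuple[float, float, float],
                         tuple[float, float, float]] = (
        (0.92, 0.74, 0.82),   # eosin-like background
        (0.30, 0.18, 0.48),   # hematoxylin-like nuclei
    )
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        for d in (self.tumour_blob_density, self.healthy_blob_density):
            if not 0.0 <= d <= 1.0:
                raise ValueError("blob densities must lie in [0, 1]")


def _paint_patch(spec: ToyPatchSpec, density: float,
                 rng: np.random.Generator) -> np.ndarray:
    size = spec.size
    bg, fg = (np.asarray(c) for c in spec.stain_palette)
    img = np.tile(bg, (size, size, 1)).astype(np.float64)
    r_lo, r_hi = size / 16.0, size / 8.0
    r_mean = (r_lo + r_hi) / 2.0
    n_blobs = int(round(density * size * size / (np.pi * r_mean ** 2)))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, 2)
        r = rng.uniform(r_lo, r_hi)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[mask] = fg
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_patches(spec: ToyPatchSpec,
                     n_per_class: int) -> tuple[list[Patch], np.ndarray]:
    """Generate ``n_per_class`` healthy then ``n_per_class`` tumour patches
    with their labels, reproducibly from ``spec.seed``."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    patches: list[Patch] = []
    labels = np.concatenate([np.zeros(n_per_class, dtype=np.int64),
                             np.ones(n_per_class, dtype=np.int64)])
    densities = [spec.healthy_blob_density, spec.tumour_blob_density]
    for i, lab in enumerate(labels):
        img = _paint_patch(spec, densities[lab], rng)
        patches.append(Patch(img, identifier=f"toy_{i:05d}"))
    return patches, labels


_DARK_CUTOFF = 0.5       # luminance below which a pixel counts as stained
_DENSITY_MIDPOINT = 0.25  # blob fraction at which the predictor is undecided


def _dark_fraction(patch: Patch) -> float:
    lum = patch.pixels @ np.array([0.2126, 0.7152, 0.0722])
    return float((lum < _DARK_CUTOFF).mean())


def analytic_predictor(sharpness: float = 12.0) -> Predictor:
    """A deterministic closed-form predictor over toy patches.

    Maps the patch's dark-blob pixel fraction through a logistic centred at
    0.25 coverage: all-background patches score near 0, blob-saturated
    patches near 1.  A family of sharpnesses stands in for an ensemble of
    independently trained models.
    """
    if not sharpness > 0:
        raise ValueError("sharpness must be positive")

    def fn(patch: Patch) -> float:
        return float(expit(sharpness * (_dark_fraction(patch) - _DENSITY_MIDPOINT)))

    return FunctionPredictor(fn, stochastic_mode=False)


def stochastic_predictor(base: Predictor, logit_sd: float = 0.5) -> Predictor:
    """Wrap a deterministic predictor with logit-space Gaussian noise.

    The wrapped predictor declares ``stochastic_mode=True`` and stands in
    for a dropout-enabled network: each call perturbs the base score on the
    logit scale, keeping the output inside (0, 1).
    """
    if base.stochastic_mode:
        raise ValueError("base predictor must be deterministic")
    if logit_sd < 0:
        raise ValueError("logit_sd must be >= 0")

    def fn(patch: Patch, rng: np.random.Generator | None) -> float:
        if rng is None:
            raise ValueError("stochastic predictor requires an rng")
        s = np.clip(base.predict(patch), 1e-9, 1 - 1e-9)
        return float(expit(logit(s) + rng.normal(0.0, logit_sd)))

    return FunctionPredictor(fn, stochastic_mode=True)
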