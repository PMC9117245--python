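"""Prediction sampling for uncertainty estimation.

Three model-agnostic strategies produce, for every input patch, ``T``
tumour-class softmax scores whose spread carries the uncertainty signal:

* **MC dropout** — ``T`` stochastic forward passes through a predictor whose
  dropout layers stay active at inference (reference configuration: dropout
  probability 0.5 before the logits, ``T`` = 50).
* **Deep ensembles** — one deterministic pass per member of an ensemble of
  identically built, independently seeded models (``T`` = number of members,
  conventionally 5).
* **Test-time augmentation (TTA)** — ``T`` passes of one deterministic model
  over randomly augmented copies of the patch (``T`` = 50), using the same
  augmentation family as histopathology training pipelines: flips, right-angle
  rotations, mild rescaling, HSV colour jitter, brightness/contrast,
  additive Gaussian noise and Gaussian blur.

The result of every sampler is a :class:`SampleMatrix`, the package's
universal interchange object.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.filters import gaussian
from skimage.transform import rescale

__all__ = [
    "Patch",
    "Predictor",
    "FunctionPredictor",
    "AugmentationSpec",
    "AugmentationParams",
    "SampleMatrix",
    "augment",
    "draw_augmentation_params",
    "apply_augmentation",
    "sample_mc_dropout",
    "sample_ensemble",
    "sample_tta",
]

_METHODS = ("mc_dropout", "ensemble", "tta", "single")


@dataclass(frozen=True)
class Patch:
    """An RGB tissue patch with channel values in [0, 1].

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array, each channel in [0, 1]; ``H, W >= 8``.
    identifier
        A stable name used in serialised sample tables.
    """

    pixels: np.ndarray
    identifier: str = "patch"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"patch must be H×W×3, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"patch must be at least 8×8, got {px.shape[:2]}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("patch channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


class Predictor:
    """Contract for user-supplied patch classifiers.

    A predictor maps a :class:`Patch` to the softmax score ``s`` of the
    tumour (positive) class, a real number in [0, 1].  ``stochastic_mode``
    declares whether repeated calls on the same patch may differ (e.g. a
    network with dropout active at inference).  Stochastic predictors receive
    a ``numpy`` :class:`~numpy.random.Generator` so that sampling stays
    reproducible; deterministic predictors may ignore it.
    """

    stochastic_mode: bool = False

    def predict(self, patch: Patch, rng: np.random.Generator | None = None) -> float:
        raise NotImplementedError


class FunctionPredictor(Predictor):
    """Adapt a plain function ``f(patch[, rng]) -> score`` to the contract."""

    def __init__(self, fn: Callable[..., float], stochastic_mode: bool = False):
        self.fn = fn
        self.stochastic_mode = stochastic_mode

    def predict(self, patch: Patch, rng: np.random.Generator | None = None) -> float:
        if self.stochastic_mode:
            return float(self.fn(patch, rng))
        return float(self.fn(patch))


@dataclass(frozen=True)
class AugmentationSpec:
    """Distribution over augmentations, defaulting to the histopathology
    training family: horizontal flip with probability 0.5, rotations by
    multiples of 90°, isotropic scaling in [0.8, 1.2], additive hue and
    saturation shifts in [−0.1, 0.1], multiplicative brightness in
    [0.65, 1.35] and contrast in [0.5, 1.5], and additive Gaussian noise and
    Gaussian blur with σ drawn from [0, 0.1]."""

    flip_prob: float = 0.5
    rot90: bool = True
    scale_range: tuple[float, float] = (0.8, 1.2)
    hue_shift_range: tuple[float, float] = (-0.1, 0.1)
    saturation_shift_range: tuple[float, float] = (-0.1, 0.1)
    brightness_range: tuple[float, float] = (0.65, 1.35)
    contrast_range: tuple[float, float] = (0.5, 1.5)
    noise_sigma_range: tuple[float, float] = (0.0, 0.1)
    blur_sigma_range: tuple[float, float] = (0.0, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be a probability")
        for name in ("scale_range", "hue_shift_range", "saturation_shift_range",
                     "brightness_range", "contrast_range",
                     "noise_sigma_range", "blur_sigma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has lower > upper: ({lo}, {hi})")

    @classmethod
    def identity(cls, seed: int = 0) -> "AugmentationSpec":
        """A spec whose every draw is the identity transform."""
        return cls(flip_prob=0.0, rot90=False, scale_range=(1.0, 1.0),
                   hue_shift_range=(0.0, 0.0), saturation_shift_range=(0.0, 0.0),
                   brightness_range=(1.0, 1.0), contrast_range=(1.0, 1.0),
                   noise_sigma_range=(0.0, 0.0), blur_sigma_range=(0.0, 0.0),
                   seed=seed)


@dataclass(frozen=True)
class AugmentationParams:
    """One concrete draw from an :class:`AugmentationSpec`.

    Holding the realised parameters separately from the transform makes every
    augmentation replayable: ``apply_augmentation(patch, params)`` is a pure
    function of its arguments (the noise field is reproduced from
    ``noise_seed``).
    """

    flip: bool
    rot_k: int
    scale: float
    hue_shift: float
    saturation_shift: float
    brightness: float
    contrast: float
    noise_sigma: float
    blur_sigma: float
    noise_seed: int


def draw_augmentation_params(spec: AugmentationSpec,
                             rng: np.random.Generator) -> AugmentationParams:
    """Draw one parameter set.  All variates are always drawn, in a fixed
    order, so the stream layout does not depend on the spec's ranges."""
    flip = bool(rng.random() < spec.flip_prob)
    rot_k = int(rng.integers(0, 4)) if spec.rot90 else 0
    return AugmentationParams(
        flip=flip,
        rot_k=rot_k,
        scale=float(rng.uniform(*spec.scale_range)),
        hue_shift=float(rng.uniform(*spec.hue_shift_range)),
        saturation_shift=float(rng.uniform(*spec.saturation_shift_range)),
        brightness=float(rng.uniform(*spec.brightness_range)),
        contrast=float(rng.uniform(*spec.contrast_range)),
        noise_sigma=float(rng.uniform(*spec.noise_sigma_range)),
        blur_sigma=float(rng.uniform(*spec.blur_sigma_range)),
        noise_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _restore_shape(img: np.ndarray, h: int, w: int) -> np.ndarray:
    """Centre-crop (larger) or reflect-pad (smaller) back to (h, w)."""
    ih, iw = img.shape[:2]
    if ih > h:
        top = (ih - h) // 2
        img = img[top:top + h]
    if iw > w:
        left = (iw - w) // 2
        img = img[:, left:left + w]
    ih, iw = img.shape[:2]
    if ih < h or iw < w:
        pad_h, pad_w = h - ih, w - iw
        img = np.pad(img,
                     ((pad_h // 2, pad_h - pad_h // 2),
                      (pad_w // 2, pad_w - pad_w // 2),
                      (0, 0)),
                     mode="reflect")
    return img


def apply_augmentation(patch: Patch, params: AugmentationParams) -> Patch:
    """Apply a realised augmentation in the canonical order: geometric
    (flip, rot90, scale), then colour (HSV shift, brightness, contrast),
    then additive noise, then blur.  Output shape equals input shape and
    values are clamped to [0, 1]."""
    img = patch.pixels
    h, w = img.shape[:2]

    if params.flip:
        img = img[:, ::-1]
    if params.rot_k % 4:
        img = np.rot90(img, k=params.rot_k)
    if params.scale != 1.0:
        img = rescale(img, params.scale, channel_axis=-1, order=1,
                      mode="reflect", anti_aliasing=False)
        img = _restore_shape(img, h, w)
    img = np.ascontiguousarray(np.clip(img, 0.0, 1.0))

    if params.hue_shift != 0.0 or params.saturation_shift != 0.0:
        hsv = rgb2hsv(img)
        hsv[..., 0] = np.mod(hsv[..., 0] + params.hue_shift, 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] + params.saturation_shift, 0.0, 1.0)
        img = np.clip(hsv2rgb(hsv), 0.0, 1.0)
    if params.brightness != 1.0:
        img = np.clip(img * params.brightness, 0.0, 1.0)
    if params.contrast != 1.0:
        mean = img.mean(axis=(0, 1), keepdims=True)
        img = np.clip(mean + params.contrast * (img - mean), 0.0, 1.0)
    if params.noise_sigma > 0.0:
        noise_rng = np.random.default_rng(params.noise_seed)
        img = np.clip(img + noise_rng.normal(0.0, params.noise_sigma, img.shape),
                      0.0, 1.0)
    if params.blur_sigma > 0.0:
        img = np.clip(gaussian(img, sigma=params.blur_sigma, channel_axis=-1,
                               preserve_range=True), 0.0, 1.0)
    return Patch(pixels=img, identifier=patch.identifier)


def augment(patch: Patch, spec: AugmentationSpec,
            rng: np.random.Generator) -> Patch:
    """Draw one augmentation from ``spec`` and apply it to ``patch``."""
    return apply_augmentation(patch, draw_augmentation_params(spec, rng))


@dataclass(frozen=True)
class SampleMatrix:
    """``N × T`` tumour-softmax samples with ground-truth labels.

    Entry ``[i, t]`` is the tumour-class score of input ``i`` from
    pass/model/augmentation ``t``.  All uncertainty metrics aggregate over
    the ``T`` axis.
    """

    samples: np.ndarray
    labels: np.ndarray
    method: str = "single"
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        lab = np.asarray(self.labels)
        if s.ndim != 2 or s.shape[1] < 1:
            raise ValueError("samples must be an N×T matrix with T >= 1")
        if s.size and (s.min() < 0.0 or s.max() > 1.0):
            raise ValueError("sample scores must lie in [0, 1]")
        if lab.shape != (s.shape[0],):
            raise ValueError("labels length must equal the number of rows")
        if lab.size and not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.method == "single" and s.shape[1] != 1:
            raise ValueError("method 'single' implies T = 1")
        ids = tuple(self.ids) if self.ids else tuple(
            f"input_{i:06d}" for i in range(s.shape[0]))
        if len(ids) != s.shape[0]:
            raise ValueError("ids length must equal the number of rows")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "labels", lab.astype(np.int64))
        object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def T(self) -> int:
        return self.samples.shape[1]

    def column(self, t: int = 0) -> np.ndarray:
        """Scores of a single pass/model, e.g. the 'one NN' baseline."""
        return self.samples[:, t].copy()


def _pair_rng(seed: int, i: int, t: int) -> np.random.Generator:
    # One independent stream per (input, pass): appending patches or passes
    # never perturbs existing entries.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, t)))


def _checked(score: float, what: str) -> float:
    s = float(score)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"{what} returned a score outside [0, 1]: {s}")
    return s


def sample_mc_dropout(predictor: Predictor, patches: Sequence[Patch],
                      T: int = 50, seed: int = 0, *,
                      allow_deterministic: bool = False) -> SampleMatrix:
    """Run ``T`` stochastic forward passes per patch.

    The predictor must declare ``stochastic_mode=True``: with a
    deterministic predictor every row would be constant and all spread-based
    uncertainty degenerates to zero, which almost always signals user error.
    Set ``allow_deterministic=True`` to force the call through anyway.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not predictor.stochastic_mode and not allow_deterministic:
        raise ValueError(
            "MC-dropout sampling needs a predictor with stochastic_mode=True "
            "(pass allow_deterministic=True to override)")
    out = np.empty((len(patches), T))
    for i, patch in enumerate(patches):
        for t in range(T):
            out[i, t] = _checked(
                predictor.predict(patch, rng=_pair_rng(seed, i, t)), "predictor")
    return SampleMatrix(out, _zeros_labels(len(patches)), method="mc_dropout",
                        ids=tuple(p.identifier for p in patches))


def sample_ensemble(predictors: Sequence[Predictor],
                    patches: Sequence[Patch]) -> SampleMatrix:
    """One deterministic pass per ensemble member; ``T`` = len(predictors)."""
    if len(predictors) == 0:
        raise ValueError("ensemble needs at least one predictor")
    for k, p in enumerate(predictors):
        if p.stochastic_mode:
            raise ValueError(f"ensemble member {k} must be deterministic")
    out = np.empty((len(patches), len(predictors)))
    for i, patch in enumerate(patches):
        for t, p in enumerate(predictors):
            out[i, t] = _checked(p.predict(patch), f"ensemble member {t}")
    method = "ensemble" if len(predictors) > 1 else "single"
    return SampleMatrix(out, _zeros_labels(len(patches)), method=method,
                        ids=tuple(p.identifier for p in patches))


def sample_tta(predictor: Predictor, patches: Sequence[Patch],
               T: int = 50,
               spec: AugmentationSpec | None = None) -> SampleMatrix:
    """Predict on ``T`` randomly augmented copies of each patch.

    Augmentation draws are reproducible from ``spec.seed``; the augmented
    patch keeps the original height and width, so any predictor that accepts
    the original patch accepts its augmented versions.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if predictor.stochastic_mode:
        raise ValueError("TTA expects a deterministic predictor; the spread "
                         "must come from the augmentations alone")
    spec = spec if spec is not None else AugmentationSpec()
    out = np.empty((len(patches), T))
    for i, patch in enumerate(patches):
        for t in range(T):
            aug = augment(patch, spec, _pair_rng(spec.seed, i, t))
            out[i, t] = _checked(predictor.predict(aug), "predictor")
    return SampleMatrix(out, _zeros_labels(len(patches)), method="tta",
                        ids=tuple(p.identifier for p in patches))


def _zeros_labels(n: int) -> np.ndarray:
    # Samplers do not know ground truth; callers attach labels via `replace`.
    return np.zeros(n, dtype=np.int64)


def with_labels(matrix: SampleMatrix, labels: np.ndarray) -> SampleMatrix:
    """Return a copy of ``matrix`` carrying the given ground-truth labels."""
    return replace(matrix, labels=np.asarray(labels))
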