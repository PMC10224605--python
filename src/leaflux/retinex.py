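"""Single- and multi-scale Retinex illumination correction.

Retinex color constancy assumes the observed image is the product of a
surface-reflectance component and an illumination component,
``S(x, y) = L(x, y) * R(x, y)``, and separates them in the log domain:
``log R = log S - log L``.  Single-scale Retinex (SSR) estimates ``log L``
as the log of a Gaussian-surround low-pass of the image; multi-scale
Retinex (MSR) averages SSR outputs over several surround scales with
weights summing to one, trading illumination removal (large scales) against
detail preservation (small scales).

The automated configuration used here derives three surround scales from
the image size — (0.01, 0.10, 0.30) x min(H, W) with equal weights — a
deterministic, reproducible rule that covers fine texture through
field-scale gradients.  The unbounded log-domain output is mapped to [0, 1]
by an affine stretch: by default an image-independent fixed map (so that
corrected frames from different acquisitions share one scale), with
adaptive per-image min-max and clipped mu +/- k*sigma windows available
for display (see :class:`RetinexConfig`).

Because a global gain multiplies both the image and its surround, SSR and
MSR are exactly invariant to global illumination rescaling when the log
guard epsilon is zero — the property that makes corrected images comparable
across acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "RetinexConfig",
    "RetinexDecomposition",
    "gaussian_kernel",
    "gaussian_surround",
    "ssr",
    "msr",
    "auto_scales",
    "stretch_to_unit",
    "stretch_minmax",
    "stretch_fixed",
    "correct_image",
]

#: kernel truncation radius in standard deviations
TRUNCATE = 3.0
#: boundary handling for the surround convolution; reflection avoids the
#: darkened borders a zero pad would produce
BOUNDARY_MODE = "reflect"

AUTO_SCALE_FRACTIONS = (0.01, 0.10, 0.30)
MIN_IMAGE_SIDE = 16


@dataclass(frozen=True)
class RetinexConfig:
    """Surround scales (pixels), their weights, and output mapping.

    ``stretch_mode`` selects how the unbounded log-domain output is mapped
    to [0, 1]:

    * ``"fixed"`` (default) — the image-independent affine map
      ``0.5 + x / (2 * log_span)``, clipped to [0, 1].  MSR output 0 (a
      pixel equal to its surround) always lands at 0.5, so two corrected
      images are directly comparable — the point of the correction;
    * ``"minmax"`` — rank-preserving per-channel map of the full range;
    * ``"zscore"`` — the classical clipped mu +/- stretch_k*sigma window.

    The adaptive modes make the output depend on each image's content,
    which re-introduces cross-image differences (and the z-score window
    clips minority classes far from the image bulk, e.g. a small canopy
    fraction on bare soil); they are kept for display use.
    """

    scales: tuple[float, ...]
    weights: tuple[float, ...]
    epsilon: float = 1e-6
    stretch_k: float = 2.0
    stretch_mode: str = "fixed"
    log_span: float = 5.0
    auto: bool = False

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.weights):
            raise ValueError("scales and weights must have equal length")
        if any(s <= 0 for s in self.scales):
            raise ValueError("all surround scales must be positive")
        if any(a >= b for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.epsilon < 0 or self.stretch_k <= 0:
            raise ValueError("epsilon must be >= 0 and stretch_k > 0")
        if self.stretch_mode not in ("fixed", "minmax", "zscore"):
            raise ValueError("stretch_mode must be 'fixed', 'minmax' or 'zscore'")
        if self.log_span <= 0:
            raise ValueError("log_span must be positive")


@dataclass(frozen=True)
class RetinexDecomposition:
    """Log-domain reflectance estimate and its [0, 1] stretched rendering."""

    log_reflectance: np.ndarray
    corrected: np.ndarray


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete Gaussian surround kernel, truncated at 3 sigma, sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = max(1, int(np.ceil(TRUNCATE * sigma)))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_surround(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-surround low-pass of an image (per channel if 3-D)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return ndi.gaussian_filter(img, sigma, mode=BOUNDARY_MODE, truncate=TRUNCATE)
    if img.ndim == 3:
        return ndi.gaussian_filter(
            img, (sigma, sigma, 0), mode=BOUNDARY_MODE, truncate=TRUNCATE
        )
    raise ValueError("expected a 2-D or 3-D image")


def ssr(image: np.ndarray, sigma: float, epsilon: float = 1e-6) -> np.ndarray:
    """Single-scale Retinex: log(image) minus log of its Gaussian surround."""
    img = np.asarray(image, dtype=float)
    if np.any(img < 0):
        raise ValueError("image values must be >= 0")
    return np.log(img + epsilon) - np.log(gaussian_surround(img, sigma) + epsilon)


def msr(image: np.ndarray, config: RetinexConfig) -> np.ndarray:
    """Multi-scale Retinex: weighted sum of SSR outputs over the scales."""
    img = np.asarray(image, dtype=float)
    out = np.zeros_like(img)
    for sigma, w in zip(config.scales, config.weights):
        out += w * ssr(img, sigma, config.epsilon)
    return out


def auto_scales(shape: tuple[int, int]) -> RetinexConfig:
    """Size-proportional three-scale configuration with equal weights."""
    h, w = shape[:2]
    if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
        raise ValueError(f"image must be at least {MIN_IMAGE_SIDE} px per side")
    m = min(h, w)
    return RetinexConfig(
        scales=tuple(f * m for f in AUTO_SCALE_FRACTIONS),
        weights=(1 / 3, 1 / 3, 1 / 3),
        auto=True,
    )


def stretch_to_unit(log_map: np.ndarray, stretch_k: float = 2.0) -> np.ndarray:
    """Affine per-channel map of [mu - k*sigma, mu + k*sigma] onto [0, 1].

    Values outside the window are clipped; a constant channel (sigma = 0)
    maps to 0.5.
    """
    if stretch_k <= 0:
        raise ValueError("stretch_k must be positive")
    x = np.asarray(log_map, dtype=float)
    added_axis = x.ndim == 2
    if added_axis:
        x = x[..., None]
    mu = x.mean(axis=(0, 1), keepdims=True)
    sd = x.std(axis=(0, 1), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, (x - mu) / (2.0 * stretch_k * sd) + 0.5, 0.5)
    out = np.clip(out, 0.0, 1.0)
    return out[..., 0] if added_axis else out


def stretch_minmax(log_map: np.ndarray) -> np.ndarray:
    """Rank-preserving per-channel affine map of the full range onto [0, 1].

    No clipping, so within-class contrast survives even for classes far
    from the image bulk; a constant channel maps to 0.5.
    """
    x = np.asarray(log_map, dtype=float)
    added_axis = x.ndim == 2
    if added_axis:
        x = x[..., None]
    lo = x.min(axis=(0, 1), keepdims=True)
    hi = x.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.5)
    return out[..., 0] if added_axis else out


def stretch_fixed(log_map: np.ndarray, log_span: float = 5.0) -> np.ndarray:
    """Image-independent affine map ``0.5 + x / (2 * log_span)``, clipped.

    A log-ratio of 0 (pixel equals its surround) maps to 0.5 for every
    image, so corrected frames from different acquisitions share one scale.
    """
    if log_span <= 0:
        raise ValueError("log_span must be positive")
    return np.clip(0.5 + np.asarray(log_map, dtype=float) / (2.0 * log_span), 0.0, 1.0)


def _stretch(log_map: np.ndarray, config: RetinexConfig) -> np.ndarray:
    if config.stretch_mode == "zscore":
        return stretch_to_unit(log_map, config.stretch_k)
    if config.stretch_mode == "minmax":
        return stretch_minmax(log_map)
    return stretch_fixed(log_map, config.log_span)


def correct_image(
    image: np.ndarray, config: RetinexConfig | None = None
) -> np.ndarray:
    """Full Retinex correction of one RGB frame, output in [0, 1].

    Integer input is first scaled by full scale (255 for 8-bit); float input
    is taken as already in [0, 1].  Applies MSR with the given or the
    automatic size-derived configuration, then the configured output
    stretch.  Deterministic.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / float(np.iinfo(image.dtype).max)
    if config is None:
        config = auto_scales(img.shape[:2])
    return _stretch(msr(img, config), config)


def decompose(image: np.ndarray, config: RetinexConfig | None = None) -> RetinexDecomposition:
    """Return both the raw log-domain MSR output and its stretched rendering."""
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / float(np.iinfo(image.dtype).max)
    if config is None:
        config = auto_scales(img.shape[:2])
    log_r = msr(img, config)
    return RetinexDecomposition(log_r, _stretch(log_r, config))
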