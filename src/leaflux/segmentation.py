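"""Vegetation segmentation and per-plant zonal extraction.

A two-class maximum-likelihood classifier (Gaussian class-conditional
densities with empirical priors, the classical remote-sensing MLC)
separates vegetation from background on per-pixel RGB features.  Sampled
plants are then summarized through square buffers — 0.2 m side by default,
converted to pixels via the ground sampling distance — intersected with
the vegetation mask, and the mean of each vegetation-index map over that
intersection is the plant's zonal value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MLCModel",
    "PlantBuffer",
    "TrainingError",
    "train_mlc",
    "classify",
    "make_buffers",
    "zonal_mean",
]

BACKGROUND, VEGETATION = 0, 1
MIN_PIXELS_PER_CLASS = 4
#: relative ridge added to covariance diagonals; synthetic constant regions
#: can otherwise be rank-deficient
COV_RIDGE = 1e-6


class TrainingError(ValueError):
    """Raised when a class is absent or too small to estimate a Gaussian."""


@dataclass(frozen=True)
class MLCModel:
    """Gaussian class-conditional model for {background, vegetation}."""

    means: np.ndarray    # (2, 3)
    covs: np.ndarray     # (2, 3, 3)
    priors: np.ndarray   # (2,)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        for c in self.covs:
            if not np.allclose(c, c.T):
                raise ValueError("covariances must be symmetric")
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be positive definite")


@dataclass(frozen=True)
class PlantBuffer:
    """Square pixel buffer centred on a sampled plant (half-open ranges)."""

    plant_id: int
    center: tuple[int, int]
    side_m: float
    side_px: int
    row0: int
    row1: int
    col0: int
    col1: int

    @property
    def area_px(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


def train_mlc(features: np.ndarray, labels: np.ndarray) -> MLCModel:
    """Estimate per-class mean, covariance and empirical priors.

    ``features`` is (N, 3); ``labels`` holds 0 (background) / 1 (vegetation).
    Covariances get a small relative ridge (1e-6 x mean variance) on the
    diagonal so degenerate training regions remain invertible.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("features must be (N, 3)")
    means, covs, counts = [], [], []
    for cls in (BACKGROUND, VEGETATION):
        xc = x[y == cls]
        if xc.shape[0] < MIN_PIXELS_PER_CLASS:
            raise TrainingError(
                f"class {cls} has {xc.shape[0]} pixels; need >= {MIN_PIXELS_PER_CLASS}"
            )
        cov = np.cov(xc.T, ddof=1)
        ridge = COV_RIDGE * max(np.trace(cov) / 3.0, 1e-6)
        covs.append(cov + ridge * np.eye(3))
        means.append(xc.mean(axis=0))
        counts.append(xc.shape[0])
    counts = np.asarray(counts, dtype=float)
    return MLCModel(np.asarray(means), np.asarray(covs), counts / counts.sum())


def _log_density(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(cov)
    inv = np.linalg.inv(cov)
    d = x - mean
    maha = np.einsum("...i,ij,...j->...", d, inv, d)
    return -0.5 * (maha + logdet + 3 * np.log(2 * np.pi))


def classify(image_features: np.ndarray, model: MLCModel) -> np.ndarray:
    """Per-pixel argmax of log prior + Gaussian log density.

    Accepts (H, W, 3) or (N, 3) features; returns a boolean vegetation
    mask of the leading shape.  Ties break to background — the conservative
    choice for index extraction.
    """
    x = np.asarray(image_features, dtype=float)
    ll_bg = _log_density(x, model.means[0], model.covs[0]) + np.log(model.priors[0])
    ll_vg = _log_density(x, model.means[1], model.covs[1]) + np.log(model.priors[1])
    return ll_vg > ll_bg


def sample_training_pixels(
    image: np.ndarray,
    labels: np.ndarray,
    vegetation_label: int = 1,
    n_per_class: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a balanced random training sample from a labelled image.

    ``labels`` equal to ``vegetation_label`` become the vegetation class;
    every other label is background.  Used to emulate an analyst drawing
    training polygons on a frame.
    """
    rng = np.random.default_rng(seed)
    flat = np.asarray(image, dtype=float).reshape(-1, 3)
    veg = (np.asarray(labels).reshape(-1) == vegetation_label)
    feats, labs = [], []
    for cls, sel in ((BACKGROUND, ~veg), (VEGETATION, veg)):
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            raise TrainingError(f"no pixels available for class {cls}")
        take = rng.choice(idx, size=min(n_per_class, idx.size), replace=False)
        feats.append(flat[take])
        labs.append(np.full(take.size, cls))
    return np.concatenate(feats), np.concatenate(labs)


def make_buffers(
    plants: pd.DataFrame,
    gsd_m: float,
    side_m: float = 0.2,
    image_shape: tuple[int, int] | None = None,
) -> list[PlantBuffer]:
    """Square buffers of ``side_m`` metres centred on plant coordinates.

    ``plants`` needs columns ``plant_id``, ``row``, ``col`` (0-based pixel
    centres).  side_px = max(1, round(side_m / gsd_m)); buffers are clipped
    to the image bounds when a shape is given, and a plant centre outside
    the image raises an ``IndexError``.
    """
    if gsd_m <= 0:
        raise ValueError("gsd_m must be positive")
    side_px = max(1, round(side_m / gsd_m))
    half = side_px // 2
    out = []
    for rec in plants.itertuples(index=False):
        r, c = int(rec.row), int(rec.col)
        if image_shape is not None:
            h, w = image_shape
            if not (0 <= r < h and 0 <= c < w):
                raise IndexError(f"plant {rec.plant_id} centre ({r}, {c}) outside image")
        r0, c0 = r - half, c - half
        r1, c1 = r0 + side_px, c0 + side_px
        if image_shape is not None:
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, h), min(c1, w)
        out.append(
            PlantBuffer(int(rec.plant_id), (r, c), side_m, side_px, r0, r1, c0, c1)
        )
    return out


def zonal_mean(
    vi_map: np.ndarray,
    mask: np.ndarray,
    buffers: Sequence[PlantBuffer],
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean of each VI band over buffer-and-mask intersections.

    ``vi_map`` is (H, W) or (H, W, K).  NaN pixels (guarded divisions) are
    ignored; a plant whose valid fraction for a band falls below
    ``min_valid_fraction`` of its in-mask pixels gets NaN for that band.
    An empty buffer-mask intersection yields an all-NaN row with a warning.
    """
    vm = np.asarray(vi_map, dtype=float)
    squeeze = vm.ndim == 2
    if squeeze:
        vm = vm[..., None]
    if vm.shape[:2] != np.asarray(mask).shape:
        raise ValueError("vi_map and mask shapes disagree")
    k = vm.shape[-1]
    rows = []
    for buf in buffers:
        sub = vm[buf.row0 : buf.row1, buf.col0 : buf.col1, :]
        msk = np.asarray(mask, dtype=bool)[buf.row0 : buf.row1, buf.col0 : buf.col1]
        vals = sub[msk]  # (n_pixels, k)
        if vals.shape[0] == 0:
            logger.warning(
                "plant %d: buffer does not intersect the vegetation mask", buf.plant_id
            )
            rows.append([np.nan] * k)
            continue
        valid = np.isfinite(vals)
        counts = valid.sum(axis=0)
        frac = counts / vals.shape[0]
        sums = np.where(valid, vals, 0.0).sum(axis=0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        dropped = frac < min_valid_fraction
        if dropped.any():
            logger.warning(
                "plant %d: %d band(s) below %.0f%% valid pixels, dropped",
                buf.plant_id,
                int(dropped.sum()),
                100 * min_valid_fraction,
            )
        means = np.where(dropped, np.nan, means)
        rows.append(means.tolist())
    df = pd.DataFrame(rows, columns=[f"band{i}" for i in range(k)])
    df.insert(0, "plant_id", [b.plant_id for b in buffers])
    if squeeze:
        df = df.rename(columns={"band0": "value"})
    return df
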