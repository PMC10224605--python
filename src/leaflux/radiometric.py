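"""RGB value conventions and empirical-line (ELM) calibration.

Two dimensionless value conventions for 8-bit imagery:

* scaling — each channel divided by the full-scale value 255, giving
  values in [0, 1];
* normalization — each channel divided by the channel sum (chromaticity),
  giving values that sum to 1 and are invariant to overall intensity.

The empirical line method maps raw digital numbers to surface reflectance
(percent) by regressing the known reflectances of in-scene grey panels on
their observed DNs.  For a log-responding camera the relationship is
exponential, ``reflectance = a * exp(b * DN)`` per channel; the fit is done
by ordinary least squares on ``ln(reflectance)`` (closed form, deterministic)
and goodness of fit is reported on both the reflectance and the log scale.

ELM assumes the illumination is uniform over the frame: under a spatially
varying field the corrected reflectance is wrong by exactly that field,
which is why a spatial correction (Retinex) is needed for variable skies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .scene import PanelSpec

__all__ = [
    "ELMChannelModel",
    "PanelReadout",
    "ElmFitError",
    "scale_rgb",
    "normalize_rgb",
    "extract_panel_dns",
    "fit_elm",
    "apply_elm",
]

CHANNELS = ("R", "G", "B")

#: a panel-channel is unusable when at least this fraction of its pixels sit
#: at the DN rails (0 or 255)
SATURATION_FRACTION = 0.01


class ElmFitError(ValueError):
    """Raised when fewer than two usable, distinct panel DNs are available."""


@dataclass(frozen=True)
class ELMChannelModel:
    """Per-channel exponential DN-to-reflectance model ``a * exp(b * DN)``.

    ``r2`` is the coefficient of determination computed on the reflectance
    scale (primary); ``r2_log`` is the same on the log scale on which the
    least-squares fit is performed.
    """

    channel: str
    a: float
    b: float
    r2: float
    r2_log: float

    def predict(self, dn) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(dn, dtype=float))


def scale_rgb(dn) -> np.ndarray:
    """Divide 8-bit values by full scale (255), yielding floats in [0, 1]."""
    dn = np.asarray(dn, dtype=float)
    if np.any(dn < 0) or np.any(dn > 255):
        raise ValueError("DN values must lie in [0, 255]")
    return dn / 255.0


def normalize_rgb(values) -> np.ndarray:
    """Chromaticity normalization: divide each channel by the channel sum.

    Works on a single (r, g, b) triplet or an (..., 3) array.  Outputs sum
    to 1 per pixel and are invariant to positive per-pixel rescaling.  An
    all-zero triplet maps to the neutral grey (1/3, 1/3, 1/3), the limit of
    grey inputs.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("last axis must hold the three channels")
    if np.any(v < 0):
        raise ValueError("components must be non-negative")
    s = v.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, v / np.where(s > 0, s, 1.0), 1.0 / 3.0)
    return out


class PanelReadout(NamedTuple):
    """Mean DN per panel and channel, with rail-saturation flags."""

    mean_dn: np.ndarray      # (n_panels, 3)
    flagged: np.ndarray      # (n_panels, 3) bool
    saturated_frac: np.ndarray
    zero_frac: np.ndarray


def extract_panel_dns(image: np.ndarray, panels: PanelSpec) -> PanelReadout:
    """Mean DN over each panel footprint, flagging clipped panels.

    A panel-channel is flagged when >= 1 % of its pixels sit at DN 255
    (saturated) or DN 0 (underexposed); flagged entries are excluded from
    the ELM fit.
    """
    h, w = image.shape[:2]
    n = len(panels.footprints)
    mean_dn = np.zeros((n, 3))
    sat = np.zeros((n, 3))
    zero = np.zeros((n, 3))
    for i, (r0, c0, r1, c1) in enumerate(panels.footprints):
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise IndexError(f"panel {i} footprint {panels.footprints[i]} outside image")
        patch = np.asarray(image[r0:r1, c0:c1, :], dtype=float)
        mean_dn[i] = patch.reshape(-1, 3).mean(axis=0)
        sat[i] = (patch == 255).reshape(-1, 3).mean(axis=0)
        zero[i] = (patch == 0).reshape(-1, 3).mean(axis=0)
    flagged = (sat >= SATURATION_FRACTION) | (zero >= SATURATION_FRACTION)
    return PanelReadout(mean_dn, flagged, sat, zero)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 1.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def fit_elm(
    panel_dns: np.ndarray | PanelReadout,
    panel_reflectances: Sequence[float],
    flagged: np.ndarray | None = None,
) -> tuple[ELMChannelModel, ELMChannelModel, ELMChannelModel]:
    """Fit the per-channel exponential DN-to-reflectance models.

    ``panel_dns`` is an (n_panels, 3) array of mean DNs or a
    :class:`PanelReadout` (whose flags are then used).  The fit is ordinary
    least squares of ``ln(reflectance) = ln(a) + b * DN``; flagged panels
    are excluded per channel.  Requires at least two usable panels with
    distinct DNs per channel.
    """
    if isinstance(panel_dns, PanelReadout):
        if flagged is None:
            flagged = panel_dns.flagged
        panel_dns = panel_dns.mean_dn
    dns = np.asarray(panel_dns, dtype=float)
    rho = np.asarray(panel_reflectances, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("panel reflectances must be positive")
    if dns.shape != (rho.size, 3):
        raise ValueError("panel_dns must be (n_panels, 3)")
    if flagged is None:
        flagged = np.zeros_like(dns, dtype=bool)

    models = []
    for c, name in enumerate(CHANNELS):
        use = ~flagged[:, c]
        x, y = dns[use, c], rho[use]
        if np.unique(x).size < 2:
            raise ElmFitError(
                f"channel {name}: need >= 2 usable panels with distinct DNs"
            )
        slope, intercept = np.polyfit(x, np.log(y), 1)
        a, b = float(np.exp(intercept)), float(slope)
        yhat = a * np.exp(b * x)
        models.append(
            ELMChannelModel(
                channel=name,
                a=a,
                b=b,
                r2=_r2(y, yhat),
                r2_log=_r2(np.log(y), np.log(yhat)),
            )
        )
    return tuple(models)


def apply_elm(image: np.ndarray, models: Sequence[ELMChannelModel]) -> np.ndarray:
    """Convert a DN image to reflectance (percent) with fitted ELM models."""
    if len(models) != 3:
        raise ValueError("three channel models required")
    dn = np.asarray(image, dtype=float)
    out = np.empty_like(dn)
    for c in range(3):
        out[..., c] = models[c].predict(dn[..., c])
    return out
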