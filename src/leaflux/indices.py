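"""Sixteen RGB vegetation indices (E1-E16).

Six difference indices (E1-E6) and ten ratio indices (E7-E16), computed
from per-pixel (r, g, b) values under any value convention (scaled,
chromaticity-normalized, ELM- or Retinex-corrected).  Ratio indices are
invariant to a positive per-pixel scalar gain; difference indices are not,
which is precisely what makes the two families respond differently to
illumination changes.

Guarded divisions: a ratio whose denominator magnitude falls below
``division_guard`` yields NaN (a flagged missing value) rather than raising,
so downstream zonal averaging can skip the offending pixels.  VEG's alpha
exponent defaults to 0.667, the value from its source literature.  RGBVI is
implemented as printed, (g^2 - b*r) / (b^2 + b*r); ``rgbvi_legacy`` selects
the variant with g^2 in the denominator found elsewhere in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VI_CODES", "VI_NAMES", "VIParams", "compute_vi", "compute_all"]

VI_CODES = tuple(f"E{i}" for i in range(1, 17))

VI_NAMES = {
    "E1": "EXG",    # excess green
    "E2": "EXR",    # excess red
    "E3": "EXB",    # excess blue
    "E4": "EXGR",   # excess green minus excess red
    "E5": "GBDI",   # green-blue difference
    "E6": "CIVE",   # color index of vegetation extraction
    "E7": "GRRI",   # green-red ratio
    "E8": "NGRDI",  # normalized green-red difference
    "E9": "NGBDI",  # normalized green-blue difference
    "E10": "MGRVI", # modified green-red vegetation index
    "E11": "VDVI",  # visible-band difference vegetation index
    "E12": "VEG",   # vegetative index
    "E13": "COM",   # combination index
    "E14": "VARI",  # visible atmospherically resistant index
    "E15": "IKAW",  # Kawashima index
    "E16": "RGBVI", # RGB vegetation index
}

DIFFERENCE_CODES = ("E1", "E2", "E3", "E4", "E5", "E6")
RATIO_CODES = tuple(c for c in VI_CODES if c not in DIFFERENCE_CODES)

CIVE_CONSTANT = 18.78745
COM_WEIGHTS = (0.36, 0.47, 0.17)  # on EXG, CIVE, VEG; sum to 1


@dataclass(frozen=True)
class VIParams:
    alpha: float = 0.667          # VEG exponent
    division_guard: float = 1e-9  # |denominator| below this -> NaN
    rgbvi_legacy: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.division_guard <= 0:
            raise ValueError("division_guard must be positive")


def _div(num, den, guard):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    bad = np.abs(den) < guard
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / np.where(bad, 1.0, den)
    return np.where(bad, np.nan, out)


def _veg(r, g, b, params):
    # g / (r^alpha * b^(1-alpha)); needs strictly positive r and b
    bad = (r <= 0) | (b <= 0)
    rs = np.where(bad, 1.0, r)
    bs = np.where(bad, 1.0, b)
    den = rs**params.alpha * bs ** (1.0 - params.alpha)
    return np.where(bad, np.nan, _div(g, den, params.division_guard))


def compute_vi(code: str, rgb, params: VIParams | None = None) -> np.ndarray:
    """Evaluate one index on an (..., 3) array of (r, g, b) values."""
    params = params or VIParams()
    v = np.asarray(rgb, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("last axis must hold (r, g, b)")
    r, g, b = v[..., 0], v[..., 1], v[..., 2]
    gd = params.division_guard

    if code == "E1":
        return 2 * g - r - b
    if code == "E2":
        return 1.4 * r - g
    if code == "E3":
        return 1.4 * b - g
    if code == "E4":
        return (2 * g - r - b) - (1.4 * r - g)
    if code == "E5":
        return g - b
    if code == "E6":
        return 0.441 * r - 0.811 * g + 0.385 * b + CIVE_CONSTANT
    if code == "E7":
        return _div(g, r, gd)
    if code == "E8":
        return _div(g - r, g + r, gd)
    if code == "E9":
        return _div(g - b, g + b, gd)
    if code == "E10":
        return _div(g**2 - r**2, g**2 + r**2, gd)
    if code == "E11":
        return _div(2 * g - r - b, 2 * g + r + b, gd)
    if code == "E12":
        return _veg(r, g, b, params)
    if code == "E13":
        w1, w2, w3 = COM_WEIGHTS
        return (
            w1 * compute_vi("E1", v, params)
            + w2 * compute_vi("E6", v, params)
            + w3 * compute_vi("E12", v, params)
        )
    if code == "E14":
        return _div(g - r, g + r - b, gd)
    if code == "E15":
        return _div(r - b, r + b, gd)
    if code == "E16":
        den = g**2 + b * r if params.rgbvi_legacy else b**2 + b * r
        return _div(g**2 - b * r, den, gd)
    raise ValueError(f"unknown vegetation index code: {code!r}")


def compute_all(rgb, params: VIParams | None = None) -> np.ndarray:
    """All 16 indices, stacked on a trailing axis in E1..E16 order."""
    params = params or VIParams()
    return np.stack([compute_vi(c, rgb, params) for c in VI_CODES], axis=-1)
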