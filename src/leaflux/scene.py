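"""Synthetic crop scenes, illumination fields and an 8-bit camera.

This module generates the ground truth that the rest of the pipeline tries
to recover: a per-pixel surface-reflectance map ``R(x, y)`` (percent units)
containing soil, plant canopies and grey calibration panels; a multiplicative
illumination field ``L(x, y)`` decomposed into a per-channel spectral gain
and a smooth spatial modulation; and a camera whose digital-number (DN)
response is logarithmic in radiance, i.e. the exact inverse of the
exponential DN-to-reflectance family used by empirical-line calibration.
An observed image is ``DN = camera(R x L)``.

Three illumination regimes are modelled:

``sunny``
    bright, spectrally neutral, spatially uniform;
``overcast``
    dimmer and blue-shifted (short wavelengths scatter more under cloud),
    spatially uniform;
``variable``
    sunny spectral gain modulated by a smooth random spatial field,
    emulating drifting partial cloud cover.

Canopy reflectance is an affine, monotone function of each plant's
chlorophyll level: chlorophyll-rich leaves absorb strongly in the red, so
red (and to a lesser degree green) reflectance decreases with chlorophyll.
SPAD readings — the handheld-meter chlorophyll proxy used as the regression
target downstream — are an affine function of chlorophyll plus measurement
noise, calibrated so a simulated field reproduces the survey moments of a
real soybean stand (mean 47.25, std 3.00 SPAD units).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SOIL",
    "CANOPY",
    "PANEL_LABEL_BASE",
    "CONDITIONS",
    "Layout",
    "PanelSpec",
    "ReflectanceScene",
    "IlluminationField",
    "CameraModel",
    "GroundTruthSPAD",
    "PlacementError",
    "RenderError",
    "make_scene",
    "make_illumination",
    "render",
    "make_spad",
    "gsd",
]

# label codes for ReflectanceScene.labels
SOIL = 0
CANOPY = 1
PANEL_LABEL_BASE = 2  # panel k -> PANEL_LABEL_BASE + k

CONDITIONS = ("sunny", "overcast", "variable")

#: spectral gain of the bright reference condition (dimensionless)
SUNNY_GAIN = (1.0, 1.0, 1.0)
#: overcast gain: overall dimming with a blue shift (l_B/l_R > 1)
OVERCAST_GAIN = (0.45 * 0.9, 0.45 * 1.0, 0.45 * 1.1)
#: spectral ratio of a fully cloud-shadowed pixel relative to full sun:
#: shadowed ground sees diffuse skylight only, which is blue-rich
SHADOW_TINT = (0.9, 1.0, 1.1)

#: effective radiance (percent) below which the log camera response is clamped
RADIANCE_GUARD = 1e-3

# SPAD generator calibration: spad = c0 + c1 * chlorophyll + N(0, noise_sd^2).
# With chlorophyll ~ N(50, 5) these give population mean 47.25 and
# std sqrt((c1*5)^2 + noise_sd^2) = 3.00, the target survey moments.
SPAD_TARGET_MEAN = 47.25
SPAD_TARGET_STD = 3.00
SPAD_TARGET_CV_PCT = 6.35
SPAD_C1 = 0.56
SPAD_C0 = SPAD_TARGET_MEAN - SPAD_C1 * 50.0
DEFAULT_SPAD_NOISE_SD = math.sqrt(SPAD_TARGET_STD**2 - (SPAD_C1 * 5.0) ** 2)


class PlacementError(ValueError):
    """Raised when plants and panels cannot be placed without overlap."""


class RenderError(ValueError):
    """Raised when the forward model receives a non-positive radiance."""


@dataclass(frozen=True)
class Layout:
    """Geometry and radiometry of the simulated field.

    Defaults describe a 512 x 512 px frame at 0.68 cm ground sampling
    distance (a low-altitude survey), three planting plots, and four grey
    reference panels at 3.5 %, 20 %, 80 % and 84.5 % reflectance.
    """

    height: int = 512
    width: int = 512
    gsd_m: float = 0.0068
    n_plots: int = 3
    panel_reflectances: tuple[float, ...] = (3.5, 20.0, 80.0, 84.5)
    panel_size_px: int = 24
    margin_px: int = 8
    plant_radius_px: int = 14
    # soil: brighter in red than green than blue, like dry bare soil
    soil_reflectance: tuple[float, float, float] = (24.0, 18.0, 12.0)
    soil_noise_sd: float = 0.5
    canopy_noise_sd: float = 0.3
    # chlorophyll population (arbitrary units)
    chl_mean: float = 50.0
    chl_sd: float = 5.0
    # canopy reflectance link: rho_c = intercept_c + slope_c * z, with z the
    # standardized chlorophyll; red darkens fastest with chlorophyll
    canopy_intercept: tuple[float, float, float] = (12.0, 22.0, 6.0)
    canopy_slope: tuple[float, float, float] = (-3.0, -2.0, -0.5)


@dataclass(frozen=True)
class PanelSpec:
    """Grey reference panels: nominal reflectances and pixel footprints.

    Footprints are half-open pixel rectangles ``(row0, col0, row1, col1)``.
    """

    nominal_reflectance: tuple[float, ...]
    footprints: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        for rho in self.nominal_reflectance:
            if not 0.0 < rho < 100.0:
                raise ValueError(f"panel reflectance {rho} outside (0, 100)")
        if len(self.nominal_reflectance) != len(self.footprints):
            raise ValueError("one footprint required per panel")


@dataclass
class ReflectanceScene:
    """Ground-truth surface reflectance with labels and plant metadata.

    ``reflectance`` is H x W x 3 in percent (0-100).  ``labels`` codes each
    pixel as soil, canopy or panel; ``plant_id`` is 0 for non-plant pixels
    and 1..P for canopy pixels of plant p.
    """

    reflectance: np.ndarray
    labels: np.ndarray
    plant_id: np.ndarray
    chlorophyll: dict[int, float]
    plant_centers: dict[int, tuple[int, int]]
    panels: PanelSpec
    gsd_m: float
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_plants(self) -> int:
        return len(self.chlorophyll)


@dataclass(frozen=True)
class IlluminationField:
    """Multiplicative illumination: per-channel gain x smooth spatial field.

    ``spatial_field`` is the scalar luminance modulation F(x, y) in (0, 1].
    ``spectral_field``, when present (the variable condition), is the full
    H x W x 3 per-channel modulation: F times a smooth shadow tint, since
    cloud shadow changes the spectrum of the incident light as well as its
    brightness.  Uniform conditions leave it None.
    """

    condition: str
    spectral_gain: tuple[float, float, float]
    spatial_field: np.ndarray
    seed: int
    spectral_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.spectral_gain):
            raise ValueError("spectral gain must be strictly positive")


@dataclass(frozen=True)
class GroundTruthSPAD:
    plant_id: int
    spad: float


@dataclass(frozen=True)
class CameraModel:
    """8-bit camera with logarithmic response.

    The inverse response is the exponential DN-to-reflectance family
    ``e(DN) = a * exp(b * DN)`` per channel, so the forward response is
    ``DN = clip(round(ln(e / a) / b), 0, 2^bits - 1)`` for effective
    radiance ``e`` in percent-reflectance units.  Defaults are per-channel
    coefficients of a calibrated consumer RGB sensor under clear sky:
    a = (1.35, 0.877, 0.817), b = (0.016, 0.017, 0.018).

    ``dn_noise_sd`` optionally adds Gaussian DN noise before quantization
    (off by default).
    """

    a: tuple[float, float, float] = (1.35, 0.877, 0.817)
    b: tuple[float, float, float] = (0.016, 0.017, 0.018)
    bit_depth: int = 8
    dn_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.a) or any(x <= 0 for x in self.b):
            raise ValueError("camera coefficients must be positive")

    @property
    def dn_max(self) -> int:
        return 2**self.bit_depth - 1

    def forward(self, e: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Quantized DN response to effective radiance ``e`` (percent)."""
        e = np.asarray(e, dtype=float)
        if np.any(e <= 0):
            raise RenderError("non-positive effective radiance")
        e = np.maximum(e, RADIANCE_GUARD)
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        dn = np.log(e / a) / b
        if self.dn_noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            dn = dn + rng.normal(0.0, self.dn_noise_sd, size=dn.shape)
        return np.clip(np.rint(dn), 0, self.dn_max).astype(np.uint8)

    def inverse(self, dn: np.ndarray) -> np.ndarray:
        """Effective radiance (percent) for a DN value: ``a * exp(b * DN)``."""
        dn = np.asarray(dn, dtype=float)
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        return a * np.exp(b * dn)


def _place_panels(layout: Layout) -> PanelSpec:
    k = len(layout.panel_reflectances)
    s, m = layout.panel_size_px, layout.margin_px
    if k * s + (k + 1) * m > layout.width or s + 2 * m > layout.height:
        raise PlacementError("image too small for the reference panels")
    step = (layout.width - 2 * m - k * s) // max(k - 1, 1) + s if k > 1 else 0
    feet = []
    for i in range(k):
        c0 = m + i * step if k > 1 else m
        feet.append((m, c0, m + s, c0 + s))
    return PanelSpec(tuple(layout.panel_reflectances), tuple(feet))


def make_scene(n_plants: int, layout: Layout | None = None, seed: int = 0) -> ReflectanceScene:
    """Generate a reflectance scene with soil, plant canopies and panels.

    Plants are placed on a jittered grid inside ``layout.n_plots``
    horizontal plot strips below the panel row.  Each plant draws a
    chlorophyll value from ``N(chl_mean, chl_sd)``; its canopy reflectance
    follows the affine chlorophyll link of the layout plus small per-pixel
    texture noise.  Panels are noise-free and spectrally flat (grey).

    Raises :class:`PlacementError` when the geometry cannot accommodate all
    plants and panels without overlap.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    layout = layout or Layout()
    rng = np.random.default_rng(seed)
    h, w = layout.height, layout.width
    panels = _place_panels(layout)

    # chlorophyll per plant (draw first so geometry jitter does not shift it)
    chl = rng.normal(layout.chl_mean, layout.chl_sd, size=n_plants)

    # plot strips below the panel row
    r_top = layout.margin_px * 2 + layout.panel_size_px
    r_bot = h - layout.margin_px
    strip_h = (r_bot - r_top) / layout.n_plots
    rad = layout.plant_radius_px
    if strip_h < 2 * rad + 2:
        raise PlacementError("plot strips too narrow for the plant radius")
    per_plot = math.ceil(n_plants / layout.n_plots)
    if per_plot * (2 * rad + 2) > w:
        raise PlacementError("plot rows too short for the requested plants")

    centers: dict[int, tuple[int, int]] = {}
    pid = 0
    for plot in range(layout.n_plots):
        row_c = r_top + (plot + 0.5) * strip_h
        n_here = min(per_plot, n_plants - pid)
        for j in range(n_here):
            col_c = (j + 0.5) * w / per_plot
            jr = rng.uniform(-3, 3)
            jc = rng.uniform(-3, 3)
            r = int(np.clip(round(row_c + jr), rad + 1, h - rad - 2))
            c = int(np.clip(round(col_c + jc), rad + 1, w - rad - 2))
            pid += 1
            centers[pid] = (r, c)
        if pid >= n_plants:
            break

    # soil background with mild texture
    soil = np.asarray(layout.soil_reflectance, dtype=float)
    reflectance = soil + rng.normal(0.0, layout.soil_noise_sd, size=(h, w, 3))
    labels = np.full((h, w), SOIL, dtype=np.int32)
    plant_map = np.zeros((h, w), dtype=np.int32)

    rr, cc = np.ogrid[:h, :w]
    icept = np.asarray(layout.canopy_intercept)
    slope = np.asarray(layout.canopy_slope)
    for p, (r, c) in centers.items():
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        z = (chl[p - 1] - layout.chl_mean) / layout.chl_sd
        rho = icept + slope * z
        n_px = int(disk.sum())
        tex = rng.normal(0.0, layout.canopy_noise_sd, size=(n_px, 3))
        reflectance[disk] = rho + tex
        labels[disk] = CANOPY
        plant_map[disk] = p

    # panels last: constant, grey, overwrite anything underneath
    for k, ((r0, c0, r1, c1), rho) in enumerate(
        zip(panels.footprints, panels.nominal_reflectance)
    ):
        reflectance[r0:r1, c0:c1, :] = rho
        labels[r0:r1, c0:c1] = PANEL_LABEL_BASE + k
        plant_map[r0:r1, c0:c1] = 0

    np.clip(reflectance, 0.5, 100.0, out=reflectance)
    return ReflectanceScene(
        reflectance=reflectance,
        labels=labels,
        plant_id=plant_map,
        chlorophyll={p: float(chl[p - 1]) for p in centers},
        plant_centers=centers,
        panels=panels,
        gsd_m=layout.gsd_m,
        seed=seed,
    )


def make_illumination(
    condition: str,
    shape: tuple[int, int],
    seed: int = 0,
    min_field: float = 0.3,
    correlation_frac: float = 0.25,
    shadow_tint: tuple[float, float, float] | None = SHADOW_TINT,
) -> IlluminationField:
    """Build the illumination field for one acquisition condition.

    ``sunny`` and ``overcast`` are spatially uniform (F = 1) and differ only
    in spectral gain; ``variable`` uses the sunny gain modulated by a smooth
    random field F in [``min_field``, 1] obtained by Gaussian low-pass
    filtering white noise at sigma = ``correlation_frac * min(H, W)``.
    Cloud shadow is also spectrally selective — a shadowed pixel is lit by
    blue-rich diffuse skylight — so the variable condition additionally
    tints each pixel toward ``shadow_tint`` in proportion to its shadow
    depth (1 - F); pass ``shadow_tint=None`` for a purely neutral field.
    """
    h, w = shape
    if condition == "sunny":
        return IlluminationField(condition, SUNNY_GAIN, np.ones((h, w)), seed)
    if condition == "overcast":
        return IlluminationField(condition, OVERCAST_GAIN, np.ones((h, w)), seed)
    if condition == "variable":
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((h, w))
        f = ndi.gaussian_filter(noise, sigma=correlation_frac * min(h, w), mode="reflect")
        lo, hi = f.min(), f.max()
        if hi - lo < 1e-12:  # degenerate: filter averaged everything out
            field = np.ones((h, w))
        else:
            field = min_field + (1.0 - min_field) * (f - lo) / (hi - lo)
        spectral = None
        if shadow_tint is not None:
            tint = np.asarray(shadow_tint, dtype=float)
            depth = (1.0 - field) / (1.0 - min_field)  # 0 in sun, 1 at deepest shadow
            spectral = field[..., None] * (1.0 + (tint - 1.0) * depth[..., None])
        return IlluminationField(condition, SUNNY_GAIN, field, seed, spectral)
    raise ValueError(f"unknown illumination condition: {condition!r}")


def render(
    scene: ReflectanceScene,
    illum: IlluminationField,
    cam: CameraModel | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render an 8-bit RGB image: ``DN = camera(R x l x F)``.

    Deterministic given (scene, illumination, camera) unless the camera has
    DN noise enabled, in which case ``rng`` drives it.
    """
    cam = cam or CameraModel()
    if illum.spatial_field.shape != scene.shape:
        raise ValueError("scene and illumination shapes disagree")
    gain = np.asarray(illum.spectral_gain, dtype=float)
    modulation = (
        illum.spectral_field
        if illum.spectral_field is not None
        else illum.spatial_field[..., None]
    )
    e = scene.reflectance * gain * modulation
    return cam.forward(e, rng=rng)


def make_spad(
    scene: ReflectanceScene,
    noise_sd: float = DEFAULT_SPAD_NOISE_SD,
    seed: int = 0,
) -> list[GroundTruthSPAD]:
    """Draw SPAD readings: affine in chlorophyll plus Gaussian meter noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    pids = sorted(scene.chlorophyll)
    eps = rng.normal(0.0, noise_sd, size=len(pids)) if noise_sd > 0 else np.zeros(len(pids))
    return [
        GroundTruthSPAD(p, float(SPAD_C0 + SPAD_C1 * scene.chlorophyll[p] + e))
        for p, e in zip(pids, eps)
    ]


def gsd(
    altitude_m: float,
    sensor_width_mm: float,
    focal_mm: float,
    image_width_px: int,
) -> float:
    """Ground sampling distance in cm per pixel for a nadir camera.

    GSD = altitude x sensor_width / (focal_length x image_width), converted
    to centimetres.  E.g. a 1-inch sensor (13.2 mm, 5472 px, 8.8 mm focal)
    gives ~2.74 cm at 100 m and ~0.69 cm at 25 m altitude.
    """
    if min(altitude_m, sensor_width_mm, focal_mm, image_width_px) <= 0:
        raise ValueError("all GSD arguments must be positive")
    metres_per_px = altitude_m * sensor_width_mm / (focal_mm * image_width_px)
    return 100.0 * metres_per_px


def scene_metadata(scene: ReflectanceScene, cam: CameraModel | None = None) -> dict:
    """JSON-serializable description of a scene for run manifests."""
    cam = cam or CameraModel()
    return {
        "gsd_m": scene.gsd_m,
        "seed": scene.seed,
        "n_plants": scene.n_plants,
        "panel_reflectances": list(scene.panels.nominal_reflectance),
        "camera": dataclasses.asdict(cam),
    }
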