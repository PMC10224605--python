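"""File I/O helpers: TIFF/PNG images and the plants/panels CSV formats."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .scene import GroundTruthSPAD, PanelSpec, ReflectanceScene

__all__ = [
    "write_image",
    "write_float_image",
    "write_mask",
    "read_image",
    "write_plants_csv",
    "read_plants_csv",
    "write_panels_csv",
    "read_panels_csv",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit RGB image as TIFF or PNG (by extension)."""
    path = Path(path)
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img, photometric="rgb")
    else:
        iio.imwrite(path, img)


def write_float_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image (corrected values/reflectance) as 32-bit TIFF."""
    data = np.asarray(image, dtype=np.float32)
    photometric = "rgb" if data.ndim == 3 and data.shape[-1] == 3 else "minisblack"
    tifffile.imwrite(Path(path), data, photometric=photometric)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit TIFF."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_plants_csv(
    path: str | Path,
    scene: ReflectanceScene,
    spad: list[GroundTruthSPAD] | None = None,
) -> None:
    """plant_id, row, col, chlorophyll and (when given) spad."""
    pids = sorted(scene.plant_centers)
    df = pd.DataFrame(
        {
            "plant_id": pids,
            "row": [scene.plant_centers[p][0] for p in pids],
            "col": [scene.plant_centers[p][1] for p in pids],
            "chlorophyll": [scene.chlorophyll[p] for p in pids],
        }
    )
    if spad is not None:
        lookup = {s.plant_id: s.spad for s in spad}
        df["spad"] = [lookup[p] for p in pids]
    df.to_csv(path, index=False)


def read_plants_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_panels_csv(path: str | Path, panels: PanelSpec) -> None:
    """panel_id, nominal_reflectance_pct and footprint corners."""
    rows = [
        {
            "panel_id": i + 1,
            "nominal_reflectance_pct": rho,
            "row0": r0,
            "col0": c0,
            "row1": r1,
            "col1": c1,
        }
        for i, (rho, (r0, c0, r1, c1)) in enumerate(
            zip(panels.nominal_reflectance, panels.footprints)
        )
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panels_csv(path: str | Path) -> PanelSpec:
    df = pd.read_csv(path)
    return PanelSpec(
        tuple(df["nominal_reflectance_pct"].astype(float)),
        tuple(
            (int(r.row0), int(r.col0), int(r.row1), int(r.col1))
            for r in df.itertuples(index=False)
        ),
    )
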