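"""End-to-end orchestration: simulate, correct, segment, extract, evaluate.

One experiment renders a single synthetic field under up to three
illumination conditions and computes per-plant vegetation indices under up
to four value conventions:

* ``scaling`` — raw DN / 255;
* ``normalized`` — raw DN chromaticity (channel / channel sum);
* ``elm`` — empirical-line reflectance from in-scene panels, then
  chromaticity-normalized (uniform-sky conditions only);
* ``retinex`` — automated multi-scale Retinex correction, then
  chromaticity-normalized.

The per-plant tables feed the evaluation instruments (std, Pearson, top-5
R²).  All randomness descends from one experiment seed through independent
child seeds for the scene, the SPAD draw, each illumination field and the
classifier training sample.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .evaluation import EvaluationReport, compare_methods
from .indices import VI_CODES, VIParams, compute_all
from .radiometric import apply_elm, extract_panel_dns, fit_elm, normalize_rgb
from .retinex import RetinexConfig, auto_scales, correct_image
from .scene import (
    CONDITIONS,
    CameraModel,
    GroundTruthSPAD,
    Layout,
    ReflectanceScene,
    make_illumination,
    make_scene,
    make_spad,
    render,
    scene_metadata,
)
from .segmentation import classify, make_buffers, sample_training_pixels, train_mlc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "run", "METHODS"]

METHODS = ("scaling", "normalized", "elm", "retinex")
UNIFORM_CONDITIONS = ("sunny", "overcast")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int
    conditions: tuple[str, ...] = CONDITIONS
    methods: tuple[str, ...] = METHODS
    n_plants: int = 12
    layout: Layout = field(default_factory=Layout)
    camera: CameraModel = field(default_factory=CameraModel)
    retinex: RetinexConfig | None = None  # None -> automatic scales
    allow_elm_variable: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if self.allow_elm_variable and "elm" in self.methods:
            logger.warning(
                "ELM requested under variable illumination: the empirical line "
                "assumes uniform irradiance and will be wrong by the spatial field"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "layout" in raw:
            raw["layout"] = Layout(**raw["layout"])
        if "camera" in raw:
            raw["camera"] = CameraModel(**raw["camera"])
        if raw.get("retinex"):
            raw["retinex"] = RetinexConfig(**raw["retinex"])
        for key in ("conditions", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ExperimentResult:
    """Everything one seeded experiment produced, in memory."""

    scene: ReflectanceScene
    spad: list[GroundTruthSPAD]
    vi_table: pd.DataFrame
    report: EvaluationReport
    images: dict[str, np.ndarray]
    corrected: dict[tuple[str, str], np.ndarray]
    masks: dict[str, np.ndarray]
    warnings: list[str]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def method_values(
    image: np.ndarray,
    method: str,
    scene: ReflectanceScene,
    retinex_config: RetinexConfig | None = None,
) -> np.ndarray:
    """Per-pixel (r, g, b) value map for one convention, float (H, W, 3)."""
    if method == "scaling":
        return image.astype(float) / 255.0
    if method == "normalized":
        return normalize_rgb(image.astype(float))
    if method == "elm":
        readout = extract_panel_dns(image, scene.panels)
        models = fit_elm(readout, scene.panels.nominal_reflectance)
        return normalize_rgb(apply_elm(image, models))
    if method == "retinex":
        return normalize_rgb(correct_image(image, retinex_config))
    raise ValueError(f"unknown method: {method!r}")


def extract_vi_table(
    scene: ReflectanceScene,
    images: dict[str, np.ndarray],
    masks: dict[str, np.ndarray],
    methods: tuple[str, ...] = METHODS,
    retinex_config: RetinexConfig | None = None,
    vi_params: VIParams | None = None,
    side_m: float = 0.2,
    allow_elm_variable: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Per-plant zonal VI means for every (condition, method) combination.

    Indices are computed per pixel inside each plant buffer intersected
    with the vegetation mask, then averaged.  ELM cells under variable
    illumination are skipped (structurally absent) unless explicitly
    allowed.  Returns the long-format table and the corrected value maps.
    """
    vi_params = vi_params or VIParams()
    plants = pd.DataFrame(
        {
            "plant_id": sorted(scene.plant_centers),
            "row": [scene.plant_centers[p][0] for p in sorted(scene.plant_centers)],
            "col": [scene.plant_centers[p][1] for p in sorted(scene.plant_centers)],
        }
    )
    buffers = make_buffers(plants, scene.gsd_m, side_m=side_m, image_shape=scene.shape)
    rows = []
    corrected: dict[tuple[str, str], np.ndarray] = {}
    for condition, image in images.items():
        mask = masks[condition]
        for method in methods:
            if method == "elm" and condition not in UNIFORM_CONDITIONS and not allow_elm_variable:
                continue
            values = method_values(image, method, scene, retinex_config)
            corrected[(method, condition)] = values
            for buf in buffers:
                sub = values[buf.row0 : buf.row1, buf.col0 : buf.col1]
                msk = mask[buf.row0 : buf.row1, buf.col0 : buf.col1]
                px = sub[msk]
                rec = {"plant_id": buf.plant_id, "condition": condition, "method": method}
                if px.shape[0] == 0:
                    logger.warning(
                        "plant %d has no vegetation pixels under %s", buf.plant_id, condition
                    )
                    rec.update({c: np.nan for c in VI_CODES})
                else:
                    vi_px = compute_all(px, vi_params)  # (n, 16)
                    valid = np.isfinite(vi_px)
                    counts = valid.sum(axis=0)
                    frac = counts / vi_px.shape[0]
                    sums = np.where(valid, vi_px, 0.0).sum(axis=0)
                    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
                    means = np.where(frac < 0.5, np.nan, means)
                    rec.update(dict(zip(VI_CODES, means)))
                rows.append(rec)
    return pd.DataFrame(rows), corrected


def run_experiment(
    seed: int,
    n_plants: int = 12,
    layout: Layout | None = None,
    camera: CameraModel | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
    methods: tuple[str, ...] = METHODS,
    retinex_config: RetinexConfig | None = None,
    spad_noise_sd: float | None = None,
    keep_images: bool = True,
) -> ExperimentResult:
    """Run one seeded simulate-correct-extract-evaluate experiment."""
    layout = layout or Layout()
    camera = camera or CameraModel()
    seeds = _child_seeds(seed, 3 + 2 * len(CONDITIONS))
    scene = make_scene(n_plants, layout, seed=seeds[0])
    spad_kwargs = {} if spad_noise_sd is None else {"noise_sd": spad_noise_sd}
    spad = make_spad(scene, seed=seeds[1], **spad_kwargs)

    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for i, condition in enumerate(conditions):
        illum = make_illumination(condition, scene.shape, seed=seeds[3 + i])
        image = render(scene, illum, camera)
        feats, labels = sample_training_pixels(
            image.astype(float) / 255.0,
            scene.labels,
            vegetation_label=1,
            seed=seeds[3 + len(CONDITIONS) + i],
        )
        model = train_mlc(feats, labels)
        masks[condition] = classify(image.astype(float) / 255.0, model)
        images[condition] = image

    table, corrected = extract_vi_table(
        scene, images, masks, methods=methods, retinex_config=retinex_config
    )
    report = compare_methods(table, spad)
    if not keep_images:
        images, corrected, masks = {}, {}, {}
    return ExperimentResult(
        scene=scene,
        spad=spad,
        vi_table=table,
        report=report,
        images=images,
        corrected=corrected,
        masks=masks,
        warnings=[],
    )


def run(config: RunConfig) -> ExperimentResult:
    """Full pipeline run with artifacts written to ``config.out_dir``.

    Writes, per condition: the rendered 8-bit frame (TIFF and PNG), the
    vegetation mask, and per (method, condition) the corrected value map as
    32-bit float TIFF; plus plants/panels CSVs, the zonal VI table, the
    three evaluation reports and a manifest recording every parameter.
    """
    t0 = time.time()
    result = run_experiment(
        seed=config.seed,
        n_plants=config.n_plants,
        layout=config.layout,
        camera=config.camera,
        conditions=config.conditions,
        methods=config.methods,
        retinex_config=config.retinex,
    )
    if config.out_dir is None:
        return result
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = result.scene

    lio.write_plants_csv(out / "plants.csv", scene, result.spad)
    lio.write_panels_csv(out / "panels.csv", scene.panels)
    for condition, image in result.images.items():
        lio.write_image(out / f"frame_{condition}.tif", image)
        lio.write_image(out / f"frame_{condition}.png", image)
        lio.write_mask(out / f"mask_{condition}.tif", result.masks[condition])
    for (method, condition), values in result.corrected.items():
        lio.write_float_image(out / f"values_{method}_{condition}.tif", values)
    result.vi_table.to_csv(out / "zonal_vis.csv", index=False)
    result.report.std_report.to_csv(out / "report_std.csv", index=False)
    result.report.corr_report.to_csv(out / "report_corr.csv", index=False)
    result.report.r2_grid.to_csv(out / "report_r2.csv")
    retinex_used = config.retinex or auto_scales(scene.shape)
    manifest = {
        "seed": config.seed,
        "conditions": list(config.conditions),
        "methods": list(config.methods),
        "n_plants": config.n_plants,
        "layout": dataclasses.asdict(config.layout),
        "scene": scene_metadata(scene, config.camera),
        "retinex": {
            "scales": list(retinex_used.scales),
            "weights": list(retinex_used.weights),
            "epsilon": retinex_used.epsilon,
            "stretch_k": retinex_used.stretch_k,
            "auto": retinex_used.auto,
        },
        "report": result.report.to_dict(),
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result
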