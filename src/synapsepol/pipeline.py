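"""End-to-end orchestration: scenes (simulated or on disk) -> CSV reports.

Every run writes, under ``config.out_dir``:

* ``scenes.csv`` — one row per scene with the measurements for the run kind;
* ``cohort.csv`` — one summary row (percentages, means);
* ``manifest.json`` — package/library versions, seed, every effective
  parameter and a config hash;
* ``run.log`` — per-scene warnings and errors.

Per-scene failures are recorded (``error`` column) and the run continues, so
one bad field does not kill a batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actin_kinetics import actin_ratio_series, extract_floating_rois
from .coloc_tracking import link_tracks, mean_speed
from .config import RunConfig
from .errors import SynapsePolError
from .interface_geometry import delimit_is_area, factin_low_area, project_interface
from .polarization import polarization_index
from .scene import ImageScene
from .scene_synth import SceneSpec, generate_conjugate_scene, generate_timelapse, generate_vesicle_frames, with_seed
from .segmentation import SegmentationConfig, _detect_puncta, detect_mtoc, detect_organelles, segment_conjugate

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("synapsepol")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        rows = _collect_rows(config)
        scenes = pd.DataFrame(rows)
        scenes.to_csv(out / "scenes.csv", index=False, float_format="%.6g")
        cohort = _summarize(scenes, config)
        cohort.to_csv(out / "cohort.csv", index=False, float_format="%.6g")
        manifest = {
            "package": "synapsepol",
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "effective_config": config.effective_values(),
            "n_scenes": len(scenes),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _collect_rows(config: RunConfig) -> list[dict]:
    if config.simulate is not None:
        return _simulate_rows(config)
    if not config.inputs:
        raise SynapsePolError("config has neither inputs nor a simulate block")
    rows = []
    for i, path in enumerate(config.inputs):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not readable: {path}")
        scene = ImageScene.read_tiff(
            path,
            channel_roles=config.channel_roles,
            pixel_size=config.pixel_size,
            z_step=config.z_step,
            frame_interval=config.frame_interval,
        )
        rows.append(_measure_static(scene, f"scene_{i:03d}", config))
    return rows


def sample_true_pol_indexes(n: int, polarized_fraction: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """Mixture of clearly-polarized and clearly-unpolarized true indexes.

    Exactly ``round(n * polarized_fraction)`` scenes draw from
    U(cutoff + 0.1, 0.9); the rest from U(-0.5, cutoff - 0.1).
    """
    n_pol = int(round(n * polarized_fraction))
    hi = rng.uniform(cutoff + 0.1, 0.9, size=n_pol)
    lo = rng.uniform(-0.5, cutoff - 0.1, size=n - n_pol)
    vals = np.concatenate([hi, lo])
    rng.shuffle(vals)
    return vals


def _simulate_rows(config: RunConfig) -> list[dict]:
    sim = config.simulate
    rng = np.random.default_rng(config.seed)
    rows = []
    if sim.kind == "static":
        indexes = sample_true_pol_indexes(sim.n_scenes, sim.polarized_fraction, config.pol_cutoff, rng)
    elif sim.kind == "zstack":
        n_dep = int(round(sim.n_scenes * sim.depleted_fraction))
        ratios = np.concatenate([
            rng.uniform(0.2, 0.35, size=n_dep), np.zeros(sim.n_scenes - n_dep)
        ])
        rng.shuffle(ratios)
    for i in range(sim.n_scenes):
        sid = f"scene_{i:03d}"
        spec = with_seed(sim.scene, config.seed * 100_003 + i)
        try:
            if sim.kind == "static":
                spec = dataclasses.replace(spec, true_pol_index=float(indexes[i]))
                scene, truth = generate_conjugate_scene(spec)
                row = _measure_static(scene, sid, config)
                row["true_pol_index"] = truth.true_pol_index
            elif sim.kind == "zstack":
                spec = dataclasses.replace(
                    spec, n_z=max(spec.n_z, 3), true_depletion_ratio=float(ratios[i])
                )
                scene, truth = generate_conjugate_scene(spec)
                row = _measure_interface(scene, sid, config)
                row["true_depletion_ratio"] = truth.true_depletion_ratio
            elif sim.kind == "timelapse":
                scene, truth = generate_timelapse(spec)
                row = _measure_kinetics(scene, sid, config)
                row["true_burst_duration"] = truth.extras["burst_duration"]
                row["true_burst_amplitude"] = truth.extras["burst_amplitude"]
            else:  # vesicles
                scene, truth = generate_vesicle_frames(spec)
                row = _measure_tracks(scene, sid, config)
                row["true_speed_um_s"] = truth.track_speed_um_s
        except SynapsePolError as exc:
            logger.warning("%s: %s (%s)", sid, exc, exc.code)
            row = {"scene_id": sid, "error": exc.code}
        rows.append(row)
    return rows


def _seg_config(config: RunConfig) -> SegmentationConfig:
    return SegmentationConfig(spot_min_area_px=config.spot_min_area_px)


def _measure_static(scene: ImageScene, sid: str, config: RunConfig) -> dict:
    seg_cfg = _seg_config(config)
    geom = segment_conjugate(scene, config=seg_cfg)
    row: dict = {"scene_id": sid, "error": ""}
    try:
        org = detect_organelles(scene, geom, config=seg_cfg)
        res = polarization_index(geom, org.weighted_centroid_px, "MVB", config.pol_cutoff)
        row.update(
            mvb_A=res.A, mvb_B=res.B, mvb_pol_index=res.pol_index, mvb_polarized=res.polarized
        )
    except SynapsePolError as exc:
        logger.warning("%s: MVB measurement failed: %s", sid, exc)
        row["error"] = exc.code
    if scene.has_role("mtoc"):
        try:
            mtoc = detect_mtoc(scene, geom, config=seg_cfg)
            res = polarization_index(geom, mtoc.weighted_centroid_px, "MTOC", config.pol_cutoff)
            row.update(mtoc_pol_index=res.pol_index, mtoc_polarized=res.polarized)
        except SynapsePolError as exc:
            logger.warning("%s: MTOC measurement failed: %s", sid, exc)
    return row


def _measure_interface(scene: ImageScene, sid: str, config: RunConfig) -> dict:
    seg_cfg = _seg_config(config)
    seg_cfg.t_cell_role = "organelle"  # cytosolic cell marker; actin is facet-patterned
    geom = segment_conjugate(scene, config=seg_cfg, volumetric=True)
    faceon = project_interface(scene, geom, slab_depth_um=config.slab_depth_um)
    region, _ = delimit_is_area(faceon, scene.pixel_size)
    proj = factin_low_area(
        faceon, region, scene.pixel_size, cutoff=config.area_cutoff,
        low_fraction=config.low_fraction,
    )
    return {
        "scene_id": sid, "error": "",
        "is_area_um2": proj.is_area,
        "factin_low_area_um2": proj.factin_low_area,
        "area_ratio": proj.area_ratio,
        "depleted": proj.depleted,
    }


def _measure_kinetics(scene: ImageScene, sid: str, config: RunConfig) -> dict:
    seg_cfg = _seg_config(config)
    seg_cfg.t_cell_role = "organelle"  # cytosolic marker; actin is burst-modulated
    series = extract_floating_rois(
        scene, band_depth_um=config.band_depth_um, central_fraction=config.central_fraction,
        config=seg_cfg,
    )
    kin = actin_ratio_series(series, delta=config.ratio_delta)
    return {
        "scene_id": sid, "error": "",
        "reorganization_duration_min": kin.reorganization_duration,
        "peak_time_min": kin.peak_time,
        "max_ratio_is_cell": kin.max_ratio_is_cell,
        "depletion_present": kin.depletion_present,
        "depletion_duration_min": kin.depletion_duration,
    }


def _measure_tracks(scene: ImageScene, sid: str, config: RunConfig) -> dict:
    seg_cfg = _seg_config(config)
    all_mask = np.ones(scene.shape_yx, dtype=bool)
    detections = []
    ch = scene.channel_roles["organelle"]
    for t in range(scene.n_frames):
        labels, table = _detect_puncta(scene.data[t, 0, ch], all_mask, seg_cfg)
        pts = table[["c0", "c1"]].to_numpy() if len(table) else np.empty((0, 2))
        detections.append(pts)
    tracks = link_tracks(
        detections, config.max_link_um, scene.pixel_size, config.min_track_len
    )
    interval_s = scene.frame_interval * 60.0
    speeds = [mean_speed(t, scene.pixel_size, interval_s) for t in tracks]
    return {
        "scene_id": sid, "error": "",
        "n_tracks": len(tracks),
        "mean_speed_um_s": float(np.mean(speeds)) if speeds else float("nan"),
    }


def _summarize(scenes: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    row: dict = {"n_scenes": len(scenes), "seed": config.seed}
    if "error" in scenes:
        row["n_failed"] = int((scenes["error"].fillna("") != "").sum())
    for col, name in (("mvb_polarized", "percent_polarized_mvb"),
                      ("mtoc_polarized", "percent_polarized_mtoc"),
                      ("depleted", "percent_depleted")):
        if col in scenes:
            valid = scenes[col].dropna()
            if len(valid):
                row[name] = 100.0 * valid.astype(bool).mean()
    for col in ("mvb_pol_index", "area_ratio", "reorganization_duration_min",
                "max_ratio_is_cell", "mean_speed_um_s"):
        if col in scenes:
            valid = pd.to_numeric(scenes[col], errors="coerce").dropna()
            if len(valid):
                row[f"mean_{col}"] = valid.mean()
    return pd.DataFrame([row])
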