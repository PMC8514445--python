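"""End-to-end pipelines wired from the library modules.

Each pipeline is a pure function of its configuration (seeds included):
rerunning with an identical config reproduces byte-identical CSV/JSON
artifacts.  Providers replace the trained networks of a full acquisition
setup: landmarks come from a CSV file or the mock detector, the brain
boundary from Otsu thresholding, a user-supplied mask file, or the
phantom ground truth.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Callable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import atlas as atlas_mod
from . import boundary, clustering, motifs, registration, roi, synthetic
from .evaluation import landmark_errors

log = logging.getLogger("mesomap")

__all__ = ["run_pipeline", "PIPELINES"]


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def _load_mask(cfg: dict, scene_dir: Path, image: np.ndarray) -> np.ndarray:
    provider = cfg.get("boundary", "otsu")
    if provider == "otsu":
        _, mask = boundary.otsu_segment(image)
        return mask
    if provider == "oracle":
        return (np.asarray(iio.imread(scene_dir / "mask.png")) > 0).astype(np.uint8)
    if provider == "file":
        p = Path(cfg["mask_path"])
        if not p.exists():
            raise FileNotFoundError(f"mask file not found: {p}")
        return (np.asarray(iio.imread(p)) > 0).astype(np.uint8)
    raise ValueError(f"unknown boundary provider {provider!r}")


def _load_obs(cfg: dict, scene_dir: Path) -> list:
    provider = cfg.get("landmarks", "file")
    if provider == "file":
        p = Path(cfg.get("landmarks_path", scene_dir / "landmarks.csv"))
        if not p.exists():
            raise FileNotFoundError(f"landmarks file not found: {p}")
        return synthetic.load_landmark_observations(p)
    raise ValueError(f"unknown landmarks provider {provider!r}")


def _pipeline_simulate(cfg: dict, out: Path) -> None:
    spec = synthetic.PhantomSpec(
        image_size=tuple(cfg.get("image_size", (256, 256))),
        vessel_count=int(cfg.get("vessel_count", 4)),
        noise_sigma=float(cfg.get("noise_sigma", 3.0)),
        seed=int(cfg.get("seed", 0)),
    )
    scene = synthetic.make_phantom(spec)
    if cfg.get("misalign", False):
        scene = synthetic.perturb_alignment(
            scene, synthetic.MisalignmentSpec(seed=int(cfg.get("seed", 0)))
        )
    synthetic.save_scene(scene, out)
    log.info("simulate: wrote phantom scene to %s", out)


def _scene_context(cfg: dict):
    scene_dir = Path(cfg["scene_dir"])
    image = tifffile.imread(scene_dir / "image.tiff").astype(float)
    n = min(image.shape)
    atlas, ccs, defs = atlas_mod.make_test_atlas(size=n)
    return scene_dir, image, atlas, ccs, defs


def _pipeline_atlas_to_brain(cfg: dict, out: Path) -> None:
    scene_dir, image, atlas, ccs, defs = _scene_context(cfg)
    mask = _load_mask(cfg, scene_dir, image)
    obs = _load_obs(cfg, scene_dir)
    res = registration.atlas_to_brain(
        atlas, obs, defs, ccs, mask,
        mode=cfg.get("mode", "default"),
        min_confidence=float(cfg.get("min_confidence", 0.5)),
    )
    iio.imwrite(out / "warped_labels.png", res.labels.astype(np.uint16))
    iio.imwrite(out / "warped_boundary.png", (res.boundary > 0).astype(np.uint8) * 255)
    _json_dump(
        {
            "left": res.left_map.matrix.ravel().tolist(),
            "right": res.right_map.matrix.ravel().tolist(),
        },
        out / "transforms.json",
    )
    rois = roi.label_by_id(
        roi.dilate_once(res.labels) if cfg.get("dilate", True) else res.labels,
        mask, atlas,
    )
    if cfg.get("numbering", "id") == "spatial":
        bregma = next(o for o in obs if o.name == "bregma")
        rois = roi.order_spatial(rois, bregma.px[1])
    roi.export_rois(rois, out / "rois.json", format="json")
    roi.export_rois(rois, out / "rois.mat", format="matfile")
    log.info("atlas-to-brain: %d ROIs -> %s", len(rois), out)


def _pipeline_brain_to_atlas(cfg: dict, out: Path) -> None:
    scene_dir, image, atlas, ccs, defs = _scene_context(cfg)
    mask = _load_mask(cfg, scene_dir, image)
    obs = _load_obs(cfg, scene_dir)
    res = registration.brain_to_atlas(
        image, obs, defs, ccs, mask, atlas.label_image.shape,
        mode=cfg.get("mode", "default"),
        min_confidence=float(cfg.get("min_confidence", 0.5)),
    )
    tifffile.imwrite(out / "registered.tiff", res.image.astype(np.float32))
    iio.imwrite(out / "registered_mask.png", res.mask.astype(np.uint8) * 255)
    _json_dump(
        {
            "left": res.left_map.matrix.ravel().tolist(),
            "right": res.right_map.matrix.ravel().tolist(),
        },
        out / "transforms.json",
    )
    # landmark agreement with the canonical atlas positions
    reg_pts = res.transform_points(np.array([o.px for o in obs]))
    canon = atlas_mod.atlas_landmark_pixels(atlas, defs, ccs)
    report = landmark_errors(
        {o.index: p for o, p in zip(obs, reg_pts)},
        {i + 1: canon[i] for i in range(9)},
        ccs.mm_per_px,
    )
    pd.DataFrame(
        {
            "index": sorted(report.distances_mm),
            "distance_mm": [report.distances_mm[i] for i in sorted(report.distances_mm)],
        }
    ).to_csv(out / "landmark_errors.csv", index=False)
    log.info("brain-to-atlas: mean landmark error %.4f mm", report.mean_mm)


def _pipeline_sensory(cfg: dict, out: Path) -> None:
    movie = tifffile.imread(cfg["movie_path"]).astype(float)
    events = pd.read_csv(cfg["events_path"])["frame"].astype(int).tolist()
    pre = int(cfg.get("pre", 10))
    post = int(cfg.get("post", 30))
    dff = motifs.compute_dff(movie + float(cfg.get("offset", 0.0)))
    avg, _ = motifs.stimulus_average(dff, events, pre, post)
    smap = motifs.peak_map(avg, pre, modality=str(cfg.get("modality", "")))
    tifffile.imwrite(out / "peak_map.tiff", smap.peak_map.astype(np.float32))
    _json_dump(
        {
            "peak_px": list(smap.peak_px),
            "centroid_px": [round(float(v), 6) for v in smap.centroid_px],
            "modality": smap.modality,
        },
        out / "sensory_map.json",
    )
    log.info("sensory: peak at %s", smap.peak_px)


def _pipeline_mbfm_build(cfg: dict, out: Path) -> None:
    movie = tifffile.imread(cfg["movie_path"]).astype(float)
    mask = (np.asarray(iio.imread(cfg["mask_path"])) > 0) if "mask_path" in cfg else (
        movie.std(axis=0) > 0
    )
    k = int(cfg.get("k", 3))
    mset = motifs.factorize_movie(
        movie, mask, k=k, l=int(cfg.get("l", 10)),
        lam=float(cfg.get("lambda", 0.0)),
        n_iter=int(cfg.get("iters", 60)), seed=int(cfg.get("seed", 0)),
    )
    images = [motifs.motif_image(m, mask) for m in mset.motifs]
    result, _ = clustering.cluster_motifs(
        images, k=int(cfg.get("knn", min(15, len(images) - 1))),
        seed=int(cfg.get("seed", 0)), mask=mask,
    )
    templates, template_mbfm = motifs.make_templates(
        images, result.labels, n_templates=int(cfg.get("n_templates", 6)), mask=mask
    )
    tifffile.imwrite(
        out / "motifs.tiff", mset.motifs.reshape(-1, *mask.shape).astype(np.float32)
    )
    tifffile.imwrite(out / "template_mbfm.tiff", template_mbfm.astype(np.float32))
    for i, t in enumerate(templates):
        tifffile.imwrite(out / f"template_{i}.tiff", t.astype(np.float32))
    pd.DataFrame(
        {"motif_id": np.arange(len(images)), "cluster": result.labels}
    ).to_csv(out / "clusters.csv", index=False)
    log.info("mbfm-build: %d motifs, %d clusters", len(images), result.n_clusters)


def _pipeline_mbfm_match(cfg: dict, out: Path) -> None:
    new = tifffile.imread(cfg["motifs_path"]).astype(float)
    template_paths = sorted(Path(cfg["templates_dir"]).glob("template_*.tiff"))
    templates = [tifffile.imread(p).astype(float) for p in template_paths]
    res = motifs.match_motifs(
        list(new), templates, r_threshold=float(cfg.get("r_threshold", 0.5))
    )
    rows = [
        {
            "motif_id": i,
            "template_id": int(res.assignment[i]),
            "r": round(float(res.r_matrix[i].max()), 6)
            if not np.all(np.isnan(res.r_matrix[i]))
            else float("nan"),
        }
        for i in range(len(new))
    ]
    pd.DataFrame(rows).to_csv(out / "assignments.csv", index=False)
    tifffile.imwrite(out / "mbfm.tiff", res.mbfm.astype(np.float32))
    log.info("mbfm-match: %d/%d motifs matched", int((res.assignment >= 0).sum()), len(new))


def _pipeline_evaluate(cfg: dict, out: Path) -> None:
    a = synthetic.load_landmark_observations(cfg["landmarks_a"])
    b = synthetic.load_landmark_observations(cfg["landmarks_b"])
    report = landmark_errors(
        {o.index: o.px for o in a},
        {o.index: o.px for o in b},
        float(cfg.get("mm_per_px", 1.0)),
    )
    _json_dump(
        {
            "distances_mm": {str(k): round(v, 9) for k, v in report.distances_mm.items()},
            "mean_mm": round(report.mean_mm, 9),
            "sem_mm": round(report.sem_mm, 9),
            "rmse_mm": round(report.rmse_mm, 9),
            "n": report.n,
        },
        out / "landmark_report.json",
    )
    log.info("evaluate: mean landmark distance %.4f mm", report.mean_mm)


PIPELINES: dict[str, Callable[[dict, Path], None]] = {
    "simulate": _pipeline_simulate,
    "atlas-to-brain": _pipeline_atlas_to_brain,
    "brain-to-atlas": _pipeline_brain_to_atlas,
    "sensory": _pipeline_sensory,
    "mbfm-build": _pipeline_mbfm_build,
    "mbfm-match": _pipeline_mbfm_match,
    "evaluate": _pipeline_evaluate,
}

_KNOWN_KEYS = {
    "pipeline", "out_dir", "scene_dir", "seed", "image_size", "vessel_count",
    "noise_sigma", "misalign", "landmarks", "landmarks_path", "boundary",
    "mask_path", "mode", "min_confidence", "dilate", "numbering", "movie_path",
    "events_path", "pre", "post", "offset", "modality", "k", "l", "lambda",
    "iters", "knn", "n_templates", "motifs_path", "templates_dir",
    "r_threshold", "landmarks_a", "landmarks_b", "mm_per_px",
}


def run_pipeline(config: dict) -> Path:
    """Run one named pipeline from a flat config dict; returns the output dir."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    name = config.get("pipeline")
    if name not in PIPELINES:
        raise ValueError(f"unknown pipeline {name!r}; choose from {sorted(PIPELINES)}")
    out = Path(config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    log.info("running pipeline %s -> %s", name, out)
    try:
        PIPELINES[name](config, out)
    except Exception:
        log.exception("pipeline stage %s failed", name)
        raise
    return out
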