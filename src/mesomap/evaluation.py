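"""Accuracy statistics: landmark distances and alignment error reports.

Distances are reported in mm (pixel distances scaled by the coordinate
system's pixel pitch); midline deviations as unsigned acute angles to the
atlas vertical.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .atlas import CommonCoordinateSystem
from .motifs import SensoryMap
from .roi import RegionROI

__all__ = [
    "LandmarkErrorReport",
    "AlignmentErrorReport",
    "landmark_errors",
    "midline_angle_error",
    "alignment_point_error",
    "centroid_roi_distance",
]


@dataclasses.dataclass
class LandmarkErrorReport:
    """Per-landmark Euclidean distances (mm) with mean, SEM, RMSE."""

    distances_mm: dict[int, float]
    mean_mm: float
    sem_mm: float
    rmse_mm: float
    n: int


@dataclasses.dataclass
class AlignmentErrorReport:
    """Registration error at the named midline points plus midline angle."""

    point_distances_mm: dict[str, float]
    midline_angle_deg: float


def landmark_errors(
    a: Mapping[int, Sequence[float]] | np.ndarray,
    b: Mapping[int, Sequence[float]] | np.ndarray,
    mm_per_px: float,
) -> LandmarkErrorReport:
    """Pairwise Euclidean distances between matched landmark sets.

    Accepts dicts keyed by landmark index or (n, 2) arrays matched by
    position; only shared indices are compared.  Reports the per-landmark
    distance in mm plus mean, SEM (sd/sqrt(n)) and RMSE aggregates.
    """
    if not isinstance(a, Mapping):
        a = {i + 1: p for i, p in enumerate(np.atleast_2d(np.asarray(a, float)))}
    if not isinstance(b, Mapping):
        b = {i + 1: p for i, p in enumerate(np.atleast_2d(np.asarray(b, float)))}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared landmark indices to compare")
    d = {
        i: float(np.linalg.norm(np.asarray(a[i], float) - np.asarray(b[i], float)))
        * mm_per_px
        for i in shared
    }
    vals = np.array(list(d.values()))
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return LandmarkErrorReport(
        distances_mm=d,
        mean_mm=float(vals.mean()),
        sem_mm=sem,
        rmse_mm=float(np.sqrt(np.mean(vals**2))),
        n=len(vals),
    )


def midline_angle_error(p: Sequence[float], q: Sequence[float]) -> float:
    """Unsigned acute angle (degrees) between segment pq and the atlas vertical."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("midline points coincide")
    cos = abs(d[0]) / norm  # vertical axis = row direction
    return float(math.degrees(math.acos(np.clip(cos, -1.0, 1.0))))


def alignment_point_error(
    registered: Mapping[str, Sequence[float]],
    reference: Mapping[str, Sequence[float]],
    ccs: CommonCoordinateSystem,
    points: Sequence[str] = ("lambda", "top_center"),
) -> AlignmentErrorReport:
    """mm distance at the named midline anchor points, plus midline angle.

    The two anchors default to the posterior midline landmark (lambda,
    standing in for the anterior interparietal-bone tip) and the anterior
    midline point (the frontal-pole cross point).  The midline angle is
    measured on the registered anchors' segment.
    """
    dists = {}
    for name in points:
        if name not in registered or name not in reference:
            raise ValueError(f"point {name!r} missing from inputs")
        dists[name] = float(
            np.linalg.norm(
                np.asarray(registered[name], float) - np.asarray(reference[name], float)
            )
            * ccs.mm_per_px
        )
    p, q = (np.asarray(registered[name], float) for name in points[:2])
    return AlignmentErrorReport(dists, midline_angle_error(p, q))


def centroid_roi_distance(
    sensory: SensoryMap, roi: RegionROI, ccs: CommonCoordinateSystem
) -> float:
    """mm distance between a sensory activation centroid and an ROI centroid.

    The ROI centroid is the mean of its mask pixel coordinates.
    """
    px = np.argwhere(roi.pixel_mask > 0)
    if len(px) == 0:
        raise ValueError("ROI mask is empty")
    roi_centroid = px.mean(axis=0)
    d = np.linalg.norm(np.asarray(sensory.centroid_px, float) - roi_centroid)
    return float(d * ccs.mm_per_px)
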