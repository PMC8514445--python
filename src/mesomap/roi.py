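"""Brain-region ROI extraction from a warped label image.

Converts a registered parcellation plus brain mask into labeled region
ROIs: one morphological dilation pass to denoise, outer-contour tracing,
a pole-of-inaccessibility center per contour (the interior point farthest
from the polygon edges, found by iterative quadtree grid refinement), and
two numbering schemes — by atlas region ID, or spatially from the
top-leftmost to bottom-rightmost center per hemisphere with vertically
aligned centers re-sorted top to bottom.
"""

from __future__ import annotations

import dataclasses
import heapq
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import savemat
from shapely.geometry import Point, Polygon
from skimage import measure

from .atlas import RegionAtlas

__all__ = [
    "RegionROI",
    "dilate_once",
    "extract_contours",
    "pole_of_inaccessibility",
    "label_by_id",
    "order_spatial",
    "export_rois",
    "load_rois_json",
]


@dataclasses.dataclass
class RegionROI:
    """One extracted brain-region ROI."""

    roi_number: int
    region_id: int | None
    acronym: str | None
    contour: np.ndarray  # (n, 2) closed polygon, (row, col), CCW
    center: tuple[float, float]  # pole of inaccessibility
    pixel_mask: np.ndarray


def dilate_once(label_image: np.ndarray) -> np.ndarray:
    """One 3x3 dilation pass: regions expand into background, ties -> lower ID."""
    lab = np.asarray(label_image)
    out = lab.copy()
    big = np.iinfo(np.int64).max
    cand = np.where(lab > 0, lab.astype(np.int64), big)
    best = np.full_like(cand, big)
    h, w = lab.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(cand, big)
            rs = slice(max(dr, 0), h + min(dr, 0))
            rd = slice(max(-dr, 0), h + min(-dr, 0))
            cs = slice(max(dc, 0), w + min(dc, 0))
            cd = slice(max(-dc, 0), w + min(-dc, 0))
            shifted[rd, cd] = cand[rs, cs]
            best = np.minimum(best, shifted)
    grow = (lab == 0) & (best < big)
    out[grow] = best[grow]
    return out


def _orient_ccw(poly: np.ndarray) -> np.ndarray:
    """Counter-clockwise in (row, col) display coordinates (shoelace < 0)."""
    p = np.asarray(poly, dtype=float)
    area2 = np.sum(p[:-1, 0] * p[1:, 1] - p[1:, 0] * p[:-1, 1])
    # rows grow downward, so screen-CCW corresponds to negative shoelace sum
    return p if area2 < 0 else p[::-1]


def extract_contours(binary_region: np.ndarray) -> list[np.ndarray]:
    """Outer boundary polygon of each connected component, CCW, closed."""
    binary = np.asarray(binary_region).astype(bool)
    polys: list[np.ndarray] = []
    lab = measure.label(binary, connectivity=2)
    for rid in range(1, lab.max() + 1):
        comp = lab == rid
        padded = np.pad(comp.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        # the outer boundary is the contour with the largest enclosed area
        def enclosed(c: np.ndarray) -> float:
            return abs(
                float(np.sum(c[:-1, 0] * c[1:, 1] - c[1:, 0] * c[:-1, 1])) / 2.0
            )

        outer = max(contours, key=enclosed) - 1.0  # undo padding offset
        if not np.allclose(outer[0], outer[-1]):
            outer = np.vstack([outer, outer[0]])
        polys.append(_orient_ccw(outer))
    return polys


def _signed_distance(poly: Polygon, r: float, c: float) -> float:
    """Distance to the polygon boundary, negative outside."""
    pt = Point(c, r)
    d = poly.exterior.distance(pt)
    for ring in poly.interiors:
        d = min(d, ring.distance(pt))
    return d if poly.contains(pt) else -d


def pole_of_inaccessibility(
    polygon: np.ndarray, precision: float = 0.5
) -> tuple[tuple[float, float], float]:
    """Interior point farthest from the polygon edges (quadtree refinement).

    Cells over the bounding box are refined in priority order of their
    potential maximum clearance until the best cell's potential is within
    ``precision`` of the best clearance found.  Returns ((row, col),
    clearance).
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    p = np.asarray(polygon, dtype=float)
    shp = Polygon([(c, r) for r, c in p])
    if not shp.is_valid:
        shp = shp.buffer(0)
    if shp.is_empty or shp.area == 0:
        raise ValueError("degenerate (zero-area) polygon")
    rmin, cmin = p.min(axis=0)
    rmax, cmax = p.max(axis=0)
    cell = min(rmax - rmin, cmax - cmin)
    if cell == 0:
        raise ValueError("degenerate (zero-area) polygon")
    half = cell / 2.0
    heap: list[tuple[float, int, float, float, float]] = []
    counter = 0

    def push(r: float, c: float, hsize: float) -> None:
        nonlocal counter
        d = _signed_distance(shp, r, c)
        heapq.heappush(heap, (-(d + hsize * math.sqrt(2)), counter, r, c, hsize))
        counter += 1

    r = rmin + half
    while r <= rmax:
        c = cmin + half
        while c <= cmax:
            push(r, c, half)
            c += cell
        r += cell
    # seed with the centroid, which the pole must beat
    cent = shp.centroid
    best_r, best_c = cent.y, cent.x
    best_d = _signed_distance(shp, best_r, best_c)
    while heap:
        neg_pot, _, r, c, hsize = heapq.heappop(heap)
        if -neg_pot - best_d <= precision:
            break
        d = _signed_distance(shp, r, c)
        if d > best_d:
            best_d, best_r, best_c = d, r, c
        if hsize * math.sqrt(2) > precision / 4:
            q = hsize / 2.0
            for dr in (-q, q):
                for dc in (-q, q):
                    push(r + dr, c + dc, q)
    return (float(best_r), float(best_c)), float(best_d)


def label_by_id(
    warped_labels: np.ndarray,
    mask: np.ndarray,
    atlas: RegionAtlas | None = None,
    precision: float = 0.5,
) -> list[RegionROI]:
    """Method 1: one ROI per region ID present (per connected component).

    The warped unique-number matrix is intersected with the brain mask;
    every connected component of every present ID becomes an ROI carrying
    that region's ID and acronym.
    """
    lab = np.asarray(warped_labels).astype(np.int64)
    mask = np.asarray(mask).astype(bool)
    lab = np.where(mask, lab, 0)
    rois: list[RegionROI] = []
    n = 0
    for rid in np.unique(lab):
        if rid == 0:
            continue
        region = lab == rid
        comp_lab = measure.label(region, connectivity=2)
        for comp_id in range(1, comp_lab.max() + 1):
            comp = comp_lab == comp_id
            if comp.sum() < 3:
                continue
            polys = extract_contours(comp)
            if not polys:
                continue
            poly = max(polys, key=lambda q: Polygon([(c, r) for r, c in q]).area)
            try:
                center, _ = pole_of_inaccessibility(poly, precision)
            except ValueError:
                continue
            n += 1
            rois.append(
                RegionROI(
                    roi_number=n,
                    region_id=int(rid),
                    acronym=atlas.acronym_of(int(rid)) if atlas is not None else None,
                    contour=poly,
                    center=center,
                    pixel_mask=comp.astype(np.uint8),
                )
            )
    return rois


def order_spatial(
    rois: Sequence[RegionROI], bregma_col: float, alignment_tol: float = 5.0
) -> list[RegionROI]:
    """Method 2: renumber ROIs spatially, separately per hemisphere.

    Within each hemisphere (center col < / >= bregma column) ROIs are
    ordered from the top-leftmost to the bottom-rightmost center; any
    maximal chain of centers whose columns successively differ by less
    than ``alignment_tol`` px counts as vertically aligned and is
    re-sorted top to bottom.  Numbering is deterministic and independent
    of the input order.
    """
    left = [r for r in rois if r.center[1] < bregma_col]
    right = [r for r in rois if r.center[1] >= bregma_col]
    ordered: list[RegionROI] = []
    for group in (left, right):
        by_col = sorted(group, key=lambda r: (r.center[1], r.center[0]))
        chains: list[list[RegionROI]] = []
        for r in by_col:
            if chains and r.center[1] - chains[-1][-1].center[1] < alignment_tol:
                chains[-1].append(r)
            else:
                chains.append([r])
        for chain in chains:
            ordered.extend(sorted(chain, key=lambda r: (r.center[0], r.center[1])))
    return [
        dataclasses.replace(r, roi_number=i + 1) for i, r in enumerate(ordered)
    ]


def export_rois(
    rois: Sequence[RegionROI], path: str | Path, format: str = "json"
) -> Path:
    """Write ROIs as JSON or as a MAT-file of logical masks (roi_<n>)."""
    path = Path(path)
    if format == "json":
        payload = [
            {
                "roi_number": r.roi_number,
                "region_id": r.region_id,
                "acronym": r.acronym,
                "center": [float(r.center[0]), float(r.center[1])],
                "contour": np.asarray(r.contour, dtype=float).tolist(),
                "mask_shape": list(r.pixel_mask.shape),
                "mask_pixels": np.argwhere(r.pixel_mask > 0).tolist(),
            }
            for r in rois
        ]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif format == "matfile":
        savemat(
            path,
            {f"roi_{r.roi_number}": r.pixel_mask.astype(bool) for r in rois},
        )
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def load_rois_json(path: str | Path) -> list[RegionROI]:
    """Read back a JSON ROI export."""
    payload = json.loads(Path(path).read_text())
    rois = []
    for item in payload:
        mask = np.zeros(tuple(item["mask_shape"]), dtype=np.uint8)
        px = np.asarray(item["mask_pixels"], dtype=int)
        if len(px):
            mask[px[:, 0], px[:, 1]] = 1
        rois.append(
            RegionROI(
                roi_number=int(item["roi_number"]),
                region_id=item["region_id"],
                acronym=item["acronym"],
                contour=np.asarray(item["contour"], dtype=float),
                center=(float(item["center"][0]), float(item["center"][1])),
                pixel_mask=mask,
            )
        )
    return rois
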