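"""Landmark-based atlas registration.

All warps operate on (row, col) pixel coordinates.  An affine map is a
2x3 matrix [A | t] acting as p' = A p + t.  Atlas-to-brain warps the
reference parcellation onto a brain image using per-hemisphere affine
transforms fitted from landmark correspondences; brain-to-atlas is the
inverse direction, registering each masked hemisphere independently into
the common atlas frame.  The fitting strategy per hemisphere follows the
number of usable landmarks: three or more -> three-point affine (triple
selected by rule or by confidence), exactly two -> similarity (rotation +
uniform scale + translation), otherwise a whole-brain fallback transform
from every available landmark.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay

from .atlas import (
    CommonCoordinateSystem,
    LandmarkDefinition,
    RegionAtlas,
    atlas_landmark_pixels,
)

__all__ = [
    "LandmarkObservation",
    "AffineMap2D",
    "PiecewiseAffineMap",
    "HemisphereSplit",
    "fit_affine_three",
    "fit_similarity_two",
    "fit_affine_multi",
    "select_triples",
    "atlas_to_brain",
    "brain_to_atlas",
    "fit_piecewise_affine",
    "apply_deformation",
    "warp_image",
    "compose",
    "invert",
]


@dataclasses.dataclass(frozen=True)
class LandmarkObservation:
    """A named landmark detected on a brain image."""

    index: int
    name: str
    px: tuple[float, float]  # (row, col)
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclasses.dataclass(frozen=True)
class AffineMap2D:
    """2x3 affine map on (row, col) pixel coordinates: p' = A p + t."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineMap2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (row, col) points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.linear.T + self.translation

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, AffineMap2D.identity().matrix, atol=tol))


def compose(a: AffineMap2D, b: AffineMap2D) -> AffineMap2D:
    """Composition a ∘ b (apply b first, then a)."""
    lin = a.linear @ b.linear
    t = a.linear @ b.translation + a.translation
    return AffineMap2D(np.column_stack([lin, t]))


def invert(a: AffineMap2D) -> AffineMap2D:
    lin = np.linalg.inv(a.linear)
    return AffineMap2D(np.column_stack([lin, -lin @ a.translation]))


def _collinear(points: np.ndarray, rel_tol: float = 1e-9) -> bool:
    p = np.asarray(points, dtype=float)
    area2 = abs(
        (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
        - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])
    )
    scale = max(np.ptp(p[:, 0]), np.ptp(p[:, 1]), 1.0)
    return area2 < rel_tol * scale**2


def fit_affine_three(src: np.ndarray, dst: np.ndarray) -> AffineMap2D:
    """Exact affine mapping three source points onto three destinations."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (3, 2) or dst.shape != (3, 2):
        raise ValueError("fit_affine_three needs exactly three point pairs")
    if _collinear(src):
        raise ValueError("source points are collinear")
    if _collinear(dst):
        raise ValueError("destination points are collinear")
    ones = np.column_stack([src, np.ones(3)])
    sol = np.linalg.solve(ones, dst)  # (3,2): rows = [A^T; t]
    return AffineMap2D(np.column_stack([sol[:2].T, sol[2]]))


def fit_similarity_two(src: np.ndarray, dst: np.ndarray) -> AffineMap2D:
    """Rotation + uniform scale + translation mapping two points exactly.

    No shear and no reflection; uses the complex-plane closed form
    w = a z + b with z = col + i row.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (2, 2) or dst.shape != (2, 2):
        raise ValueError("fit_similarity_two needs exactly two point pairs")
    z = src[:, 1] + 1j * src[:, 0]
    w = dst[:, 1] + 1j * dst[:, 0]
    if z[0] == z[1]:
        raise ValueError("source points coincide")
    a = (w[1] - w[0]) / (z[1] - z[0])
    b = w[0] - a * z[0]
    # in (row, col) coordinates the complex multiply is the same rotation
    lin = np.array([[a.real, a.imag], [-a.imag, a.real]])
    t = np.array([b.imag, b.real])
    return AffineMap2D(np.column_stack([lin, t]))


def fit_affine_multi(src: np.ndarray, dst: np.ndarray) -> AffineMap2D:
    """Least-squares affine for n >= 3 correspondences."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.ndim != 2 or src.shape[0] < 3 or src.shape != dst.shape:
        raise ValueError("fit_affine_multi needs n >= 3 matched point pairs")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("source points are collinear (rank-deficient system)")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineMap2D(np.column_stack([sol[:2].T, sol[2]]))


# --------------------------------------------------------------------------
# landmark bookkeeping

_DEFAULT_TRIPLES = {
    # lateral point, top-center midline point, lambda (by landmark index)
    "left": (4, 1, 6),
    "right": (7, 1, 6),
}


def _usable(obs: Sequence[LandmarkObservation], min_confidence: float):
    return [o for o in obs if o.confidence >= min_confidence]


def _side_obs(
    obs: Sequence[LandmarkObservation],
    defs: Sequence[LandmarkDefinition],
    side: str,
) -> list[LandmarkObservation]:
    """Observations usable by one hemisphere: its own plus midline landmarks."""
    role = {d.index: d.hemisphere_role for d in defs}
    return [o for o in obs if role.get(o.index) in (side, "midline")]


def select_triples(
    obs: Sequence[LandmarkObservation],
    defs: Sequence[LandmarkDefinition],
    mode: Literal["default", "confidence"] = "default",
    min_confidence: float = 0.5,
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Choose the three-landmark combination per hemisphere.

    ``default`` returns the prescribed triple (lateral point, anterior
    midline point, lambda), falling back to the first/last three usable
    points when a prescribed landmark is missing.  ``confidence``
    maximizes summed confidence over non-collinear candidate triples,
    preferring the default triple on ties.

    Raises ValueError when a hemisphere has fewer than three usable
    observations, signalling the caller to fall back to a two-point or
    whole-brain fit.
    """
    usable = _usable(obs, min_confidence)
    left = _select_one_triple("left", usable, defs, mode)
    right = _select_one_triple("right", usable, defs, mode)
    return left, right


def _select_one_triple(
    side: str,
    usable: Sequence[LandmarkObservation],
    defs: Sequence[LandmarkDefinition],
    mode: str,
) -> tuple[int, int, int]:
    atlas_mm = {d.index: np.asarray(d.mm_xy, dtype=float) for d in defs}
    side_obs = _side_obs(usable, defs, side)
    by_index = {o.index: o for o in side_obs}

    def triple_ok(cand) -> bool:
        # both the observed points and the atlas-side anchors must span a
        # triangle (the three midline landmarks are collinear in the atlas)
        obs_pts = np.array([by_index[i].px for i in cand])
        atlas_pts = np.array([atlas_mm[i] for i in cand])
        return not _collinear(obs_pts) and not _collinear(atlas_pts)

    if len(side_obs) < 3:
        raise ValueError(
            f"{side} hemisphere has only {len(side_obs)} usable landmarks; "
            "fall back to a two-point or whole-brain fit"
        )
    default = _DEFAULT_TRIPLES[side]
    default_ok = all(i in by_index for i in default) and triple_ok(default)
    if mode == "default":
        if default_ok:
            return default
        idx = sorted(by_index)
        candidates = itertools.combinations(idx if side == "left" else idx[::-1], 3)
        pick = next((tuple(sorted(c)) for c in candidates if triple_ok(c)), None)
        if pick is None:
            raise ValueError(f"all candidate triples for {side} hemisphere are degenerate")
        return pick
    best, best_sum = None, -np.inf
    for cand in itertools.combinations(sorted(by_index), 3):
        if not triple_ok(cand):
            continue
        s = sum(by_index[i].confidence for i in cand)
        if s > best_sum + 1e-12:
            best, best_sum = cand, s
    if best is None:
        raise ValueError(f"all candidate triples for {side} hemisphere are degenerate")
    if default_ok and sum(by_index[i].confidence for i in default) >= best_sum - 1e-12:
        best = default  # tie rule: prefer the prescribed triple
    return tuple(best)


def _fit_side(
    obs_side: list[LandmarkObservation],
    src_of: Callable[[LandmarkObservation], np.ndarray],
    dst_of: Callable[[LandmarkObservation], np.ndarray],
    triple: tuple[int, int, int] | None,
) -> AffineMap2D | None:
    """Fit one hemisphere's transform by the landmark-count strategy ladder."""
    if triple is not None:
        chosen = [o for o in obs_side if o.index in triple]
        src = np.array([src_of(o) for o in chosen])
        dst = np.array([dst_of(o) for o in chosen])
        try:
            return fit_affine_three(src, dst)
        except ValueError:
            pass  # degenerate triple; degrade to the multi/two-point rungs
    if len(obs_side) >= 3:
        src = np.array([src_of(o) for o in obs_side])
        dst = np.array([dst_of(o) for o in obs_side])
        try:
            return fit_affine_multi(src, dst)
        except ValueError:
            pass
    if len(obs_side) >= 2:
        src = np.array([src_of(o) for o in obs_side])
        dst = np.array([dst_of(o) for o in obs_side])
        # two most distant observations give the stablest similarity fit
        d = np.linalg.norm(src[:, None] - src[None, :], axis=2)
        i, j = np.unravel_index(int(d.argmax()), d.shape)
        if d[i, j] > 0:
            return fit_similarity_two(src[[i, j]], dst[[i, j]])
    return None


def _hemisphere_transforms(
    obs: Sequence[LandmarkObservation],
    defs: Sequence[LandmarkDefinition],
    atlas_px: np.ndarray,
    direction: Literal["atlas_to_brain", "brain_to_atlas"],
    mode: str,
    min_confidence: float,
) -> tuple[AffineMap2D, AffineMap2D]:
    """Fit (left, right) transforms with per-hemisphere strategy + fallback."""
    usable = _usable(obs, min_confidence)
    if len(usable) < 2:
        # confidence cut left too few landmarks: take the two most trusted
        usable = sorted(obs, key=lambda o: -o.confidence)[:2]
    if len(usable) < 2:
        raise ValueError("need at least two usable landmark observations")
    atlas_pt = {i + 1: atlas_px[i] for i in range(9)}

    def src_of(o: LandmarkObservation) -> np.ndarray:
        return np.asarray(atlas_pt[o.index] if direction == "atlas_to_brain" else o.px)

    def dst_of(o: LandmarkObservation) -> np.ndarray:
        return np.asarray(o.px if direction == "atlas_to_brain" else atlas_pt[o.index])

    triples: dict[str, tuple[int, int, int] | None] = {}
    for side in ("left", "right"):
        try:
            triples[side] = _select_one_triple(side, usable, defs, mode)
        except ValueError:
            triples[side] = None

    maps = {}
    for side in ("left", "right"):
        side_obs = _side_obs(usable, defs, side)
        maps[side] = _fit_side(side_obs, src_of, dst_of, triples[side])
    if maps["left"] is None and maps["right"] is None:
        # global fallback: one whole-brain transform from every usable landmark
        src = np.array([src_of(o) for o in usable])
        dst = np.array([dst_of(o) for o in usable])
        try:
            m = fit_affine_multi(src, dst) if len(usable) >= 3 else fit_similarity_two(src, dst)
        except ValueError:
            d = np.linalg.norm(src[:, None] - src[None, :], axis=2)
            i, j = np.unravel_index(int(d.argmax()), d.shape)
            m = fit_similarity_two(src[[i, j]], dst[[i, j]])
        return m, m
    if maps["left"] is None:
        maps["left"] = maps["right"]
    if maps["right"] is None:
        maps["right"] = maps["left"]
    return maps["left"], maps["right"]


@dataclasses.dataclass
class HemisphereSplit:
    """Midline line (point + unit direction) and left/right half-plane masks."""

    point: np.ndarray
    direction: np.ndarray  # unit (d_row, d_col), d_row >= 0 (pointing posterior)

    def side(self, points: np.ndarray) -> np.ndarray:
        """+1 right of the midline, -1 left (ties assigned left)."""
        p = np.atleast_2d(points) - self.point
        cross = self.direction[0] * p[..., 1] - self.direction[1] * p[..., 0]
        return np.where(cross > 0, 1, -1)

    def half_masks(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        s = self.side(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(shape)
        return s < 0, s > 0


def _brain_midline(
    obs: Sequence[LandmarkObservation], defs: Sequence[LandmarkDefinition]
) -> HemisphereSplit:
    """Midline through bregma and lambda observations; else vertical through bregma."""
    name = {d.index: d.name for d in defs}
    bregma = next((o for o in obs if name.get(o.index) == "bregma"), None)
    lam = next((o for o in obs if name.get(o.index) == "lambda"), None)
    top = next((o for o in obs if name.get(o.index) == "top_center"), None)
    anchor = bregma or lam or top
    if anchor is None:
        if not obs:
            raise ValueError("no landmark observations; cannot place hemisphere split")
        # no midline landmark observed: vertical split at the mean column
        mean_pt = np.mean([o.px for o in obs], axis=0)
        return HemisphereSplit(np.asarray(mean_pt, dtype=float), np.array([1.0, 0.0]))
    if bregma is not None and lam is not None:
        d = np.array(lam.px, dtype=float) - np.array(bregma.px, dtype=float)
        n = np.linalg.norm(d)
        if n > 1e-9:
            d = d / n
            if d[0] < 0:
                d = -d
            return HemisphereSplit(np.array(bregma.px, dtype=float), d)
    return HemisphereSplit(np.array(anchor.px, dtype=float), np.array([1.0, 0.0]))


def warp_image(
    m: AffineMap2D,
    image: np.ndarray,
    output_shape: tuple[int, int] | None = None,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Warp an image by an affine map: out(p) = in(m^{-1}(p))."""
    if output_shape is None:
        output_shape = image.shape
    inv = invert(m)
    rr, cc = np.mgrid[0 : output_shape[0], 0 : output_shape[1]].astype(float)
    src = inv.apply(np.stack([rr.ravel(), cc.ravel()], axis=1))
    coords = src.T.reshape(2, *output_shape)
    return map_coordinates(image.astype(float), coords, order=order, cval=cval)


def _fill_seam(labels: np.ndarray, region: np.ndarray) -> np.ndarray:
    """One nearest-neighbor dilation pass filling zeros inside ``region``.

    Zero pixels take the smallest positive 3x3-neighbor label drawn from
    pixels of the same region (hemisphere side), keeping the two warped
    halves independent.
    """
    out = labels.copy()
    big = np.iinfo(np.int64).max
    cand = np.where((labels > 0) & region, labels, big)
    best = np.full_like(cand, big)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(cand, big)
            rs = slice(max(dr, 0), labels.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), labels.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), labels.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), labels.shape[1] + min(-dc, 0))
            shifted[rd, cd] = cand[rs, cs]
            best = np.minimum(best, shifted)
    fill = (labels == 0) & region & (best < big)
    out[fill] = best[fill]
    return out


@dataclasses.dataclass
class AtlasToBrainResult:
    """Warped parcellation in the brain frame plus the transforms used."""

    labels: np.ndarray
    boundary: np.ndarray
    left_map: AffineMap2D  # atlas px -> brain px
    right_map: AffineMap2D
    midline: HemisphereSplit


def atlas_to_brain(
    atlas: RegionAtlas,
    obs: Sequence[LandmarkObservation],
    defs: Sequence[LandmarkDefinition],
    ccs: CommonCoordinateSystem,
    mask: np.ndarray,
    mode: str = "default",
    min_confidence: float = 0.5,
) -> AtlasToBrainResult:
    """Warp the reference parcellation onto a brain image.

    The left and right atlas halves are warped by independent affine
    transforms fitted from each hemisphere's landmarks; each output pixel
    is assigned by exactly one hemisphere transform according to its side
    of the brain midline, seam gaps are closed by one nearest-neighbor
    dilation pass per side, and the result is clipped to the brain mask.
    """
    mask = np.asarray(mask).astype(bool)
    atlas_px = atlas_landmark_pixels(atlas, defs, ccs)
    t_l, t_r = _hemisphere_transforms(
        obs, defs, atlas_px, "atlas_to_brain", mode, min_confidence
    )
    split = _brain_midline(list(obs), defs)
    h, w = mask.shape
    c_mid = ccs.bregma_px[1]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    side = split.side(pts).reshape(h, w)

    labels = np.zeros((h, w), dtype=np.int64)
    boundary = np.zeros((h, w), dtype=np.uint8)
    for sgn, t, atlas_side in ((-1, t_l, "left"), (1, t_r, "right")):
        sel = side == sgn
        if not sel.any():
            continue
        src = invert(t).apply(pts[sel.ravel()])
        r, c = src[:, 0], src[:, 1]
        ri = np.clip(np.rint(r).astype(int), 0, atlas.label_image.shape[0] - 1)
        ci = np.clip(np.rint(c).astype(int), 0, atlas.label_image.shape[1] - 1)
        vals = atlas.label_image[ri, ci]
        bvals = atlas.boundary_image[ri, ci]
        inside = (
            (r >= -0.5)
            & (r <= atlas.label_image.shape[0] - 0.5)
            & (c >= -0.5)
            & (c <= atlas.label_image.shape[1] - 0.5)
        )
        correct_half = (c <= c_mid) if atlas_side == "left" else (c > c_mid)
        keep = inside & correct_half
        lab_flat = np.zeros(sel.sum(), dtype=np.int64)
        lab_flat[keep] = vals[keep]
        labels[sel] = lab_flat
        b_flat = np.zeros(sel.sum(), dtype=np.uint8)
        b_flat[keep] = bvals[keep]
        boundary[sel] = b_flat

    labels = _fill_seam(labels, (side < 0) & mask)
    labels = _fill_seam(labels, (side > 0) & mask)
    labels[~mask] = 0
    boundary[~mask] = 0
    return AtlasToBrainResult(labels, boundary, t_l, t_r, split)


@dataclasses.dataclass
class BrainToAtlasResult:
    """Brain image registered into the common atlas frame."""

    image: np.ndarray
    mask: np.ndarray
    left_map: AffineMap2D  # brain px -> atlas px
    right_map: AffineMap2D
    brain_midline: HemisphereSplit

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map brain-frame points to the atlas frame by their hemisphere's transform."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        sides = self.brain_midline.side(p)
        out = np.empty_like(p)
        for sgn, t in ((-1, self.left_map), (1, self.right_map)):
            sel = sides == sgn
            if sel.any():
                out[sel] = t.apply(p[sel])
        return out


def brain_to_atlas(
    image: np.ndarray,
    obs: Sequence[LandmarkObservation],
    defs: Sequence[LandmarkDefinition],
    ccs: CommonCoordinateSystem,
    mask: np.ndarray,
    atlas_shape: tuple[int, int],
    mode: str = "default",
    min_confidence: float = 0.5,
) -> BrainToAtlasResult:
    """Register a brain image into the common atlas frame.

    Each hemisphere of the masked brain (split at the bregma-lambda
    midline) is warped independently into its side of the atlas canvas.
    Any disconnected anterior component of the mask (olfactory bulb)
    carries over with its hemisphere's transform, since the transform is
    applied to the entire half-plane.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    atlas_px_pts = np.array(
        [  # canonical landmark pixels in the atlas frame
            [ccs.bregma_px[0] - d.mm_xy[1] / ccs.mm_per_px,
             ccs.bregma_px[1] + d.mm_xy[0] / ccs.mm_per_px]
            for d in sorted(defs, key=lambda d: d.index)
        ]
    )
    t_l, t_r = _hemisphere_transforms(
        obs, defs, atlas_px_pts, "brain_to_atlas", mode, min_confidence
    )
    split = _brain_midline(list(obs), defs)
    h, w = atlas_shape
    c_mid = ccs.bregma_px[1]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    out_img = np.zeros((h, w), dtype=float)
    out_mask = np.zeros((h, w), dtype=bool)
    left_out = cc <= c_mid
    for sel, t in ((left_out, t_l), (~left_out, t_r)):
        pts = np.stack([rr[sel], cc[sel]], axis=1)
        src = invert(t).apply(pts)
        coords = src.T
        vals = map_coordinates(image, coords, order=1, cval=0.0)
        mvals = map_coordinates(mask.astype(np.uint8), coords, order=0, cval=0)
        out_img[sel] = np.where(mvals > 0, vals, 0.0)
        out_mask[sel] = mvals > 0
    return BrainToAtlasResult(out_img, out_mask, t_l, t_r, split)


# --------------------------------------------------------------------------
# piecewise-affine and dense deformation warps


class PiecewiseAffineMap:
    """Per-triangle affine interpolation between matched control points.

    Control points map exactly; interior points use the affine of their
    Delaunay triangle; points outside the convex hull extend the affine of
    the nearest triangle (by centroid distance).
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray):
        src = np.asarray(src, dtype=float)
        dst = np.asarray(dst, dtype=float)
        if src.ndim != 2 or src.shape[0] < 3 or src.shape != dst.shape:
            raise ValueError("need >= 3 matched control point pairs")
        if src.shape[0] == 3 and _collinear(src):
            raise ValueError("control points are collinear")
        if np.linalg.matrix_rank(np.column_stack([src, np.ones(len(src))])) < 3:
            raise ValueError("control points are collinear")
        self.src = src
        self.dst = dst
        self.tri = Delaunay(src)
        self._affines = [
            fit_affine_three(src[s], dst[s]) for s in self.tri.simplices
        ]
        self._centroids = np.array([src[s].mean(axis=0) for s in self.tri.simplices])

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        simplex = self.tri.find_simplex(p)
        outside = simplex < 0
        if outside.any():
            d = np.linalg.norm(
                p[outside, None, :] - self._centroids[None, :, :], axis=2
            )
            simplex = simplex.copy()
            simplex[outside] = d.argmin(axis=1)
        out = np.empty_like(p)
        for s in np.unique(simplex):
            sel = simplex == s
            out[sel] = self._affines[s].apply(p[sel])
        return out


def fit_piecewise_affine(src_peaks: np.ndarray, dst_peaks: np.ndarray) -> PiecewiseAffineMap:
    """Piecewise-affine map from matched control points (e.g. sensory peaks)."""
    return PiecewiseAffineMap(src_peaks, dst_peaks)


def apply_deformation(
    field: np.ndarray,
    image: np.ndarray,
    interpolation: Literal["nearest", "bilinear"] = "bilinear",
) -> np.ndarray:
    """Apply a dense displacement field: out(p) = in(p + field(p)).

    ``field`` is a (2, H, W) array of (row, col) displacements in px.
    Label images should use ``nearest`` interpolation.
    """
    field = np.asarray(field, dtype=float)
    image_arr = np.asarray(image)
    if field.shape != (2, *image_arr.shape):
        raise ValueError(
            f"field shape {field.shape} does not match image {image_arr.shape}"
        )
    rr, cc = np.mgrid[0 : image_arr.shape[0], 0 : image_arr.shape[1]].astype(float)
    coords = np.stack([rr + field[0], cc + field[1]])
    order = 0 if interpolation == "nearest" else 1
    out = map_coordinates(image_arr.astype(float), coords, order=order, cval=0.0)
    if interpolation == "nearest":
        out = out.astype(image_arr.dtype)
    return out
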