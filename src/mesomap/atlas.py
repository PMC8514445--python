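"""Reference cortical parcellation, common coordinate system, and landmarks.

The atlas is a 2D top-view parcellation of the dorsal mouse cortex: an
integer-labeled image (0 = background, positive IDs = regions), a region
table, and a set of nine named landmarks expressed in a bregma-origin
millimetre frame.  Pixel coordinates are (row, col), 0-based, with rows
increasing toward posterior; the mm frame has x lateral (right positive)
and y anterior positive, so bregma maps exactly to (0, 0) mm.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.segmentation import find_boundaries

__all__ = [
    "RegionAtlas",
    "CommonCoordinateSystem",
    "LandmarkDefinition",
    "load_atlas",
    "save_atlas",
    "make_test_atlas",
    "default_landmarks",
    "load_landmark_table",
    "mm_to_px",
    "px_to_mm",
    "atlas_landmark_pixels",
]


@dataclasses.dataclass(frozen=True)
class CommonCoordinateSystem:
    """Bregma-origin mm frame anchored to a pixel grid.

    Parameters
    ----------
    bregma_px : (row, col) pixel position of bregma in the atlas frame.
    mm_per_px : isotropic pixel pitch in mm (must be > 0).
    """

    bregma_px: tuple[float, float]
    mm_per_px: float
    axis_convention: str = "x-lateral-right,y-anterior-up"

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be positive, got {self.mm_per_px}")


@dataclasses.dataclass(frozen=True)
class LandmarkDefinition:
    """One of the nine cortical landmarks in atlas mm coordinates."""

    index: int
    name: str
    mm_xy: tuple[float, float]
    hemisphere_role: str  # left | right | midline

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 9:
            raise ValueError(f"landmark index must be in 1..9, got {self.index}")
        if self.hemisphere_role not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere_role {self.hemisphere_role!r}")


@dataclasses.dataclass
class RegionAtlas:
    """Integer-labeled parcellation plus region table and boundary outlines."""

    label_image: np.ndarray
    regions: pd.DataFrame  # columns: id, acronym, name, hemisphere
    boundary_image: np.ndarray

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["id"].to_numpy()

    def acronym_of(self, region_id: int) -> str | None:
        row = self.regions[self.regions["id"] == region_id]
        return None if row.empty else str(row["acronym"].iloc[0])


def _compute_boundary(label_image: np.ndarray) -> np.ndarray:
    """Region outlines: nonzero on labeled pixels adjacent to a differing label."""
    if label_image.size == 0 or label_image.max() == 0:
        return np.zeros_like(label_image, dtype=np.uint8)
    b = find_boundaries(label_image, mode="inner")
    return (b & (label_image > 0)).astype(np.uint8)


def _validate(label_image: np.ndarray, regions: pd.DataFrame) -> None:
    ids = regions["id"].to_numpy() if len(regions) else np.array([], dtype=int)
    if len(ids) != len(np.unique(ids)):
        dup = sorted(regions["id"][regions["id"].duplicated()].unique().tolist())
        raise ValueError(f"duplicate region IDs in table: {dup}")
    present = np.unique(label_image)
    present = present[present > 0]
    orphans = sorted(set(present.tolist()) - set(ids.tolist()))
    if orphans:
        raise ValueError(f"label image contains IDs absent from region table: {orphans}")


def load_atlas(label_path: str | Path, table_path: str | Path) -> RegionAtlas:
    """Load a parcellation image (integer PNG/TIFF) and its region table CSV."""
    label_image = np.asarray(iio.imread(label_path))
    if label_image.ndim == 3:  # collapse grayscale-stored-as-RGB
        label_image = label_image[..., 0]
    if not np.issubdtype(label_image.dtype, np.integer):
        if not np.all(label_image == np.round(label_image)):
            raise ValueError("label image must be integer-valued")
        label_image = label_image.astype(np.int64)
    label_image = label_image.astype(np.int64)
    regions = pd.read_csv(table_path) if Path(table_path).stat().st_size else pd.DataFrame(
        columns=["id", "acronym", "name", "hemisphere"]
    )
    missing = {"id", "acronym", "name", "hemisphere"} - set(regions.columns)
    if missing and len(regions):
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    if not len(regions):
        regions = pd.DataFrame(columns=["id", "acronym", "name", "hemisphere"])
    _validate(label_image, regions)
    return RegionAtlas(label_image, regions, _compute_boundary(label_image))


def save_atlas(atlas: RegionAtlas, label_path: str | Path, table_path: str | Path) -> None:
    """Write the label image (16-bit PNG) and region table CSV."""
    iio.imwrite(label_path, atlas.label_image.astype(np.uint16))
    atlas.regions.to_csv(table_path, index=False)


def mm_to_px(ccs: CommonCoordinateSystem, p_mm: Sequence[float]) -> tuple[float, float]:
    """Convert an (x, y) mm point to a (row, col) pixel point."""
    x, y = float(p_mm[0]), float(p_mm[1])
    row = ccs.bregma_px[0] - y / ccs.mm_per_px
    col = ccs.bregma_px[1] + x / ccs.mm_per_px
    return (row, col)


def px_to_mm(ccs: CommonCoordinateSystem, p_px: Sequence[float]) -> tuple[float, float]:
    """Convert a (row, col) pixel point to an (x, y) mm point."""
    row, col = float(p_px[0]), float(p_px[1])
    x = (col - ccs.bregma_px[1]) * ccs.mm_per_px
    y = (ccs.bregma_px[0] - row) * ccs.mm_per_px
    return (x, y)


def atlas_landmark_pixels(
    atlas: RegionAtlas,
    defs: Sequence[LandmarkDefinition],
    ccs: CommonCoordinateSystem,
) -> np.ndarray:
    """Pixel positions of the nine landmarks in definition order, (9, 2)."""
    if len(defs) != 9:
        raise ValueError(f"expected nine landmark definitions, got {len(defs)}")
    h, w = atlas.label_image.shape
    out = np.empty((9, 2), dtype=float)
    for i, d in enumerate(sorted(defs, key=lambda d: d.index)):
        r, c = mm_to_px(ccs, d.mm_xy)
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(
                f"landmark {d.index} ({d.name}) at px ({r:.1f}, {c:.1f}) "
                f"is outside the {h}x{w} atlas"
            )
        out[i] = (r, c)
    return out


# --------------------------------------------------------------------------
# Bundled synthetic test atlas
#
# Two mirrored half-ellipse hemispheres plus olfactory bulbs, partitioned
# into 11 regions per hemisphere by radial/angular sectors.  Geometry is
# drawn on the left half-plane and reflected, so left/right region pixel
# sets are exact mirror images about the midline.

_LEFT_SECTORS = [
    # (acronym, name) inner band anterior->posterior then outer band
    ("MOs", "secondary motor area"),
    ("MOp", "primary motor area"),
    ("SSp-ul", "primary somatosensory area, upper limb"),
    ("RSP", "retrosplenial area"),
    ("SSp-n", "primary somatosensory area, nose"),
    ("SSp-bfd", "primary somatosensory area, barrel field"),
    ("SSp-ll", "primary somatosensory area, lower limb"),
    ("SSp-tr", "primary somatosensory area, trunk"),
    ("VISp", "primary visual area"),
    ("AUD", "auditory areas"),
]


def make_test_atlas(
    size: int = 512, mm_per_px: float | None = None
) -> tuple[RegionAtlas, CommonCoordinateSystem, list[LandmarkDefinition]]:
    """Build the bundled mirrored test atlas at the requested pixel size.

    Returns the atlas, its coordinate system (bregma at the hemisphere
    ellipse center on the midline), and the nine landmark definitions
    computed from the atlas geometry.  mm_per_px defaults so the cortex
    spans ~8 mm laterally regardless of raster size.
    """
    n = int(size)
    if n < 32:
        raise ValueError("atlas size must be >= 32 px")
    c_mid = (n - 1) / 2.0  # mirror axis (between the two center columns)
    r0 = n * 0.52
    a = n * 0.39  # hemisphere semi-axis, rows and cols alike
    if mm_per_px is None:
        mm_per_px = 8.0 / (2 * a)  # 8 mm total cortical width

    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    left = cols < c_mid
    u = (c_mid - cols) / a  # lateral fraction, positive on the left half
    v = (rows - r0) / a  # anterior(-)/posterior(+) fraction
    rho = np.hypot(u, v)
    inside = (rho < 1.0) & left  # hemispheres meet at the midline

    theta = np.arctan2(v, u)  # -pi/2 anterior ... +pi/2 posterior
    labels_left = np.zeros((n, n), dtype=np.int64)
    inner = inside & (rho < 0.55)
    outer = inside & ~ (rho < 0.55)
    inner_edges = np.linspace(-math.pi / 2, math.pi / 2, 5)
    for i in range(4):
        sel = inner & (theta >= inner_edges[i]) & (theta < inner_edges[i + 1])
        labels_left[sel] = i + 1
    outer_edges = np.linspace(-math.pi / 2, math.pi / 2, 7)
    for i in range(6):
        sel = outer & (theta >= outer_edges[i]) & (theta < outer_edges[i + 1])
        labels_left[sel] = 5 + i
    # olfactory bulb: small ellipse anterior to the frontal pole, touching
    # the cortical ellipse so the brain forms one connected component
    ob_r, ob_c = r0 - a - 0.03 * n, c_mid - 0.12 * n
    ob = ((rows - ob_r) / (0.055 * n)) ** 2 + ((cols - ob_c) / (0.07 * n)) ** 2 < 1.0
    labels_left[ob & left & (labels_left == 0)] = 11

    # mirror: right half is the left half reflected about c_mid, IDs offset by 11
    labels = labels_left.copy()
    mirrored = labels_left[:, ::-1]
    labels[mirrored > 0] = mirrored[mirrored > 0] + 11

    recs = []
    for i, (acr, name) in enumerate(_LEFT_SECTORS, start=1):
        recs.append((i, f"{acr}-L", name, "left"))
    recs.append((11, "OB-L", "olfactory bulb", "left"))
    for i, (acr, name) in enumerate(_LEFT_SECTORS, start=1):
        recs.append((i + 11, f"{acr}-R", name, "right"))
    recs.append((22, "OB-R", "olfactory bulb", "right"))
    regions = pd.DataFrame(recs, columns=["id", "acronym", "name", "hemisphere"])

    atlas = RegionAtlas(labels, regions, _compute_boundary(labels))
    ccs = CommonCoordinateSystem(bregma_px=(r0, c_mid), mm_per_px=mm_per_px)
    defs = default_landmarks(a * mm_per_px)
    return atlas, ccs, defs


def default_landmarks(semi_axis_mm: float = 4.0) -> list[LandmarkDefinition]:
    """Nine landmark definitions derived from the test-atlas geometry.

    Geometric stand-ins: anterior midline point, frontal poles, lateral
    tips, posterior retrosplenial tips, bregma, and lambda.  Left/right
    pairs mirror exactly in x.
    """
    s = semi_axis_mm
    return [
        LandmarkDefinition(1, "top_center", (0.0, s), "midline"),
        LandmarkDefinition(2, "frontal_pole_left", (-0.6 * s, 0.8 * s), "left"),
        LandmarkDefinition(3, "rsp_posterior_left", (-0.15 * s, -0.95 * s), "left"),
        LandmarkDefinition(4, "lateral_left", (-s, 0.0), "left"),
        LandmarkDefinition(5, "bregma", (0.0, 0.0), "midline"),
        LandmarkDefinition(6, "lambda", (0.0, -0.85 * s), "midline"),
        LandmarkDefinition(7, "lateral_right", (s, 0.0), "right"),
        LandmarkDefinition(8, "frontal_pole_right", (0.6 * s, 0.8 * s), "right"),
        LandmarkDefinition(9, "rsp_posterior_right", (0.15 * s, -0.95 * s), "right"),
    ]


def load_landmark_table(path: str | Path) -> list[LandmarkDefinition]:
    """Read landmark definitions from CSV (index,name,x_mm,y_mm,hemisphere_role)."""
    df = pd.read_csv(path)
    defs = [
        LandmarkDefinition(int(r["index"]), str(r["name"]),
                           (float(r["x_mm"]), float(r["y_mm"])),
                           str(r["hemisphere_role"]))
        for _, r in df.iterrows()
    ]
    if len(defs) != 9:
        raise ValueError(f"landmark table must define nine landmarks, got {len(defs)}")
    return defs
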