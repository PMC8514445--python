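"""Phantom cortical scenes and simulated activity with known ground truth.

Every downstream stage (segmentation, registration, ROI extraction, motif
discovery, clustering) can be exercised on these generators: a phantom
frame with two bright hemispheres, dark vessel curves and nine known
landmark positions; misaligned variants with a recorded ground-truth
similarity transform; noisy mock landmark observations standing in for a
trained detector; and activity movies with planted spatio-temporal
motifs.  All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import binary_dilation, gaussian_filter, map_coordinates

from .atlas import (
    CommonCoordinateSystem,
    LandmarkDefinition,
    RegionAtlas,
    _compute_boundary,
    atlas_landmark_pixels,
    make_test_atlas,
)
from .registration import AffineMap2D, LandmarkObservation, invert

__all__ = [
    "PhantomSpec",
    "PhantomScene",
    "MisalignmentSpec",
    "MotifSimSpec",
    "make_phantom",
    "perturb_alignment",
    "mock_landmarks",
    "simulate_activity",
    "save_scene",
    "load_scene",
]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cortical frame.

    Intensities are on a [0, 255] scale: dim background, bright cortex,
    vessels darker than surrounding tissue.
    """

    image_size: tuple[int, int] = (256, 256)
    vessel_count: int = 4
    vessel_width: int = 2
    noise_sigma: float = 3.0
    background_level: float = 16.0
    brain_level: float = 160.0
    vessel_contrast: float = 0.45  # multiplicative darkening on vessel pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if min(self.image_size) < 32:
            raise ValueError("image too small for the atlas geometry")


@dataclasses.dataclass
class PhantomScene:
    """A phantom frame bundled with its ground truth."""

    image: np.ndarray
    true_mask: np.ndarray
    true_labels: np.ndarray
    true_landmarks: np.ndarray  # (9, 2) (row, col) in frame coordinates
    true_transform: AffineMap2D
    atlas: RegionAtlas
    ccs: CommonCoordinateSystem
    landmark_defs: list[LandmarkDefinition]


@dataclasses.dataclass(frozen=True)
class MisalignmentSpec:
    """Similarity-transform perturbation ranges (rotation/scale/translation)."""

    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    scale: tuple[float, float] = (0.8, 1.2)
    translation_px: tuple[float, float] = (-20.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale[0] <= 0:
            raise ValueError("scale range must be positive")


@dataclasses.dataclass(frozen=True)
class MotifSimSpec:
    """Planted spatio-temporal motif simulation parameters.

    Each motif activates a group of atlas regions in sequence over its
    ``motif_frames`` window; occurrences are placed at random onsets in a
    ``movie_frames``-long recording with additive Gaussian noise.
    """

    n_motifs: int = 3
    motif_frames: int = 10
    movie_frames: int = 300
    occurrences: int = 8
    footprints: tuple[tuple[int, ...], ...] | None = None  # region-ID groups
    amplitude: float = 1.0
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        if self.motif_frames >= self.movie_frames:
            raise ValueError("motif length must be shorter than the movie")
        if self.occurrences < 1:
            raise ValueError("occurrences must be >= 1")


def _rasterize_vessels(
    rng: np.random.Generator, mask: np.ndarray, count: int, width: int
) -> np.ndarray:
    """Random quadratic Bezier curves inside the brain mask."""
    vessel = np.zeros_like(mask, dtype=bool)
    inside = np.argwhere(mask)
    if len(inside) == 0 or count == 0:
        return vessel
    for _ in range(count):
        p0, p1, p2 = inside[rng.integers(0, len(inside), size=3)].astype(float)
        t = np.linspace(0, 1, 400)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, mask.shape[0] - 1)
        cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, mask.shape[1] - 1)
        vessel[rr, cc] = True
    if width > 1:
        vessel = binary_dilation(vessel, iterations=width - 1)
    return vessel & mask


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomScene:
    """Generate a canonical (identity-aligned) phantom cortical frame."""
    h, w = spec.image_size
    n = min(h, w)
    atlas, ccs, defs = make_test_atlas(size=n)
    labels = np.zeros((h, w), dtype=np.int64)
    r_off, c_off = (h - n) // 2, (w - n) // 2
    labels[r_off : r_off + n, c_off : c_off + n] = atlas.label_image
    if r_off or c_off:
        atlas = RegionAtlas(labels, atlas.regions, _compute_boundary(labels))
        ccs = CommonCoordinateSystem(
            (ccs.bregma_px[0] + r_off, ccs.bregma_px[1] + c_off), ccs.mm_per_px
        )
    mask = labels > 0
    rng = np.random.default_rng(spec.seed)
    image = np.where(mask, spec.brain_level, spec.background_level).astype(float)
    vessels = _rasterize_vessels(rng, mask, spec.vessel_count, spec.vessel_width)
    image[vessels] *= spec.vessel_contrast
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 255.0)
    landmarks = atlas_landmark_pixels(atlas, defs, ccs)
    return PhantomScene(
        image=image,
        true_mask=mask.astype(np.uint8),
        true_labels=labels,
        true_landmarks=landmarks,
        true_transform=AffineMap2D.identity(),
        atlas=atlas,
        ccs=ccs,
        landmark_defs=defs,
    )


def _similarity_about(
    center: Sequence[float], rot_deg: float, scale: float, translation: Sequence[float]
) -> AffineMap2D:
    """Similarity transform p' = s R (p - c) + c + t in (row, col) coords."""
    th = math.radians(rot_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    lin = scale * rot
    c = np.asarray(center, dtype=float)
    t = c + np.asarray(translation, dtype=float) - lin @ c
    return AffineMap2D(np.column_stack([lin, t]))


def perturb_alignment(scene: PhantomScene, mis: MisalignmentSpec) -> PhantomScene:
    """Apply one sampled similarity misalignment to a canonical scene.

    Image intensities are resampled bilinearly, mask/labels with nearest
    neighbor; landmarks are mapped exactly and the sampled transform is
    recorded in ``true_transform``.
    """
    if not scene.true_transform.is_identity():
        raise ValueError("scene is already misaligned")
    rng = np.random.default_rng(mis.seed)
    rot = rng.uniform(*mis.rotation_deg)
    sc = rng.uniform(*mis.scale)
    tr = rng.uniform(mis.translation_px[0], mis.translation_px[1], size=2)
    center = ((scene.image.shape[0] - 1) / 2.0, (scene.image.shape[1] - 1) / 2.0)
    m = _similarity_about(center, rot, sc, tr)
    inv = invert(m)
    h, w = scene.image.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    src = inv.apply(np.stack([rr.ravel(), cc.ravel()], axis=1)).T.reshape(2, h, w)
    image = map_coordinates(scene.image, src, order=1, cval=0.0)
    mask = map_coordinates(scene.true_mask, src, order=0, cval=0)
    labels = map_coordinates(scene.true_labels, src, order=0, cval=0)
    return PhantomScene(
        image=image,
        true_mask=mask.astype(np.uint8),
        true_labels=labels.astype(np.int64),
        true_landmarks=m.apply(scene.true_landmarks),
        true_transform=m,
        atlas=scene.atlas,
        ccs=scene.ccs,
        landmark_defs=scene.landmark_defs,
    )


def mock_landmarks(
    scene: PhantomScene,
    jitter_sigma: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> list[LandmarkObservation]:
    """Noisy landmark observations standing in for a trained detector.

    Gaussian jitter (per coordinate) is added to the true positions;
    each landmark is independently dropped with probability ``dropout``
    but at least two observations are always retained.  Confidence is
    exp(-d^2 / (2 sigma^2)) for jitter displacement d (1.0 when
    jitter_sigma is 0).
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    names = {d.index: d.name for d in scene.landmark_defs}
    jit = (
        rng.normal(0.0, jitter_sigma, size=(9, 2))
        if jitter_sigma > 0
        else np.zeros((9, 2))
    )
    u = rng.uniform(size=9)
    keep = u >= dropout
    if keep.sum() < 2:  # floor rule: retain the two least-dropped landmarks
        keep[:] = False
        keep[np.argsort(u)[-2:]] = True
    obs = []
    for i in range(9):
        if not keep[i]:
            continue
        d = float(np.linalg.norm(jit[i]))
        conf = 1.0 if jitter_sigma == 0 else float(
            np.clip(math.exp(-(d**2) / (2 * jitter_sigma**2)), 0.0, 1.0)
        )
        obs.append(
            LandmarkObservation(
                index=i + 1,
                name=names[i + 1],
                px=tuple(scene.true_landmarks[i] + jit[i]),
                confidence=conf,
            )
        )
    return obs


def simulate_activity(
    scene: PhantomScene, sim: MotifSimSpec = MotifSimSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a T x H x W activity movie with planted motifs.

    Each motif sweeps activation across its group of atlas regions over
    ``motif_frames`` frames.  The movie is the sum of motifs convolved
    with their onset trains plus Gaussian noise, clipped at zero.

    Returns ``(movie, motifs, onsets)`` with motifs of shape
    (K, L, H, W) and onsets of shape (K, occurrences) in frames.
    """
    rng = np.random.default_rng(sim.seed)
    h, w = scene.true_labels.shape
    present = np.unique(scene.true_labels)
    present = present[present > 0]
    if sim.footprints is None:
        ids = rng.permutation(present)
        groups = [
            tuple(int(x) for x in ids[(3 * k) % len(ids) : (3 * k) % len(ids) + 3])
            for k in range(sim.n_motifs)
        ]
    else:
        groups = [tuple(g) for g in sim.footprints]
        for g in groups:
            missing = set(g) - set(int(x) for x in present)
            if missing:
                raise ValueError(f"footprint region IDs not in scene: {sorted(missing)}")
        if len(groups) != sim.n_motifs:
            raise ValueError("need one footprint group per motif")

    L = sim.motif_frames
    motifs = np.zeros((sim.n_motifs, L, h, w), dtype=float)
    width = max(L / 6.0, 0.8)
    for k, group in enumerate(groups):
        m = len(group)
        for j, rid in enumerate(group):
            foot = gaussian_filter((scene.true_labels == rid).astype(float), 2.0)
            peak = foot.max()
            if peak > 0:
                foot = foot / peak
            c_j = (j + 0.5) * L / m
            env = np.exp(-((np.arange(L) - c_j) ** 2) / (2 * width**2))
            motifs[k] += sim.amplitude * env[:, None, None] * foot[None]

    T = sim.movie_frames
    onsets = rng.integers(0, T - L + 1, size=(sim.n_motifs, sim.occurrences))
    movie = np.zeros((T, h, w), dtype=float)
    for k in range(sim.n_motifs):
        for t0 in onsets[k]:
            movie[t0 : t0 + L] += motifs[k]
    if sim.noise_sigma > 0:
        movie = movie + rng.normal(0.0, sim.noise_sigma, size=movie.shape)
    movie = np.clip(movie, 0.0, None)
    return movie, motifs, onsets


# --------------------------------------------------------------------------
# scene I/O


def save_scene(scene: PhantomScene, directory: str | Path) -> None:
    """Write image.tiff, mask.png, labels.png, landmarks.csv, transform.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "image.tiff", scene.image.astype(np.float32))
    iio.imwrite(d / "mask.png", (scene.true_mask > 0).astype(np.uint8) * 255)
    iio.imwrite(d / "labels.png", scene.true_labels.astype(np.uint16))
    names = {dd.index: dd.name for dd in scene.landmark_defs}
    pd.DataFrame(
        {
            "index": np.arange(1, 10),
            "name": [names[i] for i in range(1, 10)],
            "row": scene.true_landmarks[:, 0],
            "col": scene.true_landmarks[:, 1],
            "confidence": np.ones(9),
        }
    ).to_csv(d / "landmarks.csv", index=False)
    with open(d / "transform.json", "w") as fh:
        json.dump({"matrix": scene.true_transform.matrix.ravel().tolist()}, fh)


def load_landmark_observations(path: str | Path) -> list[LandmarkObservation]:
    """Read landmark observations from CSV (index,name,row,col,confidence)."""
    df = pd.read_csv(path)
    return [
        LandmarkObservation(
            int(r["index"]), str(r["name"]), (float(r["row"]), float(r["col"])),
            float(r.get("confidence", 1.0)),
        )
        for _, r in df.iterrows()
    ]


def load_scene(directory: str | Path) -> dict:
    """Read back a saved scene as plain arrays/observations."""
    d = Path(directory)
    with open(d / "transform.json") as fh:
        mat = np.array(json.load(fh)["matrix"], dtype=float).reshape(2, 3)
    return {
        "image": tifffile.imread(d / "image.tiff").astype(float),
        "mask": (np.asarray(iio.imread(d / "mask.png")) > 0).astype(np.uint8),
        "labels": np.asarray(iio.imread(d / "labels.png")).astype(np.int64),
        "landmarks": load_landmark_observations(d / "landmarks.csv"),
        "transform": AffineMap2D(mat),
    }
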