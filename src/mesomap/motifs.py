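"""Functional maps: dF/F, sensory peak maps, and motif-based maps (MBFM).

Motif discovery uses convolutional non-negative matrix factorization with
multiplicative updates: the data matrix X (pixels x time) is approximated
by the sum over factors k of the spatio-temporal motif W_k (pixels x lag)
convolved with its temporal weighting h_k.  An optional cross-factor
orthogonality penalty discourages redundant factors that explain the
same data at nearby lags; its weight defaults to 0.  Motif images are per-motif maximum
temporal projections normalized to [0, 1], and a motif-based functional
map (MBFM) is the pointwise maximum projection of a set of normalized
motif images.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

__all__ = [
    "MotifSet",
    "SensoryMap",
    "MatchResult",
    "compute_dff",
    "stimulus_average",
    "peak_map",
    "convnmf",
    "factorize_movie",
    "motif_image",
    "epoch_split",
    "make_templates",
    "match_motifs",
    "mbfm_from_images",
]


@dataclasses.dataclass
class MotifSet:
    """Motifs and temporal weights from a convolutional factorization."""

    motifs: np.ndarray  # (K, L, H, W), nonnegative
    temporal_weights: np.ndarray  # (K, T), nonnegative
    penalty: float
    iterations: int
    error_trace: np.ndarray  # squared reconstruction error per iteration


@dataclasses.dataclass
class SensoryMap:
    """Stimulus-evoked activation map for one modality."""

    peak_map: np.ndarray
    peak_px: tuple[int, int]
    centroid_px: tuple[float, float]
    modality: str = ""


def compute_dff(movie: np.ndarray, baseline: slice | None = None) -> np.ndarray:
    """Relative fluorescence change (F - F0) / F0 with F0 the baseline mean.

    ``baseline`` selects the frames averaged into F0 (default: the whole
    recording, appropriate for spontaneous data; pass the pre-stimulus
    window for evoked data).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be T x H x W")
    baseline = baseline or slice(None)
    if movie[baseline].shape[0] == 0:
        raise ValueError("baseline window is empty")
    f0 = movie[baseline].mean(axis=0)
    bad = int(np.count_nonzero(f0 <= 0))
    if bad:
        raise ValueError(
            f"{bad} pixels have non-positive baseline F0; add a fluorescence "
            "offset before computing dF/F"
        )
    return (movie - f0) / f0


def stimulus_average(
    dff: np.ndarray, event_frames: Sequence[int], pre: int, post: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average (pre+post)-frame epochs around stimulus events.

    Returns ``(avg_epoch, trials)`` where trials has shape
    (n_events, pre+post, H, W); frame ``pre`` within the epoch is the
    stimulus frame.
    """
    dff = np.asarray(dff, dtype=float)
    t = dff.shape[0]
    bad = [int(e) for e in event_frames if e - pre < 0 or e + post > t]
    if bad:
        raise ValueError(f"epoch window exceeds movie bounds for events {bad}")
    trials = np.stack([dff[e - pre : e + post] for e in event_frames])
    return trials.mean(axis=0), trials


def peak_map(
    avg_epoch: np.ndarray,
    stim_frame_index: int,
    centroid_fraction: float = 0.75,
    modality: str = "",
) -> SensoryMap:
    """Per-pixel maximum dF/F over the frames strictly after the stimulus.

    ``peak_px`` is the argmax (ties -> smallest row, then smallest col);
    the centroid is the intensity-weighted centroid of pixels at or above
    ``centroid_fraction`` of the peak value.
    """
    epoch = np.asarray(avg_epoch, dtype=float)
    after = epoch[stim_frame_index + 1 :]
    if after.shape[0] == 0:
        raise ValueError("no frames after the stimulus index")
    pm = after.max(axis=0)
    peak = np.unravel_index(int(np.argmax(pm)), pm.shape)
    thr = centroid_fraction * pm.max()
    sel = pm >= thr
    wsum = pm[sel].sum()
    if wsum > 0:
        rr, cc = np.nonzero(sel)
        centroid = (
            float((rr * pm[sel]).sum() / wsum),
            float((cc * pm[sel]).sum() / wsum),
        )
    else:
        centroid = (float(peak[0]), float(peak[1]))
    return SensoryMap(pm, (int(peak[0]), int(peak[1])), centroid, modality)


# --------------------------------------------------------------------------
# convolutional NMF


def _shift(h: np.ndarray, lag: int) -> np.ndarray:
    """Shift rows of (K, T) right by ``lag`` frames, zero-padded."""
    if lag == 0:
        return h
    out = np.zeros_like(h)
    out[:, lag:] = h[:, : h.shape[1] - lag]
    return out


def _shift_back(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift columns of (N, T) left by ``lag`` frames, zero-padded."""
    if lag == 0:
        return x
    out = np.zeros_like(x)
    out[:, : x.shape[1] - lag] = x[:, lag:]
    return out


def _reconstruct(w: np.ndarray, h: np.ndarray) -> np.ndarray:
    """X_hat = sum_l W[:, :, l] @ shift(H, l); W is (N, K, L)."""
    n, k, L = w.shape
    xhat = np.zeros((n, h.shape[1]))
    for lag in range(L):
        xhat += w[:, :, lag] @ _shift(h, lag)
    return xhat


def _smooth_rows(a: np.ndarray, width: int) -> np.ndarray:
    """Convolve each row with a centered ones-kernel of the given width."""
    kern = np.ones(width)
    return np.apply_along_axis(lambda r: np.convolve(r, kern, mode="same"), 1, a)


def convnmf(
    x: np.ndarray,
    k: int,
    l: int,
    lam: float = 0.0,
    n_iter: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convolutional NMF by multiplicative updates.

    Factorizes a nonnegative (N_pixels, T) matrix into K motifs of lag
    length L.  ``lam`` weights the cross-factor orthogonality penalty
    that penalizes factors explaining the same data within +-L frames.
    Negative entries are clipped at zero with a warning.  Returns
    ``(W, H, error_trace)`` with W of shape (N, K, L), H of shape (K, T)
    and the squared-error objective recorded after every iteration.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.any(x < 0):
        warnings.warn("negative input entries clipped at 0 for convNMF")
        x = np.clip(x, 0.0, None)
    if k < 1 or l < 1:
        raise ValueError("K and L must be >= 1")
    n, t = x.shape
    if l >= t:
        raise ValueError("motif length L must be shorter than T")
    rng = np.random.default_rng(seed)
    xmax = x.max()
    if xmax == 0:
        return np.zeros((n, k, l)), np.zeros((k, t)), np.zeros(n_iter)
    w = rng.uniform(0.0, 1.0, size=(n, k, l)) * xmax / np.sqrt(l)
    h = rng.uniform(0.0, 1.0, size=(k, t)) / np.sqrt(t)
    eps = max(x.max(), 1.0) * 1e-10
    not_eye = 1.0 - np.eye(k)
    errs = np.empty(n_iter)
    for it in range(n_iter):
        xhat = _reconstruct(w, h)
        # H update
        num = np.zeros_like(h)
        den = np.zeros_like(h)
        for lag in range(l):
            wt = w[:, :, lag].T  # (K, N)
            num += wt @ _shift_back(x, lag)
            den += wt @ _shift_back(xhat, lag)
        if lam > 0:
            wtx = np.zeros_like(h)
            for lag in range(l):
                wtx += w[:, :, lag].T @ _shift_back(x, lag)
            den += lam * (not_eye @ _smooth_rows(wtx, 2 * l - 1))
        h *= num / (den + eps)
        # W update
        xhat = _reconstruct(w, h)
        if lam > 0:
            sh = _smooth_rows(h, 2 * l - 1)
        for lag in range(l):
            hs = _shift(h, lag)
            num_w = x @ hs.T
            den_w = xhat @ hs.T
            if lam > 0:
                den_w = den_w + lam * (x @ _shift(sh, lag).T) @ not_eye
            w[:, :, lag] *= num_w / (den_w + eps)
        xhat = _reconstruct(w, h)
        errs[it] = float(np.sum((x - xhat) ** 2))
    return w, h, errs


def factorize_movie(
    movie: np.ndarray,
    mask: np.ndarray,
    k: int,
    l: int,
    lam: float = 0.0,
    n_iter: int = 100,
    seed: int = 0,
) -> MotifSet:
    """Run convNMF on the masked pixels of a T x H x W movie."""
    movie = np.asarray(movie, dtype=float)
    mask = np.asarray(mask).astype(bool)
    t = movie.shape[0]
    x = movie[:, mask].T  # (N_pixels, T)
    w, h, errs = convnmf(x, k, l, lam=lam, n_iter=n_iter, seed=seed)
    motifs = np.zeros((k, l, *mask.shape))
    for kk in range(k):
        motifs[kk][:, mask] = w[:, kk, :].T
    return MotifSet(motifs, h, lam, n_iter, errs)


def motif_image(motif: np.ndarray, brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Maximum temporal projection of an (L, H, W) motif, normalized to [0, 1].

    Pixels outside the brain mask are zeroed before normalization; an
    all-zero motif maps to an all-zero image (no division).
    """
    m = np.asarray(motif, dtype=float).max(axis=0)
    if brain_mask is not None:
        m = np.where(np.asarray(brain_mask).astype(bool), m, 0.0)
    lo, hi = m.min(), m.max()
    if hi <= lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def mbfm_from_images(motif_images: Sequence[np.ndarray]) -> np.ndarray:
    """Motif-based functional map: pointwise max of normalized motif images."""
    if not len(motif_images):
        raise ValueError("no motif images")
    return np.max(np.stack(motif_images), axis=0)


def epoch_split(
    dff: np.ndarray, epoch_minutes: float, frame_rate: float
) -> list[np.ndarray]:
    """Split a recording into consecutive fixed-length epochs.

    A trailing remainder shorter than one epoch is dropped with a warning.
    """
    dff = np.asarray(dff)
    frames = int(round(epoch_minutes * 60.0 * frame_rate))
    if frames < 1:
        raise ValueError("epoch shorter than one frame")
    n = dff.shape[0] // frames
    if n == 0:
        raise ValueError("recording shorter than one epoch")
    if dff.shape[0] % frames:
        warnings.warn(
            f"dropping {dff.shape[0] % frames} trailing frames (< 1 epoch)"
        )
    return [dff[i * frames : (i + 1) * frames] for i in range(n)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def make_templates(
    motif_images: Sequence[np.ndarray],
    cluster_labels: Sequence[int],
    n_templates: int = 6,
    center_quantile: float = 0.5,
    mask: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Template motifs from clustered motif images, plus the template MBFM.

    Within each cluster the "center motifs" — members whose mean
    correlation to the rest of the cluster is at or above the
    ``center_quantile`` quantile — are averaged into one template.
    Clusters are ranked by member count and the ``n_templates`` most
    common kept; the template MBFM is their maximum projection.
    """
    labels = np.asarray(cluster_labels)
    if len(labels) != len(motif_images):
        raise ValueError("labels must cover all motif images")
    images = [np.asarray(m, dtype=float) for m in motif_images]
    sel = (lambda im: im[mask.astype(bool)]) if mask is not None else (lambda im: im.ravel())
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    if len(order) < n_templates:
        warnings.warn(
            f"only {len(order)} clusters available for {n_templates} templates"
        )
    templates: list[np.ndarray] = []
    for lab in order[:n_templates]:
        members = [images[i] for i in np.nonzero(labels == lab)[0]]
        if not members:
            continue
        if len(members) == 1:
            templates.append(members[0])
            continue
        vecs = np.stack([sel(m) for m in members])
        r = np.corrcoef(vecs)
        np.fill_diagonal(r, np.nan)
        mean_r = np.nanmean(r, axis=1)
        cut = np.quantile(mean_r, center_quantile)
        central = [m for m, mr in zip(members, mean_r) if mr >= cut]
        templates.append(np.mean(central, axis=0))
    return templates, mbfm_from_images(templates)


@dataclasses.dataclass
class MatchResult:
    """Assignment of new motifs to template motifs by correlation."""

    assignment: np.ndarray  # per-motif template index, -1 = unassigned
    r_matrix: np.ndarray  # (n_new, n_templates) Pearson correlations
    matched_means: dict[int, np.ndarray]  # template index -> averaged image
    mbfm: np.ndarray


def match_motifs(
    new_motifs: Sequence[np.ndarray],
    templates: Sequence[np.ndarray],
    r_threshold: float = 0.5,
    mask: np.ndarray | None = None,
) -> MatchResult:
    """Match new motif images to templates by Pearson correlation.

    Each new motif is assigned to its best-correlated template iff
    r >= r_threshold (ties -> lower template index); zero-variance images
    are left unassigned with a warning.  Matched motifs are averaged per
    template and the new MBFM is the maximum projection of the averages.
    """
    if not len(templates):
        raise ValueError("templates must be nonempty")
    if not -1.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be in (-1, 1)")
    sel = (lambda im: im[mask.astype(bool)]) if mask is not None else (lambda im: im.ravel())
    r = np.full((len(new_motifs), len(templates)), np.nan)
    for i, m in enumerate(new_motifs):
        for j, t in enumerate(templates):
            r[i, j] = _pearson(sel(np.asarray(m, float)), sel(np.asarray(t, float)))
    assignment = np.full(len(new_motifs), -1, dtype=int)
    for i in range(len(new_motifs)):
        row = r[i]
        if np.all(np.isnan(row)):
            warnings.warn(f"motif {i} has zero variance; left unassigned")
            continue
        j = int(np.nanargmax(row))  # first (lowest-index) maximizer on ties
        if row[j] >= r_threshold:
            assignment[i] = j
    matched_means: dict[int, np.ndarray] = {}
    for j in range(len(templates)):
        members = [np.asarray(new_motifs[i], float) for i in np.nonzero(assignment == j)[0]]
        if members:
            matched_means[j] = np.mean(members, axis=0)
    if matched_means:
        mbfm = mbfm_from_images(list(matched_means.values()))
    else:
        mbfm = np.zeros_like(np.asarray(templates[0], dtype=float))
    return MatchResult(assignment, r, matched_means, mbfm)
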