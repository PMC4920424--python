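"""Local descriptors around refined Harris corner points (415 elements).

Elytra unit patterns (holes, hairs, reticulation cells) concentrate
structure at corner-like interest points.  Harris corners are detected,
thinned by a density-rejection and merging procedure, and a 101x101 window
centred at each surviving point is described on the colour-gradient edge
image: a 5x5 grid of 20x20 cells, each contributing its mean, variance and
7-point-interpolated row/column projection profiles (16 values per cell),
plus a 15-bin RGB histogram of the window (5 bins per channel).  The
fragment's local feature vector is the element-wise mean of its per-point
window descriptors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import trim_mean
from skimage import feature, filters, morphology

from .features_global import _as_rgb, _channel_histogram, to_gray

N_GRID_CELLS = 25
N_PER_CELL = 16
N_WINDOW_COLOR = 15
N_LOCAL = N_GRID_CELLS * N_PER_CELL + N_WINDOW_COLOR  # 415

LOCAL_NAMES = (
    [f"loc_r{i}c{j}_{part}"
     for i in range(5) for j in range(5)
     for part in (["mean", "var"]
                  + [f"vp{k}" for k in range(1, 8)]
                  + [f"hp{k}" for k in range(1, 8)])]
    + [f"loc_col_{ch}{b}" for ch in "RGB" for b in range(1, 6)]
)
assert len(LOCAL_NAMES) == N_LOCAL


def detect_corners(gray: np.ndarray, k: float = 0.04,
                   rel_threshold: float = 1e-4,
                   min_distance: int = 3) -> np.ndarray:
    """Harris corner points as an (n, 2) array of row/col coordinates.

    Points are local maxima of the Harris response exceeding
    ``rel_threshold`` times the maximum response; a constant image has no
    structure and yields an empty array.
    """
    g = np.asarray(gray, dtype=float)
    if g.size == 0:
        raise ValueError("empty image")
    resp = feature.corner_harris(g, k=k)
    if resp.max() <= 0:
        return np.empty((0, 2), dtype=int)
    return feature.corner_peaks(resp, min_distance=min_distance,
                                threshold_rel=rel_threshold)


def refine_points(
    points: np.ndarray,
    shape: tuple[int, int],
    merge_dist: float = 15.0,
    dilate_radius: int = 4,
    tile: tuple[int, int] = (101, 101),
    trim: float = 0.25,
    cap_factor: float = 2.0,
) -> np.ndarray:
    """Reject noise-dense points and merge adjacent ones.

    Density rejection first: the image is tiled, per-tile point counts are
    collected over occupied tiles, and points in tiles whose count exceeds
    ``cap_factor`` times the 25%-truncated mean of those counts are dropped
    (dense false corners arise in local peak-noise areas).  Survivors are
    then dilated with a disk of radius ``dilate_radius``; centroids of the
    resulting connected components are iteratively merged while any pair is
    closer than ``merge_dist``.  The output centroids are pairwise at least
    ``merge_dist`` apart.
    """
    pts = np.asarray(points, dtype=int).reshape(-1, 2)
    if pts.shape[0] == 0:
        return np.empty((0, 2), dtype=int)
    h, w = shape

    tiles = (pts[:, 0] // tile[0]) * ((w // tile[1]) + 1) + (pts[:, 1] // tile[1])
    uniq, inverse, counts = np.unique(tiles, return_inverse=True, return_counts=True)
    cap = cap_factor * trim_mean(counts.astype(float), trim)
    keep = counts[inverse] <= cap
    pts = pts[keep]
    if pts.shape[0] == 0:
        return np.empty((0, 2), dtype=int)

    canvas = np.zeros((h, w), dtype=bool)
    canvas[pts[:, 0], pts[:, 1]] = True
    dilated = morphology.dilation(canvas, morphology.disk(dilate_radius))
    labels, n = ndimage.label(dilated, structure=np.ones((3, 3), dtype=int))
    centroids = np.asarray(ndimage.center_of_mass(dilated, labels, range(1, n + 1)),
                           dtype=float).reshape(-1, 2)

    # agglomerate centroids until every pair is >= merge_dist apart
    while centroids.shape[0] > 1:
        d = squareform(pdist(centroids))
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= merge_dist:
            break
        merged = centroids[[i, j]].mean(axis=0)
        centroids = np.vstack([np.delete(centroids, [i, j], axis=0), merged])

    out = np.rint(centroids).astype(int)
    out[:, 0] = np.clip(out[:, 0], 0, h - 1)
    out[:, 1] = np.clip(out[:, 1], 0, w - 1)
    return out


def color_gradient_edges(rgb: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Colour-gradient edge magnitude.

    Horizontal and vertical Sobel derivatives are taken per RGB channel and
    the magnitude is the Euclidean norm over all six channel derivatives;
    by default the map is rescaled to [0, 255].
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")
    sq = np.zeros(arr.shape[:2])
    for ch in range(3):
        sq += filters.sobel_h(arr[..., ch]) ** 2
        sq += filters.sobel_v(arr[..., ch]) ** 2
    mag = np.sqrt(sq)
    if rescale and mag.max() > 0:
        mag = mag * (255.0 / mag.max())
    return mag


def _extract_window(img: np.ndarray, p: tuple[int, int], window: int,
                    pad_mode: str) -> np.ndarray:
    half = window // 2
    r, c = int(p[0]), int(p[1])
    h, w = img.shape[:2]
    pr0, pc0 = max(0, half - r), max(0, half - c)
    pr1 = max(0, r + half + 1 - h)
    pc1 = max(0, c + half + 1 - w)
    view = img[max(0, r - half):min(h, r + half + 1),
               max(0, c - half):min(w, c + half + 1)]
    if pr0 or pr1 or pc0 or pc1:
        pads = ((pr0, pr1), (pc0, pc1)) + (((0, 0),) if img.ndim == 3 else ())
        view = np.pad(view, pads, mode=pad_mode)
    return view


def _interp7(profiles: np.ndarray) -> np.ndarray:
    """Linear interpolation of 20-sample profiles at 7 equally spaced nodes."""
    xi = np.linspace(0.0, profiles.shape[-1] - 1, 7)
    i0 = np.minimum(np.floor(xi).astype(int), profiles.shape[-1] - 2)
    frac = xi - i0
    return profiles[..., i0] * (1.0 - frac) + profiles[..., i0 + 1] * frac


def window_descriptor(edges: np.ndarray, rgb: np.ndarray, p,
                      window: int = 101, grid: tuple[int, int] = (5, 5),
                      pad_mode: str = "reflect") -> np.ndarray:
    """415-element descriptor of one interest-point window.

    The central 100x100 of the 101x101 edge window (the last row and column
    are dropped so cells are exactly 20x20) is split into a 5x5 grid; each
    cell contributes its mean, population variance and its row-sum and
    column-sum profiles linearly interpolated at 7 equally spaced positions.
    The window's RGB histogram (5 bins per channel, per-channel normalized)
    closes the vector.  Windows overhanging the image border are
    reflect-padded.
    """
    ewin = _extract_window(np.asarray(edges, dtype=float), p, window, pad_mode)
    rwin = _extract_window(np.asarray(rgb), p, window, pad_mode)
    gr, gc = grid
    ch, cw = (window - 1) // gr, (window - 1) // gc
    core = ewin[:gr * ch, :gc * cw]
    cells = core.reshape(gr, ch, gc, cw).swapaxes(1, 2)  # (gr, gc, ch, cw)

    mean = cells.mean(axis=(-2, -1))
    var = cells.var(axis=(-2, -1))
    row_prof = cells.sum(axis=-1)   # (gr, gc, ch): per-row sums
    col_prof = cells.sum(axis=-2)   # (gr, gc, cw): per-column sums
    vp = _interp7(row_prof)
    hp = _interp7(col_prof)

    per_cell = np.concatenate([
        mean[..., None], var[..., None], vp, hp], axis=-1)  # (gr, gc, 16)
    color = np.concatenate([
        _channel_histogram(rwin[..., chn].ravel(), 5) for chn in range(3)
    ])
    return np.concatenate([per_cell.reshape(-1), color])


def local_features(fragment, window: int = 101, k: float = 0.04,
                   rel_threshold: float = 1e-4, merge_dist: float = 15.0,
                   dilate_radius: int = 4, pad_mode: str = "reflect",
                   return_points: bool = False):
    """Mean window descriptor over all refined feature points of a fragment.

    Returns a named pandas Series of length 415 plus ``n_points``; with no
    refined points the vector is all zeros and a warning is emitted.
    """
    rgb = _as_rgb(fragment)
    gray = to_gray(rgb)
    pts = detect_corners(gray, k=k, rel_threshold=rel_threshold)
    pts = refine_points(pts, gray.shape, merge_dist=merge_dist,
                        dilate_radius=dilate_radius)
    if pts.shape[0] == 0:
        warnings.warn("no refined feature points; local feature vector is zero",
                      UserWarning, stacklevel=2)
        vec = np.zeros(N_LOCAL)
    else:
        edges = color_gradient_edges(rgb)
        descs = np.stack([
            window_descriptor(edges, rgb, p, window=window, pad_mode=pad_mode)
            for p in pts
        ])
        vec = descs.mean(axis=0)
    out = pd.Series(vec, index=LOCAL_NAMES)
    out["n_points"] = float(pts.shape[0])
    if return_points:
        return out, pts
    return out


class LocalFeatureExtractor:
    """Sklearn-style transformer mapping fragments to the 415-column matrix."""

    def __init__(self, window: int = 101, k: float = 0.04,
                 rel_threshold: float = 1e-4, merge_dist: float = 15.0,
                 dilate_radius: int = 4, pad_mode: str = "reflect"):
        self.window = window
        self.k = k
        self.rel_threshold = rel_threshold
        self.merge_dist = merge_dist
        self.dilate_radius = dilate_radius
        self.pad_mode = pad_mode

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("window", "k", "rel_threshold", "merge_dist",
                 "dilate_radius", "pad_mode")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        self.feature_names_out_ = list(LOCAL_NAMES) + ["n_points"]
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [local_features(frag, window=self.window, k=self.k,
                               rel_threshold=self.rel_threshold,
                               merge_dist=self.merge_dist,
                               dilate_radius=self.dilate_radius,
                               pad_mode=self.pad_mode)
                for frag in X]
        return pd.DataFrame(rows).reset_index(drop=True)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
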