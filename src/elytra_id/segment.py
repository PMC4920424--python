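"""Elytron segmentation and fragment simulation.

Two complementary binary masks are computed: one from peak-valley analysis
of the smoothed intensity histogram, one from RGB distance to a reference
colour sampled at the image centre (the elytron is centred by acquisition).
Each mask is hole-filled and opened, then the two are intersected.  Random
fragment subimages are sampled within the segmented region to emulate the
broken elytra fragments recovered from processed food.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

logger = logging.getLogger(__name__)


@dataclass
class ColorReference:
    """Reference colour for the colour-distance mask.

    ``roi`` is the centred (2% of H) x (2% of W) rectangle as slices;
    ``reference_vector`` the bin-averaged RGB triplet over that region;
    ``distance_threshold`` the accepted Euclidean RGB distance.
    """

    roi: tuple[slice, slice]
    reference_vector: np.ndarray
    distance_threshold: float


@dataclass
class FragmentImage:
    """A simulated fragment: an RGB crop plus provenance."""

    pixels: np.ndarray
    crop_rect: tuple[int, int, int, int]  # (row, col, height, width), half-open
    source_specimen_id: str | None = None
    species_index: int | None = None


def _center_roi(shape: tuple[int, int], fraction: float = 0.02) -> tuple[slice, slice]:
    h, w = shape[:2]
    rh = max(1, int(round(h * fraction)))
    rw = max(1, int(round(w * fraction)))
    r0 = (h - rh) // 2
    c0 = (w - rw) // 2
    return slice(r0, r0 + rh), slice(c0, c0 + rw)


def make_color_reference(
    rgb: np.ndarray,
    distance_threshold: float = 60.0,
    roi_fraction: float = 0.02,
    bins: int = 10,
) -> ColorReference:
    """Build the reference vector from the central region of interest.

    The per-channel reference value is the bin-weighted mean of the ROI
    histogram (``bins`` bins over [0, 256)).
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    roi = _center_roi(rgb.shape, roi_fraction)
    patch = rgb[roi].reshape(-1, 3).astype(float)
    edges = np.linspace(0, 256, bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    ref = np.empty(3)
    for ch in range(3):
        hist, _ = np.histogram(patch[:, ch], bins=edges)
        ref[ch] = (hist * centers).sum() / max(hist.sum(), 1)
    return ColorReference(roi=roi, reference_vector=ref, distance_threshold=distance_threshold)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima of a 1-D array."""
    if y.size < 3:
        return np.empty(0, dtype=int)
    inner = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    return np.flatnonzero(inner) + 1


def histogram_mask(gray: np.ndarray, foreground_reference: float | None = None) -> np.ndarray:
    """Foreground mask from histogram peak-valley analysis.

    The 256-bin histogram is smoothed by a 1-D Gaussian whose variance is
    the mean spacing of adjacent strict local maxima of the raw histogram.
    The threshold is the minimum-valued valley strictly between the two
    highest smoothed peaks.  The foreground side of the threshold is the
    peak closer to ``foreground_reference`` (defaulting to the mean
    intensity of the centred 2% x 2% region, consistent with the
    colour-reference assumption that the elytron is centred).

    Falls back to Otsu with a warning when the smoothed histogram is
    unimodal; a constant image yields an all-foreground mask.
    """
    g = np.asarray(gray, dtype=float)
    vals = np.clip(np.rint(g), 0, 255).astype(int)
    hist = np.bincount(vals.ravel(), minlength=256).astype(float)

    if foreground_reference is None:
        roi = _center_roi(g.shape)
        foreground_reference = float(g[roi].mean())

    raw_peaks = _local_maxima(hist)
    if raw_peaks.size >= 2:
        variance = float(np.diff(raw_peaks).mean())
    else:
        variance = 4.0
    sigma = math.sqrt(max(variance, 1e-6))
    smoothed = ndimage.gaussian_filter1d(hist, sigma)

    peaks = _local_maxima(smoothed)
    threshold = None
    if peaks.size >= 2:
        order = peaks[np.argsort(smoothed[peaks])[::-1]]
        p1 = order[0]
        # second peak: highest maximum at least 2*sigma bins from the first,
        # guarding against twin sub-peaks of a single noisy mode
        far = order[np.abs(order - p1) > 2 * sigma]
        if far.size:
            p2 = far[0]
            lo, hi = sorted((p1, p2))
            valley = lo + 1 + int(np.argmin(smoothed[lo + 1:hi]))
            threshold = float(valley)
    if threshold is None:
        warnings.warn("unimodal smoothed histogram; falling back to Otsu threshold",
                      UserWarning, stacklevel=2)
        if vals.min() == vals.max():
            return np.ones(g.shape, dtype=bool)
        threshold = float(filters.threshold_otsu(vals))

    if foreground_reference > threshold:
        return g > threshold
    return g <= threshold


def color_mask(rgb: np.ndarray, ref: ColorReference) -> np.ndarray:
    """Pixels whose Euclidean RGB distance to the reference is within threshold."""
    diff = rgb.astype(float) - ref.reference_vector
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return dist <= ref.distance_threshold


def clean_mask(mask: np.ndarray, opening_radius: int = 5) -> np.ndarray:
    """Fill background-enclosed holes, then open with a disk."""
    filled = ndimage.binary_fill_holes(mask)
    return morphology.opening(filled, morphology.disk(opening_radius))


def merge_masks(m1: np.ndarray, m2: np.ndarray, opening_radius: int = 5) -> np.ndarray:
    """Clean both masks (fill then open) and intersect them.

    The result is a subset of each cleaned input.
    """
    if m1.shape != m2.shape:
        raise ValueError("masks must share a shape")
    return clean_mask(m1, opening_radius) & clean_mask(m2, opening_radius)


def segment_elytron(rgb: np.ndarray, gray: np.ndarray | None = None,
                    distance_threshold: float = 60.0,
                    opening_radius: int = 5) -> np.ndarray:
    """Full segmentation: histogram mask AND colour mask, cleaned.

    The colour reference comes from the centred region of interest, which
    can occasionally land on a dark pattern object (a hole or groove)
    rather than the cuticle base colour; the resulting colour mask then
    keeps only pattern objects.  When the intersection would discard more
    than half of the cleaned histogram mask, the colour reference is
    deemed unrepresentative and the cleaned histogram mask alone is
    returned, with a warning.
    """
    if gray is None:
        gray = rgb @ np.array([0.2125, 0.7154, 0.0721])
    ref = make_color_reference(rgb, distance_threshold)
    m1 = histogram_mask(gray, foreground_reference=float(ref.reference_vector.mean()))
    m2 = color_mask(rgb, ref)
    merged = merge_masks(m1, m2, opening_radius)
    m1_clean = clean_mask(m1, opening_radius)
    if merged.sum() < 0.5 * m1_clean.sum():
        warnings.warn("colour mask discards most of the histogram mask; "
                      "using the histogram mask alone", UserWarning, stacklevel=2)
        return m1_clean
    return merged


def _clip_range(size_range: tuple[int, int], dim: int) -> tuple[int, int]:
    lo, hi = size_range
    clo, chi = min(lo, dim), min(hi, dim)
    if (clo, chi) != (lo, hi):
        logger.info("fragment size range %s clipped to %s for image dimension %d",
                    size_range, (clo, chi), dim)
    return clo, chi


def simulate_fragments(
    img: np.ndarray,
    mask: np.ndarray,
    n: int = 100,
    size_range: tuple[int, int] = (300, 2500),
    min_fg_fraction: float = 0.8,
    seed: int = 0,
    max_tries: int = 10_000,
    source_specimen_id: str | None = None,
    species_index: int | None = None,
) -> list[FragmentImage]:
    """Sample ``n`` random fragment rectangles within the elytron region.

    Widths and heights are uniform on ``size_range`` clipped to the image
    dimensions; a rectangle is accepted when at least ``min_fg_fraction``
    of its pixels are foreground.  Deterministic per seed.  Fragments hold
    views into ``img`` (no pixel copies).
    """
    h, w = mask.shape
    rng = np.random.default_rng(seed)
    h_lo, h_hi = _clip_range(size_range, h)
    w_lo, w_hi = _clip_range(size_range, w)
    integral = np.pad(mask.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    fragments: list[FragmentImage] = []
    for _ in range(n):
        for attempt in range(max_tries):
            fh = int(rng.integers(h_lo, h_hi + 1))
            fw = int(rng.integers(w_lo, w_hi + 1))
            r = int(rng.integers(0, h - fh + 1))
            c = int(rng.integers(0, w - fw + 1))
            fg = (integral[r + fh, c + fw] - integral[r, c + fw]
                  - integral[r + fh, c] + integral[r, c])
            if fg / (fh * fw) >= min_fg_fraction:
                fragments.append(FragmentImage(
                    pixels=img[r:r + fh, c:c + fw],
                    crop_rect=(r, c, fh, fw),
                    source_specimen_id=source_specimen_id,
                    species_index=species_index,
                ))
                break
        else:
            raise RuntimeError(
                f"could not place a fragment with foreground fraction >= "
                f"{min_fg_fraction} and sizes {size_range} within {max_tries} tries")
    return fragments
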