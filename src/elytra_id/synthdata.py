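"""Seeded synthetic elytra specimen images with ground truth.

Beetle elytra (hardened forewings) imaged under a stereo microscope show an
elliptical cuticle region on a plain background, a species-specific base
colour, and one or more of four recurring surface pattern categories: short
hairs (setae), holes/grooves (punctures), long longitudinal lines (striae),
and tiled unit shapes (reticulation).  Depth-sensitive microscopy adds
curvature-induced defocus toward the elytron border, specular salt noise and
per-image contrast bias.  This module renders such scenes deterministically
from a seed, together with the true foreground mask and the centres of every
drawn pattern object, so the downstream segmentation, descriptor and
classification stages can be tested against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

PATTERN_TYPES = ("hair", "hole", "line", "unit_shape")


@dataclass(frozen=True)
class SpeciesSpec:
    """Generative parameters for one species' elytron appearance.

    Parameters
    ----------
    species_index : int
        Class label (1-based in the reference collection).
    base_color : tuple of int
        Mean cuticle RGB colour, each channel in [0, 255].
    pattern_types : tuple of str
        Subset of :data:`PATTERN_TYPES`.  Two species may share pattern
        types (same-genus look-alikes) and differ only in colour or in the
        density/size statistics below.
    object_density : float
        Expected pattern objects per megapixel of elytron area.
    object_size_px : (int, int)
        Min/max characteristic object size in pixels.
    line_orientation_deg : float
        Dominant orientation of hair/line patterns, degrees from the
        image column axis.
    pattern_period_px : float
        Grid spacing of periodic unit shapes.
    color_jitter : tuple of float
        Per-channel standard deviation of the smooth colour variation.
    """

    species_index: int
    base_color: tuple[int, int, int]
    pattern_types: tuple[str, ...]
    object_density: float = 40.0
    object_size_px: tuple[int, int] = (6, 14)
    line_orientation_deg: float = 0.0
    pattern_period_px: float = 48.0
    color_jitter: tuple[float, float, float] = (6.0, 6.0, 6.0)

    def __post_init__(self) -> None:
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color components must lie in [0, 255]")
        unknown = set(self.pattern_types) - set(PATTERN_TYPES)
        if unknown:
            raise ValueError(f"unknown pattern types: {sorted(unknown)}")
        if self.object_density < 0:
            raise ValueError("object_density must be >= 0")
        lo, hi = self.object_size_px
        if lo > hi or lo < 1:
            raise ValueError("object_size_px must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class SceneSpec:
    """Canvas, elytron ellipse and image-degradation parameters.

    ``ellipse_axes`` are the semi-axes (rows, cols); the ellipse must lie
    fully inside the canvas.  ``blur_sigma_range`` gives the local defocus
    sigma from the elytron centre (min) to its border (max), emulating
    curvature-induced blur.  ``salt_noise_rate`` is the fraction of pixels
    set to saturated white, and ``contrast_bias`` the range of the
    per-image multiplicative gain.
    """

    canvas_size: tuple[int, int] = (1200, 1600)
    background_color: tuple[int, int, int] = (235, 233, 228)
    ellipse_center: tuple[float, float] = (600.0, 800.0)
    ellipse_axes: tuple[float, float] = (520.0, 720.0)
    ellipse_rotation_deg: float = 0.0
    blur_sigma_range: tuple[float, float] = (0.4, 2.5)
    salt_noise_rate: float = 0.002
    contrast_bias: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.salt_noise_rate <= 1.0:
            raise ValueError("salt_noise_rate must lie in [0, 1]")
        h, w = self.canvas_size
        cr, cc = self.ellipse_center
        ar, ac = self.ellipse_axes
        phi = math.radians(self.ellipse_rotation_deg)
        ext_r = math.hypot(ar * math.cos(phi), ac * math.sin(phi))
        ext_c = math.hypot(ar * math.sin(phi), ac * math.cos(phi))
        if cr - ext_r < 0 or cr + ext_r > h - 1 or cc - ext_c < 0 or cc + ext_c > w - 1:
            raise ValueError("elytron ellipse must lie fully inside the canvas")


@dataclass
class SpecimenCollection:
    """A rendered collection: manifest plus in-memory rasters."""

    manifest: pd.DataFrame  # columns: path, species_index, specimen_id, seed
    images: list[np.ndarray] = field(default_factory=list)
    masks: list[np.ndarray] = field(default_factory=list)
    centers: list[np.ndarray] = field(default_factory=list)


def _ellipse_mask(scene: SceneSpec) -> np.ndarray:
    h, w = scene.canvas_size
    rr, cc = np.mgrid[0:h, 0:w]
    cr, cc0 = scene.ellipse_center
    ar, ac = scene.ellipse_axes
    phi = math.radians(scene.ellipse_rotation_deg)
    dr = rr - cr
    dc = cc - cc0
    u = dr * math.cos(phi) + dc * math.sin(phi)
    v = -dr * math.sin(phi) + dc * math.cos(phi)
    return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0


def _sample_center(rng: np.random.Generator, scene: SceneSpec) -> tuple[float, float]:
    """Uniform point inside the (slightly shrunk) elytron ellipse."""
    t = rng.uniform(0.0, 2.0 * math.pi)
    rad = math.sqrt(rng.uniform()) * 0.96
    ar, ac = scene.ellipse_axes
    u = ar * rad * math.cos(t)
    v = ac * rad * math.sin(t)
    phi = math.radians(scene.ellipse_rotation_deg)
    dr = u * math.cos(phi) - v * math.sin(phi)
    dc = u * math.sin(phi) + v * math.cos(phi)
    return scene.ellipse_center[0] + dr, scene.ellipse_center[1] + dc


def _blend_aa(img: np.ndarray, rr, cc, val, color) -> None:
    h, w = img.shape[:2]
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc, val = rr[ok], cc[ok], val[ok]
    img[rr, cc] = img[rr, cc] * (1.0 - val[:, None]) + np.asarray(color, float) * val[:, None]


def _draw_segment(img, r0, c0, r1, c1, color, thickness=1) -> None:
    # anti-aliased segment; thickness realised by parallel offsets
    length = math.hypot(r1 - r0, c1 - c0)
    if length == 0:
        return
    nr, nc = (c1 - c0) / length, -(r1 - r0) / length  # unit normal
    for t in range(thickness):
        off = t - (thickness - 1) / 2.0
        rr, cc, val = draw.line_aa(
            int(round(r0 + off * nr)), int(round(c0 + off * nc)),
            int(round(r1 + off * nr)), int(round(c1 + off * nc)))
        _blend_aa(img, rr, cc, val.astype(float), color)


def _draw_object(img, rng, kind, center, species: SpeciesSpec) -> None:
    r, c = center
    lo, hi = species.object_size_px
    size = float(rng.uniform(lo, hi))
    base = np.asarray(species.base_color, float)
    if kind == "hole":
        color = base * 0.35
        rr, cc = draw.disk((r, c), max(size / 2.0, 1.0), shape=img.shape[:2])
        img[rr, cc] = color
    elif kind == "hair":
        color = base * 0.45
        ang = math.radians(species.line_orientation_deg + rng.normal(0.0, 8.0))
        half = size  # hairs ~ 2x the characteristic size
        dr, dc = -math.sin(ang) * half, math.cos(ang) * half
        _draw_segment(img, r - dr, c - dc, r + dr, c + dc, color, thickness=1)
    elif kind == "line":
        color = base * 0.5
        ang = math.radians(species.line_orientation_deg + rng.normal(0.0, 2.0))
        half = size * 3.0
        dr, dc = -math.sin(ang) * half, math.cos(ang) * half
        _draw_segment(img, r - dr, c - dc, r + dr, c + dc, color, thickness=2)
    elif kind == "unit_shape":
        color = base * 0.55
        half = max(size / 2.0, 1.0)
        if rng.uniform() < 0.5:
            rr, cc = draw.disk((r, c), half, shape=img.shape[:2])
        else:
            rr, cc = draw.rectangle(
                (int(r - half), int(c - half)), extent=(int(2 * half), int(2 * half)),
                shape=img.shape[:2])
            rr, cc = rr.astype(int), cc.astype(int)
        img[rr, cc] = color
    else:  # pragma: no cover - guarded by SpeciesSpec validation
        raise ValueError(f"unknown pattern kind {kind!r}")


def render_specimen(
    species: SpeciesSpec,
    scene: SceneSpec,
    seed: int,
    n_objects: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one specimen image.

    Returns
    -------
    image : (H, W, 3) uint8
    mask : (H, W) bool
        True foreground (elytron) mask.
    centers : (n, 2) int
        Row/col centres of the drawn pattern objects, all inside ``mask``.

    Rendering is bit-exact deterministic for fixed arguments.  The number
    of objects is Poisson around ``object_density`` times the elytron area
    in megapixels unless ``n_objects`` forces an exact count.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.canvas_size
    mask = _ellipse_mask(scene)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(scene.background_color, float)
    base = np.asarray(species.base_color, float)
    # smooth per-channel colour variation over the cuticle
    for ch in range(3):
        noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 4.0)
        sd = noise.std()
        if sd > 0:
            noise *= species.color_jitter[ch] / sd
        img[..., ch][mask] = base[ch] + noise[mask]

    area_mp = mask.sum() / 1e6
    n = int(n_objects) if n_objects is not None else int(rng.poisson(species.object_density * area_mp))
    centers = []
    for _ in range(n):
        kind = species.pattern_types[rng.integers(len(species.pattern_types))] \
            if species.pattern_types else None
        if kind is None:
            break
        for _try in range(100):
            r, c = _sample_center(rng, scene)
            if kind == "unit_shape":
                q = species.pattern_period_px
                r, c = round(r / q) * q, round(c / q) * q
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < h and 0 <= ci < w and mask[ri, ci]:
                _draw_object(img, rng, kind, (r, c), species)
                centers.append((ri, ci))
                break
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)

    # curvature defocus: sharp at the elytron centre, blurred at its border
    s_lo, s_hi = scene.blur_sigma_range
    dist = ndimage.distance_transform_edt(mask)
    dmax = dist.max()
    wgt = (dist / dmax)[..., None] if dmax > 0 else np.zeros((h, w, 1))
    sharp = ndimage.gaussian_filter(img, (s_lo, s_lo, 0.0))
    blurred = ndimage.gaussian_filter(img, (s_hi, s_hi, 0.0))
    img = wgt * sharp + (1.0 - wgt) * blurred

    k = int(round(scene.salt_noise_rate * h * w))
    if k:
        flat = rng.choice(h * w, size=k, replace=False)
        img.reshape(-1, 3)[flat] = 255.0

    img *= rng.uniform(*scene.contrast_bias)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask, centers


def make_collection(
    specs: Sequence[SpeciesSpec],
    specimens_per_species: Sequence[int],
    scene: SceneSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SpecimenCollection:
    """Render a specimen collection and build its manifest.

    One image per specimen; specimen ids are unique and species counts match
    the request.  If ``out_dir`` is given, images and truth masks are written
    as PNG under ``images/`` and ``masks/`` and the manifest as
    ``manifest.csv`` with header ``path,species_index,specimen_id,seed``.
    """
    if scene is None:
        scene = SceneSpec()
    if len(specs) != len(specimens_per_species):
        raise ValueError("specs and specimens_per_species must be aligned")
    if any(c < 1 for c in specimens_per_species):
        raise ValueError("every species needs at least one specimen")

    rows = []
    coll = SpecimenCollection(manifest=pd.DataFrame())
    for spec, count in zip(specs, specimens_per_species):
        for j in range(count):
            child = np.random.SeedSequence([int(seed), int(spec.species_index), j])
            child_seed = int(child.generate_state(1)[0] % (2**31))
            img, mask, centers = render_specimen(spec, scene, child_seed)
            specimen_id = f"s{spec.species_index:02d}_{j + 1:02d}"
            rows.append({
                "path": f"images/{specimen_id}.png",
                "species_index": spec.species_index,
                "specimen_id": specimen_id,
                "seed": child_seed,
            })
            coll.images.append(img)
            coll.masks.append(mask)
            coll.centers.append(centers)
    coll.manifest = pd.DataFrame(rows, columns=["path", "species_index", "specimen_id", "seed"])

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for row, img, mask in zip(rows, coll.images, coll.masks):
            iio.imwrite(out / row["path"], img)
            iio.imwrite(out / "masks" / f"{row['specimen_id']}_mask.png",
                        (mask.astype(np.uint8) * 255))
        coll.manifest.to_csv(out / "manifest.csv", index=False)
    return coll


# Table of per-species specimen counts in the reference collection
# (15 storage-product beetle species, 69 whole-elytron images).
REFERENCE_SPECIMEN_COUNTS = (5, 5, 4, 6, 4, 4, 4, 5, 4, 5, 5, 3, 5, 5, 5)


#: The same-genus look-alike pair in :func:`demo_species`: identical base
#: colour, distinguishable only through their key-object patterns.
DEMO_KEY_OBJECT_PAIR = (1, 2)


def demo_species() -> list[SpeciesSpec]:
    """Four illustrative species, one per pattern category.

    Species 1 (hairs) and 2 (holes) share the same base colour and differ
    only in their key-object patterns: a same-genus look-alike pair that
    colour and coarse texture cannot separate.  Species parameters are
    chosen so that between-species contrasts (base colour distance,
    key-object statistics) clearly exceed the generator's within-species
    variation, making the collection separable by construction.
    """
    return [
        SpeciesSpec(1, (150, 62, 40), ("hair",), object_density=110.0,
                    object_size_px=(5, 9), line_orientation_deg=25.0),
        SpeciesSpec(2, (150, 62, 40), ("hole",), object_density=160.0,
                    object_size_px=(4, 7)),
        SpeciesSpec(3, (120, 95, 55), ("line",), object_density=35.0,
                    object_size_px=(6, 10), line_orientation_deg=80.0),
        SpeciesSpec(4, (70, 45, 35), ("unit_shape",), object_density=60.0,
                    object_size_px=(8, 14), pattern_period_px=36.0),
    ]


def reference_species(scene: SceneSpec | None = None) -> list[SpeciesSpec]:
    """Fifteen illustrative species specs mirroring the reference collection.

    The real collection publishes no quantitative per-species pattern
    parameters, so these are deterministic, plausibly varied stand-ins:
    base colours span the dark-brown..reddish cuticle range and each
    species draws one or two pattern categories.
    """
    rng = np.random.default_rng(20160624)
    specs = []
    for idx in range(1, 16):
        base = tuple(int(v) for v in rng.integers([50, 35, 25], [185, 110, 70]))
        kinds = tuple(rng.choice(PATTERN_TYPES, size=rng.integers(1, 3), replace=False))
        specs.append(SpeciesSpec(
            species_index=idx,
            base_color=base,
            pattern_types=kinds,
            object_density=float(rng.uniform(30, 120)),
            object_size_px=(int(rng.integers(4, 8)), int(rng.integers(9, 18))),
            line_orientation_deg=float(rng.uniform(0, 180)),
            pattern_period_px=float(rng.uniform(30, 60)),
        ))
    return specs
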