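"""End-to-end orchestration: render -> enhance -> segment -> fragments -> features.

Glue used by the command-line interface, the test suite and the
reproduction script.  The stages mirror the identification workflow:
synthetic (or loaded) specimen images are enhanced, the elytron is
segmented, random fragments are sampled within it, and the global and
local descriptors are extracted into a specimen-grouped feature table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import preprocess, segment, synthdata
from .datasets import SpecimenDataset
from .features_global import GlobalFeatureExtractor
from .features_local import LocalFeatureExtractor

logger = logging.getLogger(__name__)


def specimen_fragments(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    n: int = 100,
    size_range: tuple[int, int] = (300, 2500),
    min_fg_fraction: float = 0.8,
    seed: int = 0,
    enhance: bool = True,
    specimen_id: str | None = None,
    species_index: int | None = None,
) -> list[segment.FragmentImage]:
    """Enhance one specimen image, segment it and sample fragments.

    If ``mask`` is given (e.g. generator ground truth is available) it is
    used directly instead of running the two-mask segmentation.
    """
    work = preprocess.enhance(img) if enhance else img
    if mask is None:
        mask = segment.segment_elytron(work)
    return segment.simulate_fragments(
        work, mask, n=n, size_range=size_range,
        min_fg_fraction=min_fg_fraction, seed=seed,
        source_specimen_id=specimen_id, species_index=species_index)


def collection_fragments(
    collection: synthdata.SpecimenCollection,
    fragments_per_specimen: int = 100,
    size_range: tuple[int, int] = (300, 2500),
    min_fg_fraction: float = 0.8,
    seed: int = 0,
    enhance: bool = True,
    use_truth_masks: bool = False,
) -> list[segment.FragmentImage]:
    """Sample fragments from every specimen of a rendered collection."""
    fragments = []
    for i, row in collection.manifest.iterrows():
        child = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        mask = collection.masks[i] if use_truth_masks else None
        fragments.extend(specimen_fragments(
            collection.images[i], mask=mask, n=fragments_per_specimen,
            size_range=size_range, min_fg_fraction=min_fg_fraction,
            seed=int(child), enhance=enhance,
            specimen_id=row["specimen_id"],
            species_index=int(row["species_index"])))
    return fragments


def fragment_manifest(fragments: list[segment.FragmentImage]) -> pd.DataFrame:
    """Manifest with one row per fragment (rectangles 0-based, half-open)."""
    return pd.DataFrame([
        {
            "source_specimen_id": f.source_specimen_id,
            "species_index": f.species_index,
            "row": f.crop_rect[0],
            "col": f.crop_rect[1],
            "height": f.crop_rect[2],
            "width": f.crop_rect[3],
        }
        for f in fragments
    ])


def extract_features(
    fragments: list[segment.FragmentImage],
    include: tuple[str, ...] = ("global", "local"),
    global_extractor: GlobalFeatureExtractor | None = None,
    local_extractor: LocalFeatureExtractor | None = None,
) -> SpecimenDataset:
    """Descriptor table for a list of fragments, grouped by specimen."""
    parts = []
    if "global" in include:
        g = global_extractor or GlobalFeatureExtractor()
        parts.append(g.fit_transform(fragments))
    if "local" in include:
        loc = local_extractor or LocalFeatureExtractor()
        parts.append(loc.fit_transform(fragments))
    if not parts:
        raise ValueError("include must name at least one of 'global', 'local'")
    features = pd.concat(parts, axis=1)
    labels = pd.Series([f.species_index for f in fragments], name="species_index")
    groups = pd.Series([f.source_specimen_id for f in fragments], name="specimen_id")
    return SpecimenDataset(features=features, labels=labels, groups=groups)


def recovery_scene(canvas: tuple[int, int] = (480, 640)) -> synthdata.SceneSpec:
    """Scene for the compact four-species recovery benchmark."""
    h, w = canvas
    return synthdata.SceneSpec(
        canvas_size=(h, w),
        ellipse_center=(h / 2.0, w / 2.0),
        ellipse_axes=(h * 0.448, w * 0.468),
    )


def build_recovery_dataset(
    seed: int = 0,
    specimens_per_species: int = 3,
    fragments_per_specimen: int = 20,
    canvas: tuple[int, int] = (480, 640),
    use_truth_masks: bool = False,
) -> SpecimenDataset:
    """Render the four-category demo collection and extract all features.

    Four synthetic species instantiate the four elytra pattern categories
    (hairs, holes, holes-of-different-statistics, unit shapes); two of them
    share base colour and pattern type and differ only in key-object size
    and density.
    """
    specs = synthdata.demo_species()
    scene = recovery_scene(canvas)
    coll = synthdata.make_collection(
        specs, [specimens_per_species] * len(specs), scene, seed=seed)
    fragments = collection_fragments(
        coll, fragments_per_specimen=fragments_per_specimen,
        seed=seed + 1, use_truth_masks=use_truth_masks)
    logger.info("extracting features for %d fragments", len(fragments))
    return extract_features(fragments)
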