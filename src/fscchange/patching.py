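"""Centroid-anchored patch extraction and the training-area filter.

Each FSC contributes a single fixed-size window (default 5×5 pixels, i.e.
50 m × 50 m at 10 m resolution) centered on the pixel nearest its geometric
centroid.  FSCs above 3,000 m² are "in distribution": their centroid window
is very likely fully interior, so they are eligible for training.  Smaller
FSCs are never discarded — they are classified at prediction time but kept
out of training and flagged as out-of-distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from .exceptions import EdgeError, FormatError, MaskedPatchError
from .geo_io import FSCRecord, MultispectralScene

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 5
DEFAULT_MIN_AREA_M2 = 3000.0


@dataclass
class PatchSample:
    """One FSC's centroid window in one epoch."""

    fsc_id: str
    window: np.ndarray  # (size, size, nbands)
    center_rowcol: tuple[int, int]
    epoch: str
    in_distribution: bool
    label: str | None = None


def anchor_point(record: FSCRecord):
    """Anchor map coordinate for a patch: the geometric centroid, or a
    guaranteed-interior representative point when the centroid falls outside
    the polygon (possible for concave FSCs)."""
    geom = record.geometry
    if geom.is_empty:
        raise FormatError(f"FSC {record.fsc_id}: empty geometry")
    centroid = geom.centroid
    if geom.contains(centroid):
        return centroid
    return geom.representative_point()


def extract_patch(
    scene: MultispectralScene,
    record: FSCRecord,
    size: int = DEFAULT_PATCH_SIZE,
    min_area_m2: float = DEFAULT_MIN_AREA_M2,
) -> PatchSample:
    """Extract the ``size × size`` window centered on the FSC's anchor pixel.

    Raises
    ------
    EdgeError
        The window would cross the raster edge.
    MaskedPatchError
        The window intersects nodata pixels; such samples are excluded
        rather than imputed (imputation would fabricate texture).
    """
    if size % 2 != 1 or size < 1:
        raise ValueError("patch size must be a positive odd integer")
    half = size // 2
    pt = anchor_point(record)
    row, col = scene.transform.to_rowcol(pt.x, pt.y)
    rows, cols = scene.shape
    if row - half < 0 or col - half < 0 or row + half >= rows or col + half >= cols:
        raise EdgeError(
            f"FSC {record.fsc_id}: window at ({row}, {col}) crosses the raster edge"
        )
    sl = (slice(row - half, row + half + 1), slice(col - half, col + half + 1))
    if scene.nodata_mask[sl].any():
        raise MaskedPatchError(
            f"FSC {record.fsc_id}: window at ({row}, {col}) intersects nodata"
        )
    window = scene.band_stack[sl[0], sl[1], :].copy()
    return PatchSample(
        fsc_id=record.fsc_id,
        window=window,
        center_rowcol=(row, col),
        epoch=scene.epoch,
        in_distribution=record.area_m2 > min_area_m2,
        label=record.label(scene.epoch),
    )


def extract_patches(
    scene: MultispectralScene,
    records: list[FSCRecord],
    size: int = DEFAULT_PATCH_SIZE,
    min_area_m2: float = DEFAULT_MIN_AREA_M2,
    skipped: list | None = None,
) -> list[PatchSample]:
    """Extract patches for all records, logging and skipping edge/nodata cases."""
    out: list[PatchSample] = []
    for rec in records:
        try:
            out.append(extract_patch(scene, rec, size=size, min_area_m2=min_area_m2))
        except (EdgeError, MaskedPatchError) as exc:
            logger.info("skipping sample: %s", exc)
            if skipped is not None:
                skipped.append((rec.fsc_id, str(exc)))
    return out


def split_by_area(
    records: list[FSCRecord], min_area_m2: float = DEFAULT_MIN_AREA_M2
) -> tuple[list[FSCRecord], list[FSCRecord]]:
    """Partition records into (training-eligible, out-of-distribution).

    Eligibility is the strict inequality ``area > min_area_m2``: an FSC of
    exactly 3,000 m² is out of distribution.
    """
    eligible = [r for r in records if r.area_m2 > min_area_m2]
    ood = [r for r in records if not r.area_m2 > min_area_m2]
    return eligible, ood


def train_test_split(
    samples: list[PatchSample],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[PatchSample], list[PatchSample]]:
    """Deterministic stratified split of in-distribution samples.

    Only ``in_distribution`` samples enter the training side; out-of-
    distribution samples all go to the test side.  Within each class the
    split is proportional (stratified); a class with fewer than 2
    in-distribution samples is kept whole in training with a warning.
    """
    in_dist = [s for s in samples if s.in_distribution]
    ood = [s for s in samples if not s.in_distribution]
    if len(in_dist) < 5:
        raise ValueError("need at least 5 in-distribution samples to split")
    rng = np.random.default_rng(seed)
    by_class: dict[str | None, list[PatchSample]] = {}
    for s in in_dist:
        by_class.setdefault(s.label, []).append(s)
    train: list[PatchSample] = []
    test: list[PatchSample] = []
    for label in sorted(by_class, key=str):
        group = by_class[label]
        if len(group) < 2:
            logger.warning(
                "class %r has %d sample(s); kept whole in training", label, len(group)
            )
            train.extend(group)
            continue
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    test.extend(ood)
    return train, test
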