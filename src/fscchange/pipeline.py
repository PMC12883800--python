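"""End-to-end orchestration: feature tables, selection, training, change
detection and evaluation on a scene pair.

The stages mirror the operational workflow: centroid patches are extracted
per FSC and epoch; band means, vegetation indices and GLCM texture metrics
form the candidate feature set; spectral and texture groups are ranked by
boosted-tree gain and pruned by cumulative contribution; a classifier is
trained on the epoch-1 labels of training-eligible FSCs; both epochs are
then classified and compared per FSC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as mdl
from .change import ChangeRecord, TransitionMatrix, compare_epochs, transition_matrix
from .evaluation import MetricReport, PointPattern, confusion, detection_rate, metrics, nearest_neighbor_index
from .geo_io import ALL_BANDS, CLASS_ORDER, FSCRecord, MultispectralScene
from .patching import (
    DEFAULT_MIN_AREA_M2,
    DEFAULT_PATCH_SIZE,
    PatchSample,
    extract_patches,
    train_test_split,
)
from .selection import (
    DEFAULT_CUMULATIVE_THRESHOLD,
    ImportanceRanking,
    rank_by_gain,
    select_by_cumulative,
)
from .spectral import VI_NAMES, available_indices, spectral_features
from .texture import DEFAULT_DISTANCE, DEFAULT_LEVELS, texture_features

logger = logging.getLogger(__name__)

META_COLUMNS = ("fsc_id", "epoch", "label", "in_distribution", "area_m2")


@dataclass
class FeatureConfig:
    """Feature-extraction settings shared by all stages."""

    patch_size: int = DEFAULT_PATCH_SIZE
    min_area_m2: float = DEFAULT_MIN_AREA_M2
    texture_bands: tuple[str, ...] = ("B8",)
    glcm_levels: int = DEFAULT_LEVELS
    glcm_distance: int = DEFAULT_DISTANCE
    vi_per_pixel: bool = False
    indices: tuple[str, ...] | None = None


def build_feature_table(
    scene: MultispectralScene,
    records: list[FSCRecord],
    config: FeatureConfig | None = None,
    skipped: list | None = None,
) -> pd.DataFrame:
    """One feature row per FSC whose centroid window is extractable.

    Column order is stable: metadata, band means (B2…B12), vegetation
    indices, then GLCM metrics suffixed by band.
    """
    config = config or FeatureConfig()
    patches = extract_patches(
        scene, records,
        size=config.patch_size, min_area_m2=config.min_area_m2, skipped=skipped,
    )
    areas = {rec.fsc_id: rec.area_m2 for rec in records}
    return patch_feature_table(patches, scene.band_names, config, areas=areas)


def patch_feature_table(
    patches: list[PatchSample],
    band_names: tuple[str, ...],
    config: FeatureConfig | None = None,
    areas: dict[str, float] | None = None,
) -> pd.DataFrame:
    config = config or FeatureConfig()
    indices = config.indices if config.indices is not None else available_indices(band_names)
    rows = []
    for patch in patches:
        row: dict = {
            "fsc_id": patch.fsc_id,
            "epoch": patch.epoch,
            "label": patch.label,
            "in_distribution": patch.in_distribution,
            "area_m2": (areas or {}).get(patch.fsc_id, np.nan),
        }
        row.update(spectral_features(patch, band_names, indices=indices,
                                     vi_per_pixel=config.vi_per_pixel))
        row.update(texture_features(patch, band_names,
                                    texture_bands=config.texture_bands,
                                    levels=config.glcm_levels,
                                    distance=config.glcm_distance))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    ordered = [c for c in META_COLUMNS if c in df.columns]
    ordered += [b for b in band_names if b in df.columns]
    ordered += [v for v in VI_NAMES if v in df.columns]
    ordered += [c for c in df.columns if c.startswith("GLCM_")]
    return df[ordered]


def feature_groups(columns) -> dict[str, list[str]]:
    """Split feature columns into the spectral (bands + VIs) and texture groups."""
    spectral = [c for c in columns if c in ALL_BANDS or c in VI_NAMES]
    texture = [c for c in columns if c.startswith("GLCM_")]
    return {"spectral": spectral, "texture": texture}


def feature_subset(columns, which: str) -> list[str]:
    """Feature-combination presets used by the ablation experiments."""
    bands = [c for c in columns if c in ALL_BANDS]
    vis = [c for c in columns if c in VI_NAMES]
    tex = [c for c in columns if c.startswith("GLCM_")]
    if which == "bands":
        return bands
    if which == "bands+vis":
        return bands + vis
    if which == "bands+vis+texture":
        return bands + vis + tex
    raise ValueError(f"unknown feature subset {which!r}")


def select_features(
    table: pd.DataFrame,
    threshold: float = DEFAULT_CUMULATIVE_THRESHOLD,
    seed: int = 0,
) -> tuple[dict[str, ImportanceRanking], list[str]]:
    """Grouped gain ranking + cumulative-contribution selection on labeled rows."""
    groups = feature_groups(table.columns)
    groups = {g: names for g, names in groups.items() if names}
    labels = np.array([CLASS_ORDER.index(lb) for lb in table["label"]])
    rankings = rank_by_gain(table, labels, groups, seed=seed)
    selected: list[str] = []
    for group in ("spectral", "texture"):
        if group in rankings:
            selected.extend(select_by_cumulative(rankings[group], threshold))
    return rankings, selected


def train_classifier(
    kind: str,
    table: pd.DataFrame,
    feature_names: list[str],
    seed: int = 0,
    pso_config: mdl.PSOConfig | None = None,
    proxy_epochs: int = 30,
    epochs: int = mdl.DEFAULT_EPOCHS,
) -> mdl.TrainedClassifier:
    X = table[feature_names]
    y = list(table["label"])
    if kind in ("RF", "SVM"):
        return mdl.train_baseline(kind, X, y, seed=42 if kind == "RF" else seed)
    if kind == "BPNN":
        spec = mdl.BPNNSpec(input_size=len(feature_names), epochs=epochs, seed=seed)
        return mdl.train_bpnn(spec, X, y)
    if kind == "PSO-BPNN":
        return mdl.train_pso_bpnn(
            X, y, pso_config=pso_config, proxy_epochs=proxy_epochs,
            final_epochs=epochs, seed=seed,
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class ExperimentResult:
    """Everything a two-epoch classification + change-detection run produces."""

    model: mdl.TrainedClassifier
    selected_features: list[str]
    rankings: dict[str, ImportanceRanking]
    holdout_report: MetricReport
    labels_by_epoch: dict[str, dict[str, str]]  # epoch → fsc_id → predicted
    change_records: list[ChangeRecord]
    transition: TransitionMatrix
    detected: int = 0
    missed: int = 0
    rate: float = float("nan")
    nni: float = float("nan")
    nni_p: float = float("nan")
    extras: dict = field(default_factory=dict)


def run_change_detection(
    scene1: MultispectralScene,
    scene2: MultispectralScene,
    records: list[FSCRecord],
    model_kind: str = "PSO-BPNN",
    feature_config: FeatureConfig | None = None,
    selection_threshold: float = DEFAULT_CUMULATIVE_THRESHOLD,
    feature_set: str | None = None,
    seed: int = 0,
    pso_config: mdl.PSOConfig | None = None,
    proxy_epochs: int = 30,
    epochs: int = mdl.DEFAULT_EPOCHS,
) -> ExperimentResult:
    """Classify both epochs and detect per-FSC changes.

    Training uses the epoch-1 labels of training-eligible FSCs (area above
    the threshold), with an internal stratified 80/20 train/holdout split.
    If ``feature_set`` is given ("bands", "bands+vis", "bands+vis+texture"),
    that preset replaces gain-based selection (used by ablation runs).
    """
    feature_config = feature_config or FeatureConfig()
    skipped: list = []
    patches1 = extract_patches(scene1, records, size=feature_config.patch_size,
                               min_area_m2=feature_config.min_area_m2, skipped=skipped)
    patches2 = extract_patches(scene2, records, size=feature_config.patch_size,
                               min_area_m2=feature_config.min_area_m2, skipped=skipped)
    table1 = patch_feature_table(patches1, scene1.band_names, feature_config)
    table2 = patch_feature_table(patches2, scene2.band_names, feature_config)

    train_patches, test_patches = train_test_split(patches1, 0.8, seed=seed)
    train_ids = {p.fsc_id for p in train_patches}
    holdout_ids = {p.fsc_id for p in test_patches if p.in_distribution}
    train_tab = table1[table1["fsc_id"].isin(train_ids)]

    if feature_set is not None:
        rankings: dict[str, ImportanceRanking] = {}
        selected = feature_subset(table1.columns, feature_set)
    else:
        rankings, selected = select_features(train_tab, selection_threshold, seed=seed)

    model = train_classifier(
        model_kind, train_tab, selected, seed=seed,
        pso_config=pso_config, proxy_epochs=proxy_epochs, epochs=epochs,
    )

    holdout_tab = table1[table1["fsc_id"].isin(holdout_ids)]
    pred_holdout, _ = mdl.predict(model, holdout_tab[selected])
    report = metrics(confusion(list(holdout_tab["label"]), pred_holdout,
                               class_order=CLASS_ORDER))

    labels_by_epoch: dict[str, dict[str, str]] = {}
    for scene, table in ((scene1, table1), (scene2, table2)):
        pred, _ = mdl.predict(model, table[selected])
        labels_by_epoch[scene.epoch] = dict(zip(table["fsc_id"], pred))

    common = set(labels_by_epoch[scene1.epoch]) & set(labels_by_epoch[scene2.epoch])
    l1 = {i: labels_by_epoch[scene1.epoch][i] for i in common}
    l2 = {i: labels_by_epoch[scene2.epoch][i] for i in common}
    change_records = compare_epochs(l1, l2)
    transition = transition_matrix(change_records,
                                   epoch_pair=(scene1.epoch, scene2.epoch))

    result = ExperimentResult(
        model=model, selected_features=selected, rankings=rankings,
        holdout_report=report, labels_by_epoch=labels_by_epoch,
        change_records=change_records, transition=transition,
        extras={"skipped": skipped, "n_train": len(train_patches),
                "n_holdout": len(holdout_ids)},
    )

    truth_changed = {
        r.fsc_id for r in records
        if r.label(scene1.epoch) is not None and r.label(scene2.epoch) is not None
        and r.label(scene1.epoch) != r.label(scene2.epoch)
    }
    detected_changed = {c.fsc_id for c in change_records if c.changed}
    if truth_changed:
        result.detected, result.missed, result.rate = detection_rate(
            truth_changed, detected_changed
        )
    if len(detected_changed) >= 2:
        geom_by_id = {r.fsc_id: r.geometry for r in records}
        pts = np.array([
            (geom_by_id[i].centroid.x, geom_by_id[i].centroid.y)
            for i in sorted(detected_changed)
        ])
        rows, cols = scene1.shape
        area = rows * cols * scene1.transform.pixel_size**2
        result.nni, _, result.nni_p = nearest_neighbor_index(PointPattern(pts, area))
    return result
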