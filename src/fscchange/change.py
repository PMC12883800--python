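"""Post-classification change detection.

Each epoch is classified independently; an FSC is flagged changed when its
labels differ between the two epochs.  Transitions are summarized in a K×K
matrix whose rows are the earlier epoch and columns the later epoch, from
which per-class retention rates (diagonal share of the row) and pairwise
conversion rates are derived.  FSCs lacking a label in either epoch (e.g.
cloud-masked patches) are excluded from the matrix and reported separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping

from .exceptions import DegenerateInputError, FormatError
from .geo_io import CLASS_ORDER, FSCRecord


@dataclass
class ChangeRecord:
    fsc_id: str
    from_class: str
    to_class: str
    changed: bool


@dataclass
class TransitionMatrix:
    """K×K transition counts; rows = earlier epoch, columns = later epoch."""

    counts: np.ndarray
    class_order: tuple[str, ...]
    epoch_pair: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def compare_epochs(
    labels_e1: dict[str, str], labels_e2: dict[str, str]
) -> list[ChangeRecord]:
    """One :class:`ChangeRecord` per FSC; both epochs must cover the same ids."""
    ids1, ids2 = set(labels_e1), set(labels_e2)
    if ids1 != ids2:
        missing = sorted(ids1 ^ ids2)
        raise FormatError(
            "epoch label sets differ; unmatched ids: " + ", ".join(missing[:10])
        )
    return [
        ChangeRecord(
            fsc_id=fid,
            from_class=labels_e1[fid],
            to_class=labels_e2[fid],
            changed=labels_e1[fid] != labels_e2[fid],
        )
        for fid in sorted(labels_e1)
    ]


def transition_matrix(
    records: list[ChangeRecord],
    class_order: tuple[str, ...] = CLASS_ORDER,
    epoch_pair: tuple[str, str] = ("e1", "e2"),
) -> TransitionMatrix:
    """Count transitions; the grand total equals the number of records."""
    if not records:
        raise DegenerateInputError("no change records")
    index = {c: k for k, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for rec in records:
        if rec.from_class not in index or rec.to_class not in index:
            raise FormatError(
                f"unknown class label in record {rec.fsc_id}: "
                f"{rec.from_class!r} → {rec.to_class!r}"
            )
        counts[index[rec.from_class], index[rec.to_class]] += 1
    return TransitionMatrix(counts=counts, class_order=class_order, epoch_pair=epoch_pair)


def retention_rate(matrix: TransitionMatrix, cls: str) -> float:
    """Percentage of a class's FSCs keeping their class between the epochs."""
    k = matrix.class_order.index(cls)
    row_sum = matrix.counts[k].sum()
    if row_sum == 0:
        raise DegenerateInputError(f"class {cls!r} has no FSCs in the earlier epoch")
    return 100.0 * matrix.counts[k, k] / row_sum


def conversion_rate(matrix: TransitionMatrix, from_class: str, to_class: str) -> float:
    """Percentage of ``from_class`` FSCs converting to ``to_class``."""
    a = matrix.class_order.index(from_class)
    b = matrix.class_order.index(to_class)
    row_sum = matrix.counts[a].sum()
    if row_sum == 0:
        raise DegenerateInputError(f"class {from_class!r} has no FSCs in the earlier epoch")
    return 100.0 * matrix.counts[a, b] / row_sum


def rates_table(matrix: TransitionMatrix) -> pd.DataFrame:
    """Retention and all pairwise conversion rates, one row per class pair."""
    rows = []
    for a in matrix.class_order:
        if matrix.counts[matrix.class_order.index(a)].sum() == 0:
            continue
        for b in matrix.class_order:
            rate = conversion_rate(matrix, a, b)
            rows.append({"from": a, "to": b, "rate_pct": rate, "retention": a == b})
    return pd.DataFrame(rows)


def export_change_layer(
    records: list[ChangeRecord], fsc_records: list[FSCRecord], path
) -> int:
    """Write changed FSC polygons to GeoJSON with from/to attributes.

    Returns the number of features written (= number of changed records).
    """
    geom_by_id = {r.fsc_id: r.geometry for r in fsc_records}
    features = []
    for rec in records:
        if not rec.changed:
            continue
        if rec.fsc_id not in geom_by_id:
            raise FormatError(f"no geometry for changed FSC {rec.fsc_id}")
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(geom_by_id[rec.fsc_id]),
                "properties": {
                    "fsc_id": rec.fsc_id,
                    "from_class": rec.from_class,
                    "to_class": rec.to_class,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return len(features)
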