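"""Grouped gain-based feature ranking and cumulative-contribution selection.

Spectral features (raw bands + vegetation indices) and texture features are
ranked in two independent groups, each by the total gain (summed
loss-reduction over all tree splits) the feature earns in a gradient-boosted
classifier trained on that group alone.  Grouping avoids the bias a joint
model would introduce through the different dimensionality of the two
feature families.  Within each group, the selected set is the smallest
prefix of the gain ranking whose cumulative normalized gain reaches the
contribution threshold (default 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .exceptions import ConfigError

#: Gradient-boosting settings used for ranking; fixed for determinism.
DEFAULT_BOOST_PARAMS = dict(
    n_estimators=100,
    max_depth=4,
    learning_rate=0.1,
    tree_method="hist",
    n_jobs=1,
)

DEFAULT_CUMULATIVE_THRESHOLD = 0.85


@dataclass
class ImportanceRanking:
    """Gain ranking of one feature group, normalized to sum 1."""

    group: str
    entries: list[tuple[str, float, float, float]] = field(default_factory=list)
    # each entry: (feature, gain, normalized_gain, cumulative_fraction)

    @property
    def features(self) -> list[str]:
        return [e[0] for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.entries, columns=["feature", "gain", "normalized", "cumulative"]
        )
        df.insert(0, "group", self.group)
        df.insert(1, "rank", np.arange(1, len(df) + 1))
        return df


def rank_by_gain(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: dict[str, list[str]],
    seed: int = 0,
    boost_params: dict | None = None,
) -> dict[str, ImportanceRanking]:
    """Rank each feature group by total gain in its own boosted classifier.

    Parameters
    ----------
    features
        One row per sample, one column per candidate feature.
    labels
        Integer-encoded class labels (≥2 classes present).
    groups
        Mapping group name → list of feature column names.

    Features that never split (e.g. constants) receive gain 0 and rank last;
    ties are broken alphabetically for determinism.
    """
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ConfigError("ranking requires at least 2 classes")
    params = dict(DEFAULT_BOOST_PARAMS)
    if boost_params:
        params.update(boost_params)
    y = np.searchsorted(classes, labels)
    rankings: dict[str, ImportanceRanking] = {}
    for group, names in groups.items():
        if not names:
            raise ConfigError(f"feature group {group!r} is empty")
        model = xgb.XGBClassifier(
            random_state=seed,
            num_class=len(classes) if len(classes) > 2 else None,
            objective="multi:softprob" if len(classes) > 2 else "binary:logistic",
            **params,
        )
        model.fit(features[names].to_numpy(), y)
        raw = model.get_booster().get_score(importance_type="total_gain")
        # booster keys are f0, f1, ... in column order
        gains = {name: float(raw.get(f"f{k}", 0.0)) for k, name in enumerate(names)}
        ordered = sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(g for _, g in ordered)
        if total <= 0:
            # no splits at all: uniform attribution keeps the contract
            normalized = [1.0 / len(ordered)] * len(ordered)
        else:
            normalized = [g / total for _, g in ordered]
        cumulative = np.cumsum(normalized)
        rankings[group] = ImportanceRanking(
            group=group,
            entries=[
                (name, gain, norm, float(cum))
                for (name, gain), norm, cum in zip(ordered, normalized, cumulative)
            ],
        )
    return rankings


def select_by_cumulative(
    ranking: ImportanceRanking,
    threshold: float = DEFAULT_CUMULATIVE_THRESHOLD,
) -> list[str]:
    """Smallest prefix of the ranking reaching the cumulative threshold."""
    if not ranking.entries:
        raise ConfigError(f"ranking for group {ranking.group!r} is empty")
    selected: list[str] = []
    for name, _, _, cumulative in ranking.entries:
        selected.append(name)
        if cumulative >= threshold - 1e-12:
            break
    return selected
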