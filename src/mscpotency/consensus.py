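"""Cross-model consensus panels, consensus refits, and line ablation.

A feature flagged as important — in the top fraction of a standard family's
importance ranking, or present in enough qualifying symbolic-regression
models — by at least ``min_models`` families enters the consensus panel.
Consensus models are the same families re-tuned on the panel-restricted
matrix; the ablation refit drops a designated cell line (e.g. the single
iPSC-derived outlier) while keeping the panel fixed, with a reduced CV fold
count for the smaller sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import CompositeScore, ValidationError, logger
from .models import FAMILIES, FittedModel, ModelSpec, importance, loo_r2, tune, _standardize


@dataclass
class ConsensusPanel:
    """Features important in >= min_models families, with memberships."""

    membership: dict[str, set[str]]
    min_models: int = 2
    top_fraction: float = 0.20

    def __post_init__(self) -> None:
        for f, fams in self.membership.items():
            if len(fams) < self.min_models:
                raise ValidationError(
                    f"panel feature {f!r} flagged by {len(fams)} < min_models families"
                )

    @property
    def features(self) -> list[str]:
        return sorted(self.membership)

    def counts(self) -> dict[str, int]:
        return {f: len(v) for f, v in self.membership.items()}


def top_fraction_features(fitted: FittedModel, fraction: float = 0.20) -> set[str]:
    """Top ``ceil(fraction * n)`` features of a fitted model by importance.

    ``n`` is the size of the model's final (post-selection) feature set.
    Ties break by stable position in that feature order.
    """
    feats = fitted.selected_features
    if not feats:
        return set()
    k = math.ceil(fraction * len(feats))
    order = sorted(range(len(feats)),
                   key=lambda i: (-fitted.importance.get(feats[i], 0.0), i))
    return {feats[i] for i in order[:k]}


def build_consensus(
    family_sets: Mapping[str, set[str]],
    min_models: int = 2,
    top_fraction: float = 0.20,
) -> ConsensusPanel:
    """Features flagged by >= ``min_models`` of the supplied family sets."""
    if len(family_sets) < 2:
        raise ValidationError("build_consensus needs >= 2 family feature sets")
    counts: dict[str, set[str]] = {}
    for fam, feats in family_sets.items():
        for f in feats:
            counts.setdefault(f, set()).add(fam)
    membership = {f: fams for f, fams in counts.items() if len(fams) >= min_models}
    logger.info("consensus panel: %d features from %d families",
                len(membership), len(family_sets))
    return ConsensusPanel(membership=membership, min_models=min_models,
                          top_fraction=top_fraction)


def consensus_refit(
    panel: ConsensusPanel,
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    cv_folds: int = 5,
    grids: Mapping[str, Mapping] | None = None,
) -> dict[str, FittedModel]:
    """Re-tune and LOO-evaluate each family on the panel-restricted matrix.

    No further feature selection happens: the panel is the model input.
    """
    feats = [f for f in X.columns if f in panel.membership]
    if not feats:
        raise ValidationError(
            "consensus panel is empty on this matrix; lower min_models or top_fraction"
        )
    Xp = _standardize(X[feats])
    grids = grids or {}
    out: dict[str, FittedModel] = {}
    for fam in families:
        spec = ModelSpec(family=fam, grid=grids.get(fam), cv_folds=cv_folds, seed=seed)
        params = tune(spec, Xp, y)
        imp = importance(spec, Xp, y, params)
        r2 = loo_r2(spec, Xp, y, params)
        out[fam] = FittedModel(
            family=fam, params=params, selected_features=feats,
            importance=imp.to_dict(), loo_r2=r2, n_features_in=len(feats),
        )
    return out


def ablation_refit(
    panel: ConsensusPanel,
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    exclude_line: str,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    cv_folds: int = 3,
    grids: Mapping[str, Mapping] | None = None,
) -> dict[str, FittedModel]:
    """Consensus refit without one cell line, same panel, reduced CV folds."""
    if exclude_line not in X.index:
        raise ValidationError(f"line {exclude_line!r} not present in the matrix")
    keep = [l for l in X.index if l != exclude_line]
    if len(keep) < 4:
        raise ValidationError("ablation would leave < 4 lines")
    scores = y.scores if isinstance(y, CompositeScore) else y
    return consensus_refit(
        panel, X.loc[keep], scores.loc[keep], families=families,
        seed=seed, cv_folds=cv_folds, grids=grids,
    )
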