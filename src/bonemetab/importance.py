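"""Removal-based feature importance and one-feature models.

For a chosen best model (dataset + classifier family), each input feature
is removed in turn and the LOOCV accuracy recomputed; the delta
(new − pool) ranks the features. By the study's convention a *negative*
delta marks an important feature (the model suffers without it) and a
positive delta marks noise whose removal improves the model. Only
single-feature removals are performed — no greedy multi-step elimination.

One-feature models use the same classifier family and CV but a single
input column at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import EncodedDataset
from .evaluation import DEFAULT_SEED, EvalResult, loocv_accuracy


@dataclass
class AblationResult:
    output: str
    removed_feature: str
    score: float            # LOOCV accuracy without the feature
    delta: float            # score − pool score


@dataclass
class OneFeatureResult:
    output: str
    feature: str
    score: float            # LOOCV accuracy with only this feature
    delta: float            # score − pool score


def _subset(dataset: EncodedDataset, columns: list[str]) -> EncodedDataset:
    return replace(dataset, X=dataset.X[columns])


def importance_by_removal(dataset: EncodedDataset, family: str,
                          pool_score: float | None = None,
                          seed: int = DEFAULT_SEED) -> list[AblationResult]:
    """One LOOCV re-evaluation per removed feature, ranked by ascending delta
    (most negative = most important)."""
    features = dataset.feature_names
    if len(features) < 2:
        raise ValueError("removal importance needs at least 2 features")
    if pool_score is None:
        pool_score = loocv_accuracy(dataset, family, seed).score
    results = []
    for feat in features:
        kept = [f for f in features if f != feat]
        res = loocv_accuracy(_subset(dataset, kept), family, seed)
        results.append(AblationResult(dataset.spec.output, feat, res.score,
                                      res.score - pool_score))
    results.sort(key=lambda r: (r.delta, r.removed_feature))
    return results


def one_feature_models(dataset: EncodedDataset, family: str,
                       pool_score: float | None = None,
                       seed: int = DEFAULT_SEED) -> list[OneFeatureResult]:
    """One LOOCV model per single input feature, same family and CV."""
    if pool_score is None:
        pool_score = loocv_accuracy(dataset, family, seed).score
    results = []
    for feat in dataset.feature_names:
        res = loocv_accuracy(_subset(dataset, [feat]), family, seed)
        results.append(OneFeatureResult(dataset.spec.output, feat, res.score,
                                        res.score - pool_score))
    results.sort(key=lambda r: (r.score, r.feature))
    return results


@dataclass
class RefinedBest:
    """Pool model, possibly improved by dropping one noise feature."""

    output: str
    family: str
    score: float
    removed_feature: str | None     # None = pool model kept


def refine_best(pool: EvalResult, ablations: list[AblationResult]) -> RefinedBest:
    """If any single removal strictly improves the pool score, adopt the best
    such reduced model; otherwise keep the pool model."""
    best = max(ablations, key=lambda r: r.delta, default=None)
    if best is not None and best.delta > 0:
        return RefinedBest(pool.output, pool.family, best.score,
                           best.removed_feature)
    return RefinedBest(pool.output, pool.family, pool.score, None)


def ablation_frame(results: list[AblationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"output": r.output, "removed_feature": r.removed_feature,
         "new_acc": r.score, "delta_vs_pool": r.delta}
        for r in results
    ])


def one_feature_frame(results: list[OneFeatureResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"output": r.output, "feature": r.feature,
         "acc": r.score, "delta_vs_pool": r.delta}
        for r in results
    ])
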