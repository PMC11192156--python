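"""Random-forest species classifier: training, tuning, prediction,
Gini importance and importance-filtered refits.

The forest contract — bootstrap bagging, Gini splits, ``mtry`` candidate
predictors per split, majority vote, out-of-bag error — is delegated to
scikit-learn's ``RandomForestClassifier``; bit-compatibility with any other
ecosystem's forests is a non-goal, statistical equivalence is the contract.
The categorical Site predictor is one-hot expanded internally but counts as
one logical predictor for p and for the default mtry = floor(sqrt(p)).

Importance is reported as mean decrease in Gini on the conventional scale:
per tree, the sum over nodes of (node sample share x impurity decrease),
scaled by the training-set size and averaged over trees; one-hot Site
columns are summed back into a single Site entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import RESPONSE_COLUMN, default_predictors

__all__ = [
    "ForestConfig",
    "TrainedForest",
    "train_forest",
    "predict_species",
    "tune_forest",
    "importance_filter_refit",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class ForestConfig:
    ntree: int = 500
    mtry: Optional[int] = None  # None -> floor(sqrt(p))
    min_node_size: int = 1
    rng_seed: int = 0
    class_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolved_mtry(self, p: int) -> int:
        if self.mtry is not None:
            if self.mtry > p:
                raise ValueError(f"mtry={self.mtry} exceeds predictor count {p}")
            return self.mtry
        return max(1, math.floor(math.sqrt(p)))


@dataclass
class TrainedForest:
    forest: RandomForestClassifier
    config: ForestConfig
    predictors: List[str]  # logical predictor names (Site is one)
    site_levels: List[str]  # observed Site vocabulary, fixed at fit time
    class_labels: List[str]
    oob_error: float
    importance: pd.Series  # mean decrease in Gini per logical predictor

    @property
    def p(self) -> int:
        return len(self.predictors)


def _encode(
    table: pd.DataFrame, predictors: Sequence[str], site_levels: Sequence[str]
) -> np.ndarray:
    """Design matrix: numeric predictors as-is, Site one-hot over the
    stored vocabulary.  Unseen Site levels fail loudly."""
    cols = []
    for name in predictors:
        if name == "Site":
            site = table["Site"].astype(str)
            unseen = sorted(set(site) - set(site_levels))
            if unseen:
                raise ValueError(
                    f"unseen Site level(s) {unseen}; model knows {list(site_levels)}"
                )
            for lev in site_levels:
                cols.append((site == lev).to_numpy(dtype=float))
        else:
            if name not in table:
                raise ValueError(f"feature table is missing predictor {name!r}")
            cols.append(table[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def _expanded_names(predictors: Sequence[str], site_levels: Sequence[str]) -> List[str]:
    out: List[str] = []
    for name in predictors:
        if name == "Site":
            out.extend(f"Site={lev}" for lev in site_levels)
        else:
            out.append(name)
    return out


def _check_schema(model: TrainedForest, table: pd.DataFrame) -> None:
    missing = [c for c in model.predictors if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing predictor column(s) {missing}")


def train_forest(
    train: pd.DataFrame,
    config: Optional[ForestConfig] = None,
    predictors: Optional[Sequence[str]] = None,
) -> TrainedForest:
    """Fit a seeded random forest on a labeled feature table."""
    config = config or ForestConfig()
    predictors = list(predictors) if predictors is not None else default_predictors()
    predictors = [c for c in predictors if c in train.columns or c == "Site"]

    # canonical row order first: the fit is then invariant to how the
    # caller happened to order the training table
    sort_cols = [c for c in predictors if c in train.columns] + [RESPONSE_COLUMN]
    train = train.sort_values(by=sort_cols, kind="mergesort").reset_index(drop=True)

    labels = train[RESPONSE_COLUMN].astype(str)
    classes = config.class_labels or sorted(labels.unique())
    if labels.nunique() < 2:
        raise ValueError("training data must contain at least 2 classes")

    site_levels = (
        sorted(train["Site"].astype(str).unique()) if "Site" in predictors else []
    )
    X = _encode(train, predictors, site_levels)
    y = labels.to_numpy()

    mtry = config.resolved_mtry(len(predictors))
    rf = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=mtry,
        min_samples_leaf=config.min_node_size,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        random_state=config.rng_seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    oob_error = 1.0 - float(rf.oob_score_)

    imp = _mean_decrease_gini(rf, len(y))
    importance = _aggregate_importance(imp, predictors, site_levels)

    return TrainedForest(
        forest=rf,
        config=config,
        predictors=predictors,
        site_levels=site_levels,
        class_labels=list(classes),
        oob_error=oob_error,
        importance=importance,
    )


def _mean_decrease_gini(rf: RandomForestClassifier, n_train: int) -> np.ndarray:
    """Unnormalized per-column impurity decrease, averaged over trees and
    scaled to sample counts (the conventional mean-decrease-Gini units)."""
    per_tree = [
        est.tree_.compute_feature_importances(normalize=False)
        for est in rf.estimators_
    ]
    return np.mean(per_tree, axis=0) * n_train


def _aggregate_importance(
    imp: np.ndarray, predictors: Sequence[str], site_levels: Sequence[str]
) -> pd.Series:
    names = _expanded_names(predictors, site_levels)
    s = pd.Series(imp, index=names)
    if site_levels:
        site_cols = [f"Site={lev}" for lev in site_levels]
        site_total = s[site_cols].sum()
        s = s.drop(site_cols)
        s["Site"] = site_total
    return s.reindex(predictors)


def predict_species(model: TrainedForest, table: pd.DataFrame) -> pd.DataFrame:
    """Per-row majority-vote prediction with per-class vote fractions.

    Ties break to the first label in ``class_labels`` order.  Returns a
    DataFrame with a ``predicted`` column and one ``vote_<class>`` column
    per class; vote fractions sum to 1 per row.
    """
    if table.empty:
        cols = ["predicted"] + [f"vote_{c}" for c in model.class_labels]
        return pd.DataFrame(columns=cols)
    _check_schema(model, table)
    X = _encode(table, model.predictors, model.site_levels)
    ntree = len(model.forest.estimators_)
    votes = np.zeros((len(table), len(model.class_labels)))
    label_pos = {lab: k for k, lab in enumerate(model.class_labels)}
    sk_to_pos = np.array([label_pos[c] for c in model.forest.classes_])
    row_idx = np.arange(len(table))
    for est in model.forest.estimators_:
        pred_idx = est.predict(X).astype(int)
        votes[row_idx, sk_to_pos[pred_idx]] += 1
    frac = votes / ntree
    winners = [model.class_labels[int(np.argmax(row))] for row in frac]
    out = pd.DataFrame({"predicted": winners}, index=table.index)
    for k, lab in enumerate(model.class_labels):
        out[f"vote_{lab}"] = frac[:, k]
    return out


def tune_forest(
    train: pd.DataFrame,
    ntree_grid: Sequence[int],
    mtry_grid: Sequence[int],
    rng_seed: int = 0,
    predictors: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, ForestConfig]:
    """Grid search over (ntree, mtry) by OOB error on shared data.

    Best = lowest oob_error; ties resolve to smaller ntree, then smaller
    mtry.  Returns the full grid as a DataFrame plus the winning config.
    """
    if not len(ntree_grid) or not len(mtry_grid):
        raise ValueError("ntree_grid and mtry_grid must be non-empty")
    rows = []
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            cfg = ForestConfig(ntree=int(ntree), mtry=int(mtry), rng_seed=rng_seed)
            model = train_forest(train, cfg, predictors=predictors)
            rows.append({"ntree": int(ntree), "mtry": int(mtry),
                         "oob_error": model.oob_error})
    grid = pd.DataFrame(rows)
    best = grid.sort_values(["oob_error", "ntree", "mtry"]).iloc[0]
    best_cfg = ForestConfig(
        ntree=int(best["ntree"]), mtry=int(best["mtry"]), rng_seed=rng_seed
    )
    return grid, best_cfg


def importance_filter_refit(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model: TrainedForest,
    threshold: float,
) -> tuple[List[str], float, TrainedForest]:
    """Refit keeping only predictors with mean-decrease-Gini above
    ``threshold``; returns (retained predictors, refit test accuracy,
    refit model).  The importance scale grows with n, so quantile-style
    thresholds (percentile of the importance vector) are often more
    portable than absolute units.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:  # no-op filter: keep everything, even never-split predictors
        retained = list(model.predictors)
    else:
        retained = [p for p in model.predictors if model.importance[p] > threshold]
    if not retained:
        raise ValueError(
            f"no predictor has importance > {threshold}; "
            f"max is {model.importance.max():.3g} — lower the threshold"
        )
    cfg = model.config
    mtry = min(cfg.resolved_mtry(model.p), len(retained))
    refit_cfg = ForestConfig(
        ntree=cfg.ntree, mtry=mtry, min_node_size=cfg.min_node_size,
        rng_seed=cfg.rng_seed, class_labels=model.class_labels,
    )
    refit = train_forest(train, refit_cfg, predictors=retained)
    calls = predict_species(refit, test)
    accuracy = float(
        (calls["predicted"].to_numpy() == test[RESPONSE_COLUMN].to_numpy()).mean()
    )
    return retained, accuracy, refit


def save_model(model: TrainedForest, path: str) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "config": model.config,
        "predictors": model.predictors,
        "site_levels": model.site_levels,
        "class_labels": model.class_labels,
        "oob_error": model.oob_error,
        "importance": model.importance,
    }
    joblib.dump(payload, path)


def load_model(path: str) -> TrainedForest:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format {payload.get('format_version')!r}"
        )
    return TrainedForest(
        forest=payload["forest"],
        config=payload["config"],
        predictors=payload["predictors"],
        site_levels=payload["site_levels"],
        class_labels=payload["class_labels"],
        oob_error=payload["oob_error"],
        importance=payload["importance"],
    )
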