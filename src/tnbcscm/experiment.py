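"""The repeated-holdout protocol and feature-stability counting.

The discriminative-gene analysis is a resampling protocol rather than a
single fit: the cohort is split into a stratified 80%/20% train/test pair,
three learners (Set Covering Machine, decision tree, random forest) are
tuned and fitted on the training split and evaluated on the held-out
split, and the whole procedure is repeated (100 times at full scale) with
fresh splits. Per algorithm, the ten models with the best held-out F1 are
retained and the attributes they rely on are counted — an SCM conjunction
contributes every attribute in its rules; trees and forests contribute
their first three distinct features in breadth-first order from the root
(per tree for a forest, deduplicated per model). Counts are rolled up from
isoform attributes to genes (a gene is as supported as its best isoform)
and each counted attribute receives a direction-of-regulation call from
its class means: up- or down-regulated in TNBC relative to non-TNBC.

Everything is a pure function of (data, RepeatConfig): per-repeat seeds
are spawned from the master seed, so the full experiment — including the
final feature-count table — is bit-reproducible.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricSet, compute_metrics, confusion_counts
from .scm import SCMModel, cross_validate_scm, predict_scm
from .views import FeatureSpace

__all__ = [
    "RepeatConfig",
    "RepeatResult",
    "split_train_test",
    "run_experiment",
    "select_best_models",
    "extract_model_features",
    "tree_first_features",
    "count_features",
    "gene_count_table",
    "direction_of_regulation",
]

Algorithm = Literal["scm", "dt", "rf"]


@dataclass(frozen=True)
class RepeatConfig:
    """Protocol parameters; defaults follow the full-scale design
    (100 repeats of an 80/20 split, ten best models per algorithm, F1
    selection)."""

    n_repeats: int = 100
    train_fraction: float = 0.8
    algorithms: tuple[Algorithm, ...] = ("scm", "dt", "rf")
    selection_metric: Literal["f1", "accuracy"] = "f1"
    k_best: int = 10
    master_seed: int = 0
    scm_p_grid: tuple[float, ...] = (0.1, 0.316, 1.0, 3.16, 10.0)
    scm_s_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    cv_folds: int = 5
    rf_n_estimators: int = 100
    n_tree_features: int = 3
    tree_feature_order: Literal["breadth_first", "depth_first"] = "breadth_first"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_best > self.n_repeats:
            raise ValueError("k_best cannot exceed n_repeats")
        unknown = set(self.algorithms) - {"scm", "dt", "rf"}
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")


@dataclass
class RepeatResult:
    repeat_index: int
    algorithm: Algorithm
    model: Any
    hyperparameters: dict
    train_metrics: MetricSet
    test_metrics: MetricSet
    model_features: list[str]


def split_train_test(
    labels: Sequence[int], train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified holdout split; returns (train_indices, test_indices).

    Per class, floor(fraction * n_class) samples go to the training set;
    the leftover slots (so that the global train size is
    round(fraction * n)) are granted to classes by largest fractional
    remainder. Which samples land where is decided by a seeded shuffle
    within each class; the split is disjoint, exhaustive and deterministic
    per seed.
    """
    y = np.asarray(labels).astype(int)
    n = y.shape[0]
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"class(es) {small} have fewer than 2 samples")
    n_train_total = int(np.floor(train_fraction * n + 0.5))
    exact = {c: train_fraction * m for c, m in zip(classes, counts)}
    take = {c: int(np.floor(exact[c])) for c in classes}
    leftover = n_train_total - sum(take.values())
    order = sorted(classes, key=lambda c: (-(exact[c] - take[c]), -exact[c], c))
    for c in order[:leftover]:
        take[c] += 1
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.shape[0])]
        train_parts.append(idx[: take[c]])
        test_parts.append(idx[take[c] :])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def tree_first_features(
    tree, attribute_ids: Sequence[str], k: int = 3, order: str = "breadth_first"
) -> list[str]:
    """First ``k`` distinct split attributes of a fitted sklearn tree.

    Traversal starts at the root; breadth-first (default) visits split
    nodes level by level, so the returned attributes are the splits closest
    to the root — the most informative ones under CART's greedy criterion.
    """
    t = tree.tree_
    found: list[str] = []
    stack: deque[int] = deque([0])
    while stack and len(found) < k:
        node = stack.popleft() if order == "breadth_first" else stack.pop()
        if t.children_left[node] == -1:  # leaf
            continue
        attr = attribute_ids[t.feature[node]]
        if attr not in found:
            found.append(attr)
        children = (t.children_left[node], t.children_right[node])
        if order == "breadth_first":
            stack.extend(children)
        else:
            stack.extend(reversed(children))
    return found


def extract_model_features(result: RepeatResult, config: RepeatConfig | None = None) -> list[str]:
    """Attributes a fitted model relies on, per the counting convention.

    SCM: every attribute in the conjunction, in greedy selection order.
    Decision tree: first three distinct attributes breadth-first from the
    root. Random forest: the per-tree first-three sets pooled (deduplicated)
    over the forest.
    """
    cfg = config or RepeatConfig()
    return _model_features(result.algorithm, result.model, result.model_features, cfg)


def _model_features(
    algorithm: str, model: Any, attribute_ids: Sequence[str], cfg: RepeatConfig
) -> list[str]:
    if model is None:
        raise ValueError("model is not fitted")
    if algorithm == "scm":
        return model.attributes
    if algorithm == "dt":
        return tree_first_features(
            model, attribute_ids, cfg.n_tree_features, cfg.tree_feature_order
        )
    if algorithm == "rf":
        pooled: dict[str, None] = {}
        for est in model.estimators_:
            for a in tree_first_features(
                est, attribute_ids, cfg.n_tree_features, cfg.tree_feature_order
            ):
                pooled.setdefault(a, None)
        return list(pooled)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _child_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    feature_space: FeatureSpace | np.ndarray,
    labels: Sequence[int],
    config: RepeatConfig = RepeatConfig(),
    attribute_ids: Sequence[str] | None = None,
) -> list[RepeatResult]:
    """Run the repeated-holdout protocol; one RepeatResult per (repeat, algorithm).

    Per repeat, the split seed and every learner seed derive from the master
    seed, hyperparameters are selected on the training split only (the SCM
    by stratified CV over its (p, s) grid; tree and forest use fixed library
    settings with a per-repeat random state), and metrics are computed on
    both splits. Test samples never influence fitting.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.tree import DecisionTreeClassifier

    if isinstance(feature_space, FeatureSpace):
        X = feature_space.values
        attribute_ids = feature_space.attribute_ids
    else:
        X = np.asarray(feature_space, dtype=float)
        if attribute_ids is None:
            attribute_ids = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels).astype(int)

    results: list[RepeatResult] = []
    for r in range(config.n_repeats):
        split_seed = _child_seed(config.master_seed, r, 0)
        train_idx, test_idx = split_train_test(y, config.train_fraction, split_seed)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]
        for a, algorithm in enumerate(config.algorithms):
            algo_seed = _child_seed(config.master_seed, r, 1 + a)
            try:
                if algorithm == "scm":
                    model, hyper = cross_validate_scm(
                        Xtr,
                        ytr,
                        p_grid=config.scm_p_grid,
                        s_grid=config.scm_s_grid,
                        n_folds=config.cv_folds,
                        seed=algo_seed,
                        attribute_ids=attribute_ids,
                    )
                    pred_tr = predict_scm(model, Xtr, attribute_ids)
                    pred_te = predict_scm(model, Xte, attribute_ids)
                elif algorithm == "dt":
                    model = DecisionTreeClassifier(random_state=algo_seed)
                    model.fit(Xtr, ytr)
                    hyper = {"random_state": algo_seed}
                    pred_tr, pred_te = model.predict(Xtr), model.predict(Xte)
                else:
                    model = RandomForestClassifier(
                        n_estimators=config.rf_n_estimators, random_state=algo_seed
                    )
                    model.fit(Xtr, ytr)
                    hyper = {
                        "n_estimators": config.rf_n_estimators,
                        "random_state": algo_seed,
                    }
                    pred_tr, pred_te = model.predict(Xtr), model.predict(Xte)
            except Exception as exc:
                raise RuntimeError(
                    f"repeat {r}, algorithm {algorithm}: fit failed"
                ) from exc
            features = _model_features(algorithm, model, attribute_ids, config)
            results.append(
                RepeatResult(
                    repeat_index=r,
                    algorithm=algorithm,
                    model=model,
                    hyperparameters=hyper,
                    train_metrics=compute_metrics(confusion_counts(ytr, pred_tr)),
                    test_metrics=compute_metrics(confusion_counts(yte, pred_te)),
                    model_features=features,
                )
            )
    return results


def select_best_models(
    results: Sequence[RepeatResult],
    k_best: int = 10,
    selection_metric: str = "f1",
) -> list[RepeatResult]:
    """Per algorithm, the ``k_best`` models with the best held-out metric.

    Ties break by held-out accuracy, then by lower repeat index.
    """
    selected: list[RepeatResult] = []
    for algorithm in dict.fromkeys(r.algorithm for r in results):
        pool = [r for r in results if r.algorithm == algorithm]
        if len(pool) < k_best:
            raise ValueError(
                f"{algorithm}: {len(pool)} results but k_best={k_best}"
            )
        pool.sort(
            key=lambda r: (
                -getattr(r.test_metrics, selection_metric),
                -r.test_metrics.accuracy,
                r.repeat_index,
            )
        )
        selected.extend(pool[:k_best])
    return selected


def direction_of_regulation(
    column: np.ndarray, labels: Sequence[int]
) -> tuple[str, float, float]:
    """Direction call for one attribute: mean in TNBC vs mean in non-TNBC.

    Returns (direction, mean_tnbc, mean_non_tnbc) with direction
    ``up_in_tnbc`` / ``down_in_tnbc`` / ``unchanged``.
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present for a direction call")
    v = np.asarray(column, dtype=float)
    mean_tnbc = float(v[y].mean())
    mean_non = float(v[~y].mean())
    if mean_tnbc > mean_non:
        direction = "up_in_tnbc"
    elif mean_tnbc < mean_non:
        direction = "down_in_tnbc"
    else:
        direction = "unchanged"
    return direction, mean_tnbc, mean_non


def count_features(
    selected: Sequence[RepeatResult],
    feature_space: FeatureSpace,
    labels: Sequence[int],
) -> pd.DataFrame:
    """Attribute-level feature-count table over the selected models.

    Each model contributes each of its distinct attributes once. Columns:
    attribute_id, gene_symbol, view, count, direction, mean_tnbc,
    mean_non_tnbc; sorted by count descending, then gene symbol, then
    attribute id.
    """
    if not selected:
        raise ValueError("no selected models to count over")
    counts: dict[str, int] = {}
    for r in selected:
        for a in dict.fromkeys(r.model_features):
            counts[a] = counts.get(a, 0) + 1
    rows = []
    for attr, cnt in counts.items():
        info = feature_space.registry.get(attr)
        j = feature_space.column_index(attr)
        direction, m_tnbc, m_non = direction_of_regulation(
            feature_space.values[:, j], labels
        )
        rows.append(
            {
                "attribute_id": attr,
                "gene_symbol": (info.gene if info else None) or attr,
                "view": info.view if info else "",
                "count": cnt,
                "direction": direction,
                "mean_tnbc": m_tnbc,
                "mean_non_tnbc": m_non,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["count", "gene_symbol", "attribute_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def gene_count_table(attribute_counts: pd.DataFrame) -> pd.DataFrame:
    """Roll attribute counts up to genes: a gene scores its best isoform.

    The gene-level count is the max over the gene's attributes; direction
    and class means are taken from that best-supported attribute.
    """
    best = (
        attribute_counts.sort_values(
            ["gene_symbol", "count", "attribute_id"], ascending=[True, False, True]
        )
        .groupby("gene_symbol", as_index=False)
        .first()
    )
    return (
        best[
            [
                "gene_symbol",
                "view",
                "count",
                "direction",
                "mean_tnbc",
                "mean_non_tnbc",
                "attribute_id",
            ]
        ]
        .sort_values(["count", "gene_symbol"], ascending=[False, True])
        .reset_index(drop=True)
    )
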