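"""The Set Covering Machine (SCM): greedy conjunctions of threshold rules.

The SCM learns a conjunction (or disjunction) of boolean threshold rules
("rays"): single-attribute predicates of the form ``x[a] <= t`` or
``x[a] > t``. Writing P for the positive training examples and N for the
negatives, each greedy step scores every candidate rule h by the utility

    U_h = |N_h| - p * |Pbar_h|

where N_h is the set of not-yet-covered negatives the rule classifies
correctly (for a conjunction: negatives on which the rule is false) and
Pbar_h the still-active positives it misclassifies. The rule maximizing U
is appended, the negatives it covers and the positives it sacrifices are
removed, and the loop stops when no negatives remain, when ``s`` rules have
been chosen (early stopping), or when no rule has positive utility. The
penalty ``p >= 0`` trades covered negatives against sacrificed positives;
``s >= 1`` caps model size. The result is a sparse, human-readable
classifier whose attributes are directly interpretable as discriminative
features.

Candidate thresholds are the midpoints between consecutive distinct sorted
training values of each attribute, in both directions; constant attributes
yield no rules. Ties in utility are broken deterministically: larger
|N_h|, then smaller attribute index, then smaller threshold, then the
"<=" direction.

A disjunction is learned by running the conjunction algorithm on the
complemented labels and complementing the returned rules (De Morgan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ThresholdRule",
    "TraceStep",
    "SCMModel",
    "CoverageState",
    "build_rays",
    "rule_utility",
    "fit_scm",
    "predict_scm",
    "save_model",
    "load_model",
    "cross_validate_scm",
    "DEFAULT_P_GRID",
    "DEFAULT_S_GRID",
]

ModelType = Literal["conjunction", "disjunction"]

#: Hyperparameter grid searched by :func:`cross_validate_scm` (half-decade
#: spaced penalties; model sizes 1..5).
DEFAULT_P_GRID: tuple[float, ...] = (0.1, 0.316, 1.0, 3.16, 10.0)
DEFAULT_S_GRID: tuple[int, ...] = (1, 2, 3, 4, 5)

_CHUNK = 4096  # columns scored per block, bounds peak memory in the greedy scan


@dataclass(frozen=True)
class ThresholdRule:
    """Boolean predicate on one attribute: value <= threshold, or value > it."""

    attribute: str
    threshold: float
    direction: Literal["leq", "gt"]

    def evaluate(self, column: np.ndarray) -> np.ndarray:
        if self.direction == "leq":
            return np.asarray(column) <= self.threshold
        return np.asarray(column) > self.threshold

    def complement(self) -> "ThresholdRule":
        return ThresholdRule(
            self.attribute,
            self.threshold,
            "gt" if self.direction == "leq" else "leq",
        )

    def __str__(self) -> str:
        op = "<=" if self.direction == "leq" else ">"
        return f"{self.attribute} {op} {self.threshold:g}"


@dataclass(frozen=True)
class TraceStep:
    rule: ThresholdRule
    utility: float
    n_covered_negatives: int
    n_sacrificed_positives: int


@dataclass
class SCMModel:
    model_type: ModelType
    rules: list[ThresholdRule]
    penalty_p: float
    stopping_s: int
    training_trace: list[TraceStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rules) > self.stopping_s:
            raise ValueError("more rules than the early-stopping point allows")

    @property
    def attributes(self) -> list[str]:
        """Attributes used, in selection order, without duplicates."""
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.attribute, None)
        return list(seen)

    def prefix(self, k: int) -> "SCMModel":
        """The model truncated to its first ``k`` greedy rules."""
        return SCMModel(
            model_type=self.model_type,
            rules=self.rules[:k],
            penalty_p=self.penalty_p,
            stopping_s=self.stopping_s,
            training_trace=self.training_trace[:k],
        )


@dataclass
class CoverageState:
    """Greedy bookkeeping: negatives not yet covered, positives not sacrificed."""

    remaining_negatives: np.ndarray  # boolean mask over training samples
    active_positives: np.ndarray

    def __post_init__(self) -> None:
        if (self.remaining_negatives & self.active_positives).any():
            raise ValueError("coverage sets must be disjoint")


def build_rays(
    X: np.ndarray, attribute_ids: Sequence[str] | None = None
) -> list[ThresholdRule]:
    """Enumerate every candidate threshold rule over a training matrix.

    Per attribute: thresholds at the midpoints between consecutive distinct
    sorted values, each in both directions. Constant attributes yield none.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a non-empty 2-D training matrix")
    if attribute_ids is None:
        attribute_ids = [f"x{j}" for j in range(X.shape[1])]
    rays = []
    for j, attr in enumerate(attribute_ids):
        distinct = np.unique(X[:, j])
        for t in (distinct[:-1] + distinct[1:]) / 2.0:
            rays.append(ThresholdRule(attr, float(t), "leq"))
            rays.append(ThresholdRule(attr, float(t), "gt"))
    return rays


def rule_utility(
    rule: ThresholdRule,
    column: np.ndarray,
    state: CoverageState,
    penalty_p: float,
) -> tuple[float, int, int]:
    """(U, |N_h|, |Pbar_h|) of one rule for a conjunction step.

    ``column`` holds the rule's attribute over the training samples. A
    conjunction predicts negative as soon as one rule is false, so the rule
    handles correctly the remaining negatives on which it is false, and
    misclassifies the active positives on which it is false.
    """
    false_on = ~rule.evaluate(column)
    n_h = int((false_on & state.remaining_negatives).sum())
    pbar_h = int((false_on & state.active_positives).sum())
    return n_h - penalty_p * pbar_h, n_h, pbar_h


class _SortedMatrix:
    """Per-column sort of the training matrix, reusable across greedy steps
    (and across penalties during cross-validation)."""

    def __init__(self, X: np.ndarray, chunk: int = _CHUNK):
        X = np.ascontiguousarray(X, dtype=float)
        self.n, self.d = X.shape
        self.chunks: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
        for start in range(0, self.d, chunk):
            block = X[:, start : start + chunk]
            order = np.argsort(block, axis=0, kind="stable")
            svals = np.take_along_axis(block, order, axis=0)
            boundary_ok = svals[1:] > svals[:-1] if self.n > 1 else np.zeros((0, block.shape[1]), bool)
            self.chunks.append((start, order, svals, boundary_ok))


def _best_rule(
    sm: _SortedMatrix,
    neg_mask: np.ndarray,
    pos_mask: np.ndarray,
    penalty_p: float,
) -> tuple[float, int, int, int, float, str] | None:
    """Single greedy step: argmax of U over all rays, with the deterministic
    tie-break (max U, max |N_h|, min attribute index, min threshold, leq first).

    Returns (U, N_h, Pbar_h, column, threshold, direction) or None when no
    attribute admits a threshold.
    """
    wn = neg_mask.astype(float)
    wp = pos_mask.astype(float)
    n_rem = wn.sum()
    p_act = wp.sum()
    best: tuple | None = None  # sort key: (-U, -N, col, threshold, dir_rank)
    for start, order, svals, boundary_ok in sm.chunks:
        if boundary_ok.size == 0 or not boundary_ok.any():
            continue
        cn = np.cumsum(wn[order], axis=0)[:-1]
        cp = np.cumsum(wp[order], axis=0)[:-1]
        thresholds = (svals[:-1] + svals[1:]) / 2.0
        # direction "leq": rule false where value > t  -> counts above the cut
        # direction "gt":  rule false where value <= t -> counts below the cut
        for dir_rank, (N, P) in enumerate(
            ((n_rem - cn, p_act - cp), (cn, cp))
        ):
            U = np.where(boundary_ok, N - penalty_p * P, -np.inf)
            u_max = U.max()
            if best is not None and u_max < -best[0]:
                continue
            cand = np.flatnonzero((U == u_max).ravel())
            Nf = N.ravel()[cand]
            cand = cand[Nf == Nf.max()]
            rows, cols = np.unravel_index(cand, U.shape)
            # smallest column, then smallest threshold within it
            jloc = cols.min()
            sel = cols == jloc
            rows, cols = rows[sel], cols[sel]
            t_loc = thresholds[rows, cols]
            i = int(np.argmin(t_loc))
            key = (
                -float(u_max),
                -float(N[rows[i], cols[i]]),
                start + int(jloc),
                float(t_loc[i]),
                dir_rank,
            )
            if best is None or key < best:
                best = key + (float(P[rows[i], cols[i]]),)
    if best is None:
        return None
    neg_u, neg_n, col, threshold, dir_rank, pbar = best
    return (
        -neg_u,
        int(-neg_n),
        int(pbar),
        col,
        threshold,
        "leq" if dir_rank == 0 else "gt",
    )


def _fit_conjunction(
    X: np.ndarray,
    y: np.ndarray,
    penalty_p: float,
    stopping_s: int,
    attribute_ids: Sequence[str],
    sorted_matrix: _SortedMatrix | None = None,
) -> tuple[list[ThresholdRule], list[TraceStep]]:
    pos = y.astype(bool)
    neg = ~pos
    sm = sorted_matrix if sorted_matrix is not None else _SortedMatrix(X)
    remaining = neg.copy()
    active = pos.copy()
    rules: list[ThresholdRule] = []
    trace: list[TraceStep] = []
    while remaining.any() and len(rules) < stopping_s:
        found = _best_rule(sm, remaining, active, penalty_p)
        if found is None:
            break
        U, n_h, pbar_h, col, threshold, direction = found
        if U <= 0:
            break
        rule = ThresholdRule(attribute_ids[col], threshold, direction)  # type: ignore[arg-type]
        rules.append(rule)
        trace.append(TraceStep(rule, U, n_h, pbar_h))
        false_on = ~rule.evaluate(X[:, col])
        remaining &= ~false_on
        active &= ~false_on
    return rules, trace


def fit_scm(
    X: np.ndarray,
    y: Sequence[int],
    penalty_p: float = 1.0,
    stopping_s: int = 5,
    model_type: ModelType = "conjunction",
    attribute_ids: Sequence[str] | None = None,
    _sorted_matrix: _SortedMatrix | None = None,
) -> SCMModel:
    """Greedily fit a Set Covering Machine.

    Parameters
    ----------
    X, y
        Training matrix (samples x attributes) and binary labels; both
        classes must be present.
    penalty_p
        Utility penalty ``p`` on sacrificed positives.
    stopping_s
        Early-stopping point ``s``: maximum number of rules.
    model_type
        ``"conjunction"`` predicts positive iff every rule holds;
        ``"disjunction"`` iff any rule holds (learned on complemented
        labels, rules complemented on output).
    attribute_ids
        Names for the columns; defaults to ``x0, x1, ...``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes are inconsistent")
    if penalty_p < 0:
        raise ValueError("penalty_p must be >= 0")
    if stopping_s < 1:
        raise ValueError("stopping_s must be >= 1")
    classes = set(np.unique(y).tolist())
    if not classes <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("training data holds a single class; both are required")
    if attribute_ids is None:
        attribute_ids = [f"x{j}" for j in range(X.shape[1])]
    if len(attribute_ids) != X.shape[1]:
        raise ValueError("attribute_ids length does not match matrix width")

    fit_y = y if model_type == "conjunction" else 1 - y
    rules, trace = _fit_conjunction(
        X, fit_y, penalty_p, stopping_s, attribute_ids, _sorted_matrix
    )
    if model_type == "disjunction":
        rules = [r.complement() for r in rules]
        trace = [
            TraceStep(r, t.utility, t.n_covered_negatives, t.n_sacrificed_positives)
            for r, t in zip(rules, trace)
        ]
    return SCMModel(
        model_type=model_type,
        rules=rules,
        penalty_p=penalty_p,
        stopping_s=stopping_s,
        training_trace=trace,
    )


def predict_scm(
    model: SCMModel,
    X: np.ndarray,
    attribute_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Binary predictions; conjunction = AND of rules, disjunction = OR.

    An empty conjunction is vacuously true (all positive); an empty
    disjunction predicts all positive as well, being the complement of the
    empty conjunction on complemented labels.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if attribute_ids is None:
        attribute_ids = [f"x{j}" for j in range(X.shape[1])]
    col = {a: j for j, a in enumerate(attribute_ids)}
    if model.model_type == "conjunction":
        out = np.ones(X.shape[0], dtype=bool)
    else:
        out = (
            np.zeros(X.shape[0], dtype=bool)
            if model.rules
            else np.ones(X.shape[0], dtype=bool)
        )
    for rule in model.rules:
        if rule.attribute not in col:
            raise KeyError(f"unknown attribute {rule.attribute!r} in prediction data")
        holds = rule.evaluate(X[:, col[rule.attribute]])
        out = (out & holds) if model.model_type == "conjunction" else (out | holds)
    return out.astype(int)


# ---------------------------------------------------------------------------
# hyperparameter selection


def cross_validate_scm(
    X: np.ndarray,
    y: Sequence[int],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    s_grid: Sequence[int] = DEFAULT_S_GRID,
    n_folds: int = 5,
    seed: int = 0,
    model_type: ModelType = "conjunction",
    attribute_ids: Sequence[str] | None = None,
) -> tuple[SCMModel, dict]:
    """Stratified k-fold CV over (p, s); refit the winner on all the data.

    F1 on the held-out folds is the selection score (the positive class is
    the minority of interest, so F1 is preferred over accuracy on this
    imbalanced problem). For a fixed penalty the greedy rule sequence does
    not depend on ``s``, so each fold is fitted once per penalty at
    ``max(s_grid)`` and the smaller model sizes are scored as prefixes.
    Ties prefer the sparser model (smaller s), then the smaller penalty.
    """
    from sklearn.model_selection import StratifiedKFold

    from .metrics import compute_metrics, confusion_counts

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    s_max = max(s_grid)
    n_folds = min(n_folds, int(np.bincount(y, minlength=2).min()))
    if n_folds < 2:
        raise ValueError("too few samples in a class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = {(p, s): 0.0 for p in p_grid for s in s_grid}
    for train_idx, val_idx in skf.split(X, y):
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]
        sm = _SortedMatrix(Xtr)
        for p in p_grid:
            full = fit_scm(
                Xtr, ytr, p, s_max, model_type, attribute_ids, _sorted_matrix=sm
            )
            for s in s_grid:
                pred = predict_scm(full.prefix(min(s, len(full.rules))), Xval, attribute_ids)
                f1 = compute_metrics(confusion_counts(yval, pred)).f1
                scores[(p, s)] += f1 / n_folds
    best_p, best_s = min(scores, key=lambda ps: (-scores[ps], ps[1], ps[0]))
    model = fit_scm(X, y, best_p, best_s, model_type, attribute_ids)
    return model, {"p": best_p, "s": best_s, "cv_f1": scores[(best_p, best_s)]}


# ---------------------------------------------------------------------------
# serialization


def save_model(model: SCMModel, path) -> None:
    """Human-readable rule listing plus an exact JSON sidecar (``path + ".json"``)."""
    lines = [
        f"# set covering machine ({model.model_type}), "
        f"p={model.penalty_p:g}, s={model.stopping_s}",
        "attribute\tdirection\tthreshold",
    ]
    for r in model.rules:
        lines.append(f"{r.attribute}\t{r.direction}\t{r.threshold!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    payload = {
        "model_type": model.model_type,
        "penalty_p": model.penalty_p,
        "stopping_s": model.stopping_s,
        "rules": [
            {"attribute": r.attribute, "direction": r.direction, "threshold": r.threshold}
            for r in model.rules
        ],
        "trace": [
            {
                "utility": t.utility,
                "n_covered_negatives": t.n_covered_negatives,
                "n_sacrificed_positives": t.n_sacrificed_positives,
            }
            for t in model.training_trace
        ],
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> SCMModel:
    with open(f"{path}.json") as fh:
        payload = json.load(fh)
    rules = [
        ThresholdRule(r["attribute"], r["threshold"], r["direction"])
        for r in payload["rules"]
    ]
    trace = [
        TraceStep(rule, t["utility"], t["n_covered_negatives"], t["n_sacrificed_positives"])
        for rule, t in zip(rules, payload["trace"])
    ]
    return SCMModel(
        model_type=payload["model_type"],
        rules=rules,
        penalty_p=payload["penalty_p"],
        stopping_s=payload["stopping_s"],
        training_trace=trace,
    )
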