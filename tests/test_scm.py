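"""Set Covering Machine: ray construction, utility, greedy fit, prediction.

The greedy step is checked against an exhaustive brute-force maximization
of the utility over every candidate ray, replicating the documented
tie-break (max U, max |N_h|, min attribute index, min threshold, "<="
first) so agreement is exact, not merely up to ties.
"""

import numpy as np
import pytest

from tnbcscm.cohort import CohortConfig, generate_cohort
from tnbcscm.scm import (
    CoverageState,
    SCMModel,
    ThresholdRule,
    build_rays,
    cross_validate_scm,
    fit_scm,
    load_model,
    predict_scm,
    rule_utility,
    save_model,
)


def brute_force_step(X, remaining, active, p, attribute_ids=None):
    """Exhaustive argmax of U over all rays, with the documented tie-break."""
    if attribute_ids is None:
        attribute_ids = [f"x{j}" for j in range(X.shape[1])]
    state = CoverageState(remaining.copy(), active.copy())
    attr_index = {a: j for j, a in enumerate(attribute_ids)}
    best = None
    for ray in build_rays(X, attribute_ids):
        j = attr_index[ray.attribute]
        U, n_h, _ = rule_utility(ray, X[:, j], state, p)
        key = (-U, -n_h, j, ray.threshold, 0 if ray.direction == "leq" else 1)
        if best is None or key < best[0]:
            best = (key, ray, U)
    return best  # None when no attribute admits a ray


def brute_force_greedy(X, y, p, s, attribute_ids=None):
    """Reference greedy conjunction built only from build_rays + rule_utility."""
    pos = np.asarray(y).astype(bool)
    remaining, active = (~pos).copy(), pos.copy()
    rules = []
    if attribute_ids is None:
        attribute_ids = [f"x{j}" for j in range(X.shape[1])]
    attr_index = {a: j for j, a in enumerate(attribute_ids)}
    while remaining.any() and len(rules) < s:
        found = brute_force_step(X, remaining, active, p, attribute_ids)
        if found is None or found[2] <= 0:
            break
        _, ray, _ = found
        rules.append(ray)
        false_on = ~ray.evaluate(X[:, attr_index[ray.attribute]])
        remaining &= ~false_on
        active &= ~false_on
    return rules


class TestRays:
    def test_midpoints_both_directions(self):
        X = np.array([[1.0], [3.0], [5.0]])
        rays = build_rays(X)
        assert len(rays) == 4
        assert {(r.threshold, r.direction) for r in rays} == {
            (2.0, "leq"), (2.0, "gt"), (4.0, "leq"), (4.0, "gt"),
        }

    def test_constant_attribute_yields_no_rules(self):
        assert build_rays(np.array([[7.0], [7.0], [7.0]])) == []

    def test_ray_count_formula(self, rng):
        # 2 attributes x 2 directions x (4 distinct - 1) thresholds
        col = rng.permutation(np.repeat([1.0, 2.0, 5.0, 9.0], 2))
        X = np.column_stack([col, rng.permutation(col)])
        assert len(build_rays(X)) == 2 * 2 * 3


class TestUtility:
    def setup_method(self):
        self.state = CoverageState(
            remaining_negatives=np.array([False, False, False, True, True, True]),
            active_positives=np.array([True, True, True, False, False, False]),
        )
        self.col = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])

    def test_perfect_rule_scores_all_negatives(self):
        U, n_h, pbar = rule_utility(ThresholdRule("x0", 5.0, "leq"), self.col, self.state, 1.0)
        assert (U, n_h, pbar) == (3.0, 3, 0)

    def test_penalty_formula(self):
        # rule x <= 8.5 misses only the last negative; flip to "gt" to make mistakes
        U, n_h, pbar = rule_utility(ThresholdRule("x0", 2.5, "gt"), self.col, self.state, 1.0)
        assert n_h == 0 and pbar == 2
        assert U == 0 - 1.0 * 2

    def test_zero_penalty_ignores_positive_mistakes(self):
        U, n_h, pbar = rule_utility(ThresholdRule("x0", 0.5, "leq"), self.col, self.state, 0.0)
        assert pbar == 3 and U == n_h == 3


class TestFit:
    def test_separable_single_rule(self):
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = fit_scm(X, y, penalty_p=1.0, stopping_s=2)
        assert len(model.rules) == 1
        rule = model.rules[0]
        assert rule.direction == "leq" and 3.0 < rule.threshold < 7.0
        assert np.array_equal(predict_scm(model, X), y)
        # brute force confirms a single ray attains U = 3 with no mistakes
        ref = brute_force_greedy(X, y, 1.0, 2)
        assert ref == model.rules

    def test_early_stopping_caps_rules(self, rng):
        X = rng.normal(size=(40, 5))
        y = (rng.random(40) < 0.4).astype(int)
        model = fit_scm(X, y, penalty_p=0.5, stopping_s=1)
        assert len(model.rules) <= 1

    def test_two_rule_conjunction_on_corner_layout(self):
        # positives occupy the low-x0 high-x1 corner: no single ray separates,
        # a conjunction of two rays does (verified exhaustively below)
        X = np.array(
            [
                [1.0, 8.0], [2.0, 9.0], [1.5, 7.5],           # positives
                [6.0, 8.5], [7.0, 9.5], [1.2, 2.0], [2.5, 1.0], [6.5, 1.5],  # negatives
            ]
        )
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        single_ray_separates = any(
            np.array_equal(ray.evaluate(X[:, int(ray.attribute[1])]).astype(int), y)
            for ray in build_rays(X)
        )
        assert not single_ray_separates
        model = fit_scm(X, y, penalty_p=1.0, stopping_s=2)
        assert len(model.rules) == 2
        assert np.array_equal(predict_scm(model, X), y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_scm(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_monotone_negative_coverage(self, rng):
        X = rng.normal(size=(60, 6))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        model = fit_scm(X, y, penalty_p=1.0, stopping_s=5)
        for step in model.training_trace:
            assert step.n_covered_negatives > 0  # U > 0 requires covering something

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(25, 3))
        y = (rng.random(25) < 0.4).astype(int)
        if y.sum() in (0, 25):
            y[0] = 1 - y[0]
        base = fit_scm(X, y, 1.0, 3)
        Xs = X.copy()
        Xs[:, 1] *= 10.0
        scaled = fit_scm(Xs, y, 1.0, 3)
        assert len(base.rules) == len(scaled.rules)
        for rb, rs in zip(base.rules, scaled.rules):
            assert rb.attribute == rs.attribute and rb.direction == rs.direction
            factor = 10.0 if rb.attribute == "x1" else 1.0
            assert rs.threshold == pytest.approx(rb.threshold * factor)


class TestOracleEquivalence:
    """Greedy trace equals exhaustive utility maximization on small instances."""

    @pytest.mark.parametrize("trial", range(60))
    def test_random_small_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 13))
        d = int(rng.integers(1, 4))
        n_distinct = int(rng.integers(2, 7))
        X = rng.choice(np.arange(n_distinct, dtype=float), size=(n, d))
        y = (rng.random(n) < 0.4).astype(int)
        if y.sum() == 0:
            y[0] = 1
        if y.sum() == n:
            y[0] = 0
        p = float(rng.choice([0.1, 0.5, 1.0, 2.0]))
        s = int(rng.integers(1, 4))
        model = fit_scm(X, y, p, s)
        assert model.rules == brute_force_greedy(X, y, p, s)


class TestPredict:
    def test_conjunction_and_semantics(self):
        model = SCMModel(
            "conjunction",
            [ThresholdRule("x0", 5.0, "leq"), ThresholdRule("x1", 3.0, "gt")],
            1.0,
            2,
        )
        assert predict_scm(model, np.array([[4.0, 7.0]]))[0] == 1
        assert predict_scm(model, np.array([[4.0, 2.0]]))[0] == 0

    def test_empty_conjunction_vacuously_positive(self):
        model = SCMModel("conjunction", [], 1.0, 1)
        assert predict_scm(model, np.zeros((3, 2))).tolist() == [1, 1, 1]

    def test_unknown_attribute_errors(self):
        model = SCMModel("conjunction", [ThresholdRule("zz", 0.0, "leq")], 1.0, 1)
        with pytest.raises(KeyError, match="zz"):
            predict_scm(model, np.zeros((1, 2)))

    def test_disjunction_is_de_morgan_dual(self, rng):
        X = rng.normal(size=(20, 3))
        y = (rng.random(20) < 0.5).astype(int)
        if len(set(y.tolist())) < 2:
            y[0] = 1 - y[0]
        dis = fit_scm(X, y, 1.0, 3, model_type="disjunction")
        conj = fit_scm(X, 1 - y, 1.0, 3, model_type="conjunction")
        assert np.array_equal(predict_scm(dis, X), 1 - predict_scm(conj, X))
        assert [r.complement() for r in dis.rules] == conj.rules


def test_separable_planted_cohorts_reach_perfect_f1():
    """delta >= 3 planted signals: training F1 = 1 with <= 2 rules, >=95% of 20 seeds."""
    from tnbcscm.metrics import compute_metrics, confusion_counts

    wins = 0
    for seed in range(20):
        cfg = CohortConfig(
            n_samples=60,
            view_widths={"isoform": 60},
            isoforms_per_gene=3,
            n_planted_down=3,
            n_planted_up=2,
            effect_size=3.0,
            seed=seed,
        )
        cohort, _ = generate_cohort(cfg)
        view = cohort.views["isoform"]
        # a sacrifice-averse penalty: covering negatives must not cost positives
        model = fit_scm(view.values, cohort.labels, 5.0, 2, attribute_ids=view.attribute_ids)
        pred = predict_scm(model, view.values, view.attribute_ids)
        f1 = compute_metrics(confusion_counts(cohort.labels, pred)).f1
        if f1 == 1.0 and len(model.rules) <= 2:
            wins += 1
    assert wins >= 19  # 95% of 20


def test_cross_validation_selects_from_grid_and_prefix_property(rng):
    X = rng.normal(size=(60, 8))
    y = (X[:, 2] > 0.3).astype(int)
    model, hyper = cross_validate_scm(X, y, n_folds=3, seed=1)
    assert hyper["p"] in (0.1, 0.316, 1.0, 3.16, 10.0)
    assert 1 <= hyper["s"] <= 5
    # greedy path does not depend on s: fitting at s=2 equals the s=5 prefix
    full = fit_scm(X, y, 1.0, 5)
    short = fit_scm(X, y, 1.0, 2)
    assert short.rules == full.rules[:2]


def test_model_serialization_round_trips_exactly(tmp_path, rng):
    X = rng.normal(size=(30, 4))
    y = (X[:, 0] < -0.1).astype(int)
    if len(set(y.tolist())) < 2:
        y[0] = 1 - y[0]
    model = fit_scm(X, y, 0.316, 3)
    save_model(model, tmp_path / "model.txt")
    back = load_model(tmp_path / "model.txt")
    assert back.rules == model.rules
    assert back.penalty_p == model.penalty_p
    assert back.model_type == model.model_type
    assert [t.utility for t in back.training_trace] == [
        t.utility for t in model.training_trace
    ]
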