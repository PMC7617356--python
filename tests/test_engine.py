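"""Objectives, Pareto machinery and the evolutionary loop."""

import math

import numpy as np
import pandas as pd
import pytest

from mosr.engine import (EvolutionParams, Individual, ParetoFront,
                         crowding_distance, evolve, load_model,
                         non_dominated_sort, objectives, predict_probability,
                         save_model, select_final_model)
from mosr.cohort import make_fixture


def _individuals(points):
    return [Individual(("const", float(i)), objectives=tuple(p))
            for i, p in enumerate(points)]


# -- independent O(n^2) dominance oracle -----------------------------------

def _oracle_fronts(points):
    """Peel non-dominated layers by directly applying the dominance definition."""
    remaining = list(range(len(points)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                all(points[j][m] <= points[i][m] for m in range(2))
                and any(points[j][m] < points[i][m] for m in range(2))
                for j in remaining if j != i)
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestObjectives:
    def test_coin_flip_probabilities_give_ln2(self, small_matrix):
        X, y = small_matrix
        bce, _ = objectives(("const", 0.0), X, y)
        assert bce == pytest.approx(math.log(2), abs=1e-12)

    def test_single_case_hand_value(self):
        X = pd.DataFrame({"x1": [0.0, 0.0]})
        y = np.array([1, 0])
        # p = expit(logit(0.8)) = 0.8 for both rows
        logit = math.log(0.8 / 0.2)
        bce, _ = objectives(("const", logit), X, y)
        want = -(math.log(0.8) + math.log(0.2)) / 2
        assert bce == pytest.approx(want, rel=1e-12)

    def test_perfect_confident_predictions(self):
        X = pd.DataFrame({"x1": [-2.0, -1.0, 1.0, 2.0]})
        y = np.array([0, 0, 1, 1])
        # huge positive score iff x1 > 0 reproduces these labels exactly
        tree = ("if_greater", ("feat", "x1"), ("const", 0.0),
                ("const", 40.0), ("const", -40.0))
        bce, f1c = objectives(tree, X, y)
        assert bce < 1e-8 and f1c == 0.0

    def test_single_class_labels_error(self, small_matrix):
        X, _ = small_matrix
        with pytest.raises(ValueError, match="both outcome classes"):
            objectives(("const", 0.0), X, np.zeros(len(X), dtype=int))

    def test_probability_link(self, small_matrix):
        X, _ = small_matrix
        assert predict_probability(("const", 0.0), X)[0] == 0.5
        assert predict_probability(("const", 20.0), X)[0] > 0.999999
        tree = ("add", ("feat", "x1"), ("feat", "x2"))
        vec = predict_probability(tree, X)
        from mosr.trees import evaluate_expression
        from scipy.special import expit
        for i in range(5):
            raw = evaluate_expression(tree, {c: X[c].iloc[i] for c in X})
            assert vec[i] == pytest.approx(float(expit(raw)), rel=1e-12)


class TestParetoMachinery:
    def test_single_individual_single_front(self):
        fronts = non_dominated_sort(_individuals([(1.0, 1.0)]))
        assert len(fronts) == 1 and fronts[0][0].rank == 0

    def test_square_example(self):
        pts = [(1, 1), (2, 2), (1, 2), (2, 1)]
        inds = _individuals(pts)
        fronts = non_dominated_sort(inds)
        got = [sorted(tuple(i.objectives) for i in f) for f in fronts]
        assert got == [[(1, 1)], [(1, 2), (2, 1)], [(2, 2)]]

    def test_duplicates_share_a_front(self):
        inds = _individuals([(1.0, 2.0), (1.0, 2.0), (1.0, 2.0)])
        fronts = non_dominated_sort(inds)
        assert len(fronts) == 1 and len(fronts[0]) == 3

    def test_agrees_with_pairwise_oracle(self):
        rng = np.random.default_rng(19)
        for n in (5, 30, 120, 200):
            pts = rng.integers(0, 12, size=(n, 2)).astype(float).tolist()
            inds = _individuals(pts)
            fronts = non_dominated_sort(inds)
            got = [sorted(int(i.tree[1]) for i in f) for f in fronts]
            assert got == _oracle_fronts(pts)

    def test_crowding_small_front_is_infinite(self):
        for pts in ([(1.0, 1.0)], [(1.0, 2.0), (2.0, 1.0)]):
            assert crowding_distance(_individuals(pts)) == [np.inf] * len(pts)

    def test_crowding_collinear_middle_point(self):
        d = crowding_distance(_individuals([(0.0, 0.0), (1.0, 2.0), (2.0, 4.0)]))
        assert d[0] == np.inf and d[2] == np.inf
        assert d[1] == pytest.approx(2.0)  # half-range on each axis, twice

    def test_crowding_degenerate_axis(self):
        d = crowding_distance(_individuals([(0.0, 5.0), (1.0, 5.0), (2.0, 5.0)]))
        assert d[1] == pytest.approx(1.0)  # flat axis contributes nothing


class TestEvolve:
    def test_zero_generations_gives_empty_history(self, small_matrix):
        X, y = small_matrix
        front, hist = evolve(X, y, EvolutionParams(
            population_size=20, generations=0, seed=3))
        assert len(hist) == 0 and len(front) >= 1
        assert all(ind.rank == 0 for ind in front)

    def test_front_members_mutually_non_dominating(self, small_matrix):
        X, y = small_matrix
        front, _ = evolve(X, y, EvolutionParams(
            population_size=30, generations=5, seed=3))
        objs = [ind.objectives for ind in front]
        for a in objs:
            for b in objs:
                if a is not b:
                    assert not (a[0] <= b[0] and a[1] <= b[1]
                                and (a[0] < b[0] or a[1] < b[1]))

    def test_separable_fixture_reaches_perfect_f1(self):
        X, y, _ = make_fixture("separable", seed=1)
        front, hist = evolve(X, y, EvolutionParams(
            population_size=50, generations=30, seed=1))
        assert len(hist) == 30
        assert min(ind.objectives[1] for ind in front) == 0.0

    def test_elitism_keeps_history_monotone(self, small_matrix):
        X, y = small_matrix
        _, hist = evolve(X, y, EvolutionParams(
            population_size=30, generations=25, seed=9))
        assert (np.diff(hist["best_bce"]) <= 1e-15).all()
        assert (np.diff(hist["best_f1_complement"]) <= 1e-15).all()

    def test_seed_reproducibility(self, small_matrix):
        X, y = small_matrix
        p = EvolutionParams(population_size=25, generations=8, seed=21)
        f1, h1 = evolve(X, y, p)
        f2, h2 = evolve(X, y, p)
        assert [i.formula for i in f1] == [i.formula for i in f2]
        pd.testing.assert_frame_equal(h1, h2)

    def test_front_deduplicated_by_formula(self, small_matrix):
        X, y = small_matrix
        front, _ = evolve(X, y, EvolutionParams(
            population_size=40, generations=10, seed=2))
        formulas = [i.formula for i in front]
        assert len(formulas) == len(set(formulas))


class TestSelection:
    def test_singleton_front(self, small_matrix):
        X, y = small_matrix
        ind = Individual(("const", 0.1), objectives=(0.5, 0.5))
        assert select_final_model(ParetoFront([ind]), X, y) is ind

    def test_auc_dominates_choice(self):
        X = pd.DataFrame({"x1": [-2.0, -1.0, 1.0, 2.0]})
        y = np.array([0, 0, 1, 1])
        good = Individual(("feat", "x1"), objectives=(0.3, 0.2))       # AUC 1
        bad = Individual(("neg", ("feat", "x1")), objectives=(0.2, 0.1))  # AUC 0
        assert select_final_model(ParetoFront([bad, good]), X, y) is good

    def test_full_tie_prefers_smaller_tree(self, small_matrix):
        X, y = small_matrix
        small = Individual(("const", 0.0), objectives=(0.6, 0.6))
        big = Individual(("add", ("const", 0.0), ("const", 0.0)),
                         objectives=(0.6, 0.6))
        assert select_final_model(ParetoFront([big, small]), X, y) is small

    def test_model_file_round_trip(self, tmp_path, small_matrix):
        X, y = small_matrix
        ind = Individual(("add", ("feat", "x1"), ("const", 1.5)),
                         objectives=(0.4, 0.3))
        path = tmp_path / "model.txt"
        save_model(ind, path, params=EvolutionParams(), extra={"note": "t"})
        back, meta = load_model(path, features=["x1", "x2", "x3"])
        assert back.formula == ind.formula
        assert tuple(meta["objectives"]) == ind.objectives
        assert meta["note"] == "t"


class TestImbalanceBehaviour:
    """Why two objectives: on a rare outcome, cross-entropy alone is happy
    predicting no positives; the F1 axis forces positive predictions."""

    @staticmethod
    def _bce_only_run(X, y, params):
        """Single-objective GP at the same budget: tournament and survival
        on binary cross-entropy alone."""
        from mosr import trees
        from mosr._rng import substream

        cols = {c: X[c].to_numpy(dtype=float) for c in X.columns}
        features = list(cols)
        rng = substream(params.seed, "gp_init")
        rng_var = substream(params.seed, "gp_mutation")
        pop = [(t, objectives(t, X, y, params.threshold)[0])
               for t in trees.ramped_half_and_half(
                   rng, params.population_size, features,
                   list(params.operators), params.const_range,
                   *params.init_depth)]
        for _ in range(params.generations):
            children = []
            while len(children) < params.population_size:
                pick = lambda: min(
                    (pop[i] for i in rng_var.integers(len(pop), size=2)),
                    key=lambda pair: pair[1])
                a, b = pick()[0], pick()[0]
                if rng_var.random() < params.crossover_prob:
                    a, b = trees.subtree_crossover(rng_var, a, b, params.max_depth)
                for t in (a, b):
                    if rng_var.random() < params.mutation_prob:
                        t = trees.subtree_mutation(
                            rng_var, t, features, list(params.operators),
                            params.const_range, params.max_depth)
                    children.append((t, objectives(t, X, y, params.threshold)[0]))
            pop = sorted(pop + children[: params.population_size],
                         key=lambda pair: pair[1])[: params.population_size]
        return min(pop, key=lambda pair: pair[1])[0]

    def test_f1_objective_buys_recall_at_low_prevalence(self):
        from mosr.cohort import sample_planted_logistic
        from mosr.evaluation import confusion, metric_panel
        from mosr.preprocess import SplitSpec, stratified_split

        wins = 0
        for seed in (1, 2, 3):
            X, y = sample_planted_logistic(
                1200, coefficients=(3.0,), intercept=-3.4, feature_sd=1.0,
                n_noise=2, seed=seed)
            df = X.copy()
            df["death_1y"] = y
            train, test = stratified_split(df, SplitSpec(seed=seed))
            cols = list(X.columns)
            params = EvolutionParams(population_size=60, generations=20,
                                     seed=seed)
            front, _ = evolve(train[cols], train["death_1y"], params)
            chosen = select_final_model(front, train[cols], train["death_1y"])

            def recall(tree):
                p = predict_probability(tree, test[cols])
                rep = metric_panel(confusion(test["death_1y"], p))
                return rep.sensitivity if rep.sensitivity is not None else 0.0

            bce_tree = self._bce_only_run(train[cols], train["death_1y"], params)
            if recall(chosen.tree) > recall(bce_tree):
                wins += 1
        assert wins >= 2
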