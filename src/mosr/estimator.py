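"""scikit-learn estimator interface to the symbolic-regression engine."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from scipy.special import expit

from .engine import (EvolutionParams, evolve, select_final_model,
                     predict_probability)
from .trees import DEFAULT_OPERATORS, evaluate_matrix, tree_features


class MOSRClassifier(BaseEstimator, ClassifierMixin):
    """Multi-objective symbolic-regression classifier.

    Evolves a population of expression trees against (binary
    cross-entropy, 1 - F1) with NSGA-II selection, then picks one Pareto
    front member by AUC, sensitivity and specificity.  Designed for
    imbalanced binary outcomes where cross-entropy alone collapses to the
    majority class.

    Parameters mirror :class:`~mosr.engine.EvolutionParams`; defaults are
    the study protocol (population 300, 500 generations).  Pass a pandas
    DataFrame to keep feature names in the evolved formulas; plain arrays
    get column names ``x1..xn``.

    Attributes (after ``fit``)
    --------------------------
    pareto_front_ : ParetoFront of non-dominated individuals.
    best_individual_ : the selected model (tree + objectives).
    formula_ : its human-readable serialized form.
    history_ : per-generation best of each objective (DataFrame).
    """

    def __init__(self, population_size: int = 300, generations: int = 500,
                 crossover_prob: float = 0.8, mutation_prob: float = 0.2,
                 tournament_size: int = 2, max_depth: int = 17,
                 init_depth_min: int = 2, init_depth_max: int = 6,
                 const_min: float = -2.0, const_max: float = 2.0,
                 operators: tuple = DEFAULT_OPERATORS, threshold: float = 0.5,
                 random_state: int = 0):
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.tournament_size = tournament_size
        self.max_depth = max_depth
        self.init_depth_min = init_depth_min
        self.init_depth_max = init_depth_max
        self.const_min = const_min
        self.const_max = const_max
        self.operators = operators
        self.threshold = threshold
        self.random_state = random_state

    def _params(self) -> EvolutionParams:
        return EvolutionParams(
            population_size=self.population_size,
            generations=self.generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            tournament_size=self.tournament_size,
            max_depth=self.max_depth,
            init_depth=(self.init_depth_min, self.init_depth_max),
            const_range=(self.const_min, self.const_max),
            operators=tuple(self.operators),
            threshold=self.threshold,
            seed=self.random_state,
        )

    def _frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        names = getattr(self, "feature_names_in_",
                        [f"x{i + 1}" for i in range(X.shape[1])])
        return pd.DataFrame(X, columns=list(names))

    def fit(self, X, y, X_val=None, y_val=None):
        """Evolve the population, then select the final model on the
        validation data when given (otherwise on the training data)."""
        Xf = self._frame(X)
        y = np.asarray(y).astype(int)
        if len(Xf) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("MOSRClassifier requires exactly two classes")
        self.feature_names_in_ = np.asarray(Xf.columns)
        self.n_features_in_ = Xf.shape[1]
        self.pareto_front_, self.history_ = evolve(Xf, y, self._params())
        if X_val is not None:
            self.select(X_val, y_val)
        else:
            self.select(Xf, y)
        return self

    def select(self, X_val, y_val) -> "MOSRClassifier":
        """Re-pick the final model from the fitted front on held-out data
        (AUC, then sensitivity, then specificity)."""
        if not hasattr(self, "pareto_front_"):
            raise RuntimeError("fit before select")
        self.best_individual_ = select_final_model(
            self.pareto_front_, self._frame(X_val), np.asarray(y_val).astype(int),
            self.threshold)
        self.formula_ = self.best_individual_.formula
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw (pre-logistic) formula output per row."""
        self._check_fitted()
        Xf = self._frame(X)
        cols = {c: Xf[c].to_numpy(dtype=float) for c in Xf.columns}
        return evaluate_matrix(self.best_individual_.tree, cols, n_rows=len(Xf))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.threshold).astype(int)]

    def used_features(self) -> list[str]:
        """Features the selected formula actually references."""
        self._check_fitted()
        return sorted(tree_features(self.best_individual_.tree))

    def _check_fitted(self):
        if not hasattr(self, "best_individual_"):
            raise RuntimeError("MOSRClassifier is not fitted")


def mosr_trainer(X_train, y_train, X_val, y_val, params: dict,
                 seed: int) -> MOSRClassifier:
    """Grid-search adapter: train on the inner-train part, select the
    front member on the inner-validation part."""
    clf = MOSRClassifier(random_state=seed, **params)
    clf.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    return clf
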