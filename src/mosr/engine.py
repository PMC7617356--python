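"""Multi-objective symbolic regression engine.

Evolves a population of expression trees against two simultaneously
minimised objectives — binary cross-entropy and 1 - F1 — using the
canonical NSGA-II machinery: fast non-dominated sorting, crowding
distance, binary tournament selection on (rank, crowding), subtree
crossover, subtree/point mutation, and elitist mu+lambda survival.
The raw tree output is mapped to a class probability through a logistic
link; classification uses a fixed threshold (default 0.5).

The two objectives pull in different directions on an imbalanced
outcome: cross-entropy rewards well-calibrated probabilities (which a
majority-class model satisfies cheaply) while 1 - F1 forces the model to
commit to positive predictions.  The final Pareto front exposes that
trade-off; ``select_final_model`` picks one member by AUC, sensitivity
and specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import trees
from ._rng import substream
from .evaluation import confusion, metric_panel, roc_auc
from .trees import (DEFAULT_OPERATORS, evaluate_matrix, serialize_formula,
                    parse_formula, tree_size)

__all__ = [
    "EvolutionParams",
    "Individual",
    "ParetoFront",
    "predict_probability",
    "objectives",
    "non_dominated_sort",
    "crowding_distance",
    "evolve",
    "select_final_model",
    "save_model",
    "load_model",
]

_BCE_EPS = 1e-12


@dataclass
class EvolutionParams:
    """Knobs of the evolutionary run.  Defaults follow the study protocol
    (300 models refined over 500 generations); variation rates and tree
    bounds are standard GP practice and exposed to grid search."""

    population_size: int = 300
    generations: int = 500
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    tournament_size: int = 2
    max_depth: int = 17
    init_depth: tuple[int, int] = (2, 6)
    const_range: tuple[float, float] = (-2.0, 2.0)
    operators: tuple[str, ...] = DEFAULT_OPERATORS
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        unknown = set(self.operators) - set(trees.OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")


@dataclass
class Individual:
    tree: tuple
    objectives: tuple[float, float] | None = None  # (bce, 1 - F1)
    rank: int | None = None
    crowding: float | None = None

    @property
    def n_nodes(self) -> int:
        return tree_size(self.tree)

    @property
    def formula(self) -> str:
        return serialize_formula(self.tree)


@dataclass
class ParetoFront:
    """Rank-0 individuals of the final population, deduplicated by
    serialized formula."""

    members: list[Individual] = field(default_factory=list)

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        return self.members[i]


def _columns(X) -> tuple[Mapping[str, np.ndarray], int]:
    if isinstance(X, pd.DataFrame):
        return {c: X[c].to_numpy(dtype=float) for c in X.columns}, len(X)
    if isinstance(X, Mapping):
        cols = {k: np.asarray(v, dtype=float) for k, v in X.items()}
        n = len(next(iter(cols.values()))) if cols else 0
        return cols, n
    raise TypeError("X must be a DataFrame or a mapping of column arrays")


def predict_probability(tree, X) -> np.ndarray:
    """Raw tree scores pushed through the logistic link; values in (0, 1)."""
    cols, n = _columns(X)
    return expit(evaluate_matrix(tree, cols, n_rows=n))


def objectives(tree, X, labels, threshold: float = 0.5) -> tuple[float, float]:
    """(binary cross-entropy, 1 - F1) for one tree on labelled data."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("objectives need both outcome classes present")
    p = np.clip(predict_probability(tree, X), _BCE_EPS, 1 - _BCE_EPS)
    bce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    f1 = metric_panel(confusion(y, p, threshold)).f1
    if f1 is None:  # perfect all-negative table cannot occur with both classes
        f1 = 0.0
    return bce, 1.0 - f1


def non_dominated_sort(population: Sequence[Individual]) -> list[list[Individual]]:
    """Fast non-dominated sort (minimisation on both objectives).

    ``a`` dominates ``b`` iff a <= b on both objectives and a < b on at
    least one.  Assigns ``rank`` on every individual and returns fronts in
    rank order.
    """
    n = len(population)
    obj = np.array([ind.objectives for ind in population], dtype=float)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        # i_dom[j]: i dominates j; dom_i[j]: j dominates i
        i_dom = (obj[i] <= obj).all(axis=1) & (obj[i] < obj).any(axis=1)
        dom_i = (obj <= obj[i]).all(axis=1) & (obj < obj[i]).any(axis=1)
        dominated_by[i] = np.flatnonzero(i_dom).tolist()
        domination_count[i] = int(dom_i.sum())
    fronts: list[list[Individual]] = []
    current = [i for i in range(n) if domination_count[i] == 0]
    rank = 0
    while current:
        for i in current:
            population[i].rank = rank
        fronts.append([population[i] for i in current])
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        current, rank = nxt, rank + 1
    return fronts


def crowding_distance(front: Sequence[Individual]) -> list[float]:
    """NSGA-II crowding distance; boundary points get +inf, a zero-range
    objective contributes nothing.  Also stores the value on each member."""
    n = len(front)
    if n == 0:
        raise ValueError("empty front")
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
    else:
        obj = np.array([ind.objectives for ind in front], dtype=float)
        for m in range(obj.shape[1]):
            order = np.argsort(obj[:, m], kind="stable")
            lo, hi = obj[order[0], m], obj[order[-1], m]
            dist[order[0]] = dist[order[-1]] = np.inf
            if hi > lo:
                gaps = (obj[order[2:], m] - obj[order[:-2], m]) / (hi - lo)
                dist[order[1:-1]] += gaps
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist.tolist()


def _rank_population(population: list[Individual]) -> list[list[Individual]]:
    fronts = non_dominated_sort(population)
    for front in fronts:
        crowding_distance(front)
    return fronts


def _environmental_selection(population: list[Individual], k: int) -> list[Individual]:
    """Elitist survival: fill by fronts; the splitting front is truncated by
    descending crowding distance (boundary members survive)."""
    fronts = _rank_population(population)
    survivors: list[Individual] = []
    for front in fronts:
        if len(survivors) + len(front) <= k:
            survivors.extend(front)
        else:
            rest = sorted(front, key=lambda ind: -ind.crowding)
            survivors.extend(rest[: k - len(survivors)])
            break
    return survivors


def _tournament(rng, population: list[Individual], size: int) -> Individual:
    picks = rng.integers(len(population), size=size)
    best = population[picks[0]]
    for i in picks[1:]:
        c = population[i]
        if (c.rank, -c.crowding) < (best.rank, -best.crowding):
            best = c
    return best


def evolve(X, labels, params: EvolutionParams) -> tuple[ParetoFront, pd.DataFrame]:
    """Run the generational loop; returns the final front and a history of
    the per-generation best (minimum) of each objective.

    Elitism makes both history columns monotone non-increasing.  All
    randomness flows from ``params.seed`` via named substreams.
    """
    cols, _ = _columns(X)
    features = list(cols)
    y = np.asarray(labels).astype(int)
    rng_init = substream(params.seed, "gp_init")
    rng_sel = substream(params.seed, "gp_selection")
    rng_x = substream(params.seed, "gp_crossover")
    rng_mut = substream(params.seed, "gp_mutation")
    ops = list(params.operators)

    genomes = trees.ramped_half_and_half(
        rng_init, params.population_size, features, ops, params.const_range,
        *params.init_depth)
    population = [Individual(t, objectives(t, X, y, params.threshold))
                  for t in genomes]
    _rank_population(population)

    history = []
    for _ in range(params.generations):
        offspring: list[Individual] = []
        while len(offspring) < params.population_size:
            p1 = _tournament(rng_sel, population, params.tournament_size)
            p2 = _tournament(rng_sel, population, params.tournament_size)
            t1, t2 = p1.tree, p2.tree
            if rng_x.random() < params.crossover_prob:
                t1, t2 = trees.subtree_crossover(rng_x, t1, t2, params.max_depth)
            out = []
            for t in (t1, t2):
                if rng_mut.random() < params.mutation_prob:
                    if rng_mut.random() < 0.5:
                        t = trees.subtree_mutation(
                            rng_mut, t, features, ops, params.const_range,
                            params.max_depth)
                    else:
                        t = trees.point_mutation(
                            rng_mut, t, features, ops, params.const_range)
                out.append(t)
            offspring.extend(Individual(t, objectives(t, X, y, params.threshold))
                             for t in out)
        offspring = offspring[: params.population_size]
        population = _environmental_selection(population + offspring,
                                              params.population_size)
        obj = np.array([ind.objectives for ind in population])
        history.append({"best_bce": float(obj[:, 0].min()),
                        "best_f1_complement": float(obj[:, 1].min()),
                        "front_size": sum(1 for ind in population if ind.rank == 0)})

    _rank_population(population)
    seen: dict[str, Individual] = {}
    for ind in population:
        if ind.rank == 0:
            seen.setdefault(ind.formula, ind)
    front = ParetoFront(sorted(seen.values(), key=lambda ind: ind.formula))
    return front, pd.DataFrame(history,
                               columns=["best_bce", "best_f1_complement", "front_size"])


def select_final_model(front: ParetoFront, X, labels,
                       threshold: float = 0.5) -> Individual:
    """Pick the front member with the lexicographically best
    (AUC, sensitivity, specificity) on the supplied validation data; ties
    go to the smaller tree, then to serialized-formula order."""
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    y = np.asarray(labels).astype(int)

    def key(ind: Individual):
        p = predict_probability(ind.tree, X)
        rep = metric_panel(confusion(y, p, threshold))
        auc = roc_auc(y, p)
        return (-(auc if auc is not None else 0.0),
                -(rep.sensitivity if rep.sensitivity is not None else 0.0),
                -(rep.specificity if rep.specificity is not None else 0.0),
                ind.n_nodes, ind.formula)

    return min(front, key=key)


# ---------------------------------------------------------------------------
# model files: one formula line + one JSON metadata line

def save_model(individual: Individual, path, params: EvolutionParams | None = None,
               extra: Mapping | None = None) -> None:
    meta = {"objectives": list(individual.objectives or ()),
            "n_nodes": individual.n_nodes}
    if params is not None:
        meta["params"] = asdict(params)
    if extra:
        meta.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(individual.formula + "\n")
        fh.write(json.dumps(meta, default=str) + "\n")


def load_model(path, features: Sequence[str] | None = None) -> tuple[Individual, dict]:
    with open(path, encoding="utf-8") as fh:
        formula = fh.readline().strip()
        meta_line = fh.readline().strip()
    tree = parse_formula(formula, features)
    meta = json.loads(meta_line) if meta_line else {}
    obj = tuple(meta["objectives"]) if meta.get("objectives") else None
    return Individual(tree, objectives=obj), meta
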