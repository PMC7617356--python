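"""Model-agnostic Shapley-value feature attribution.

For a prediction f(x), each feature receives its average marginal
contribution over feature coalitions; "absent" features are integrated
out interventionally, i.e. replaced by values drawn from a background
sample (marginal expectation, the standard model-agnostic choice).

Two estimators are provided: exact coalition enumeration for up to 12
features (2^k model evaluations, vectorised over the background), and a
permutation-sampling estimator for wider models, unbiased for the exact
value, with a per-feature Monte Carlo standard error and a final
residual correction that restores additivity by spreading the residual
proportionally to |attribution|.

Attributions are computed on the probability scale by default (how
beeswarm plots for classifiers are read); the raw-score scale is
available via ``output="raw"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from . import engine as _engine
from .trees import evaluate_matrix, tree_features

__all__ = [
    "ShapReport",
    "shapley_exact",
    "shapley_sampled",
    "summarize_importance",
    "explain_model",
    "MAX_EXACT_FEATURES",
]

MAX_EXACT_FEATURES = 12


def _model_fn(model, output: str = "probability") -> tuple[Callable, set[str] | None]:
    """Normalise ``model`` into a DataFrame -> 1-D array callable.

    Accepts an expression tree, an ``Individual``, an estimator with
    ``predict_proba``/``decision_function``, or a plain callable.  Also
    returns the set of features the model is known to use (None when
    unknowable).
    """
    if output not in ("probability", "raw"):
        raise ValueError("output must be 'probability' or 'raw'")
    tree = None
    if isinstance(model, tuple):
        tree = model
    elif hasattr(model, "tree") and isinstance(getattr(model, "tree"), tuple):
        tree = model.tree
    elif hasattr(model, "best_individual_"):
        tree = model.best_individual_.tree

    if tree is not None:
        used = tree_features(tree)
        if output == "probability":
            return (lambda df: _engine.predict_probability(tree, df)), used
        return (lambda df: evaluate_matrix(
            tree, {c: df[c].to_numpy(dtype=float) for c in df.columns},
            n_rows=len(df))), used
    if hasattr(model, "predict_proba") and output == "probability":
        return (lambda df: np.asarray(model.predict_proba(df))[:, -1]), None
    if hasattr(model, "decision_function") and output == "raw":
        return (lambda df: np.asarray(model.decision_function(df))), None
    if callable(model):
        return (lambda df: np.asarray(model(df), dtype=float).reshape(len(df))), None
    raise TypeError(f"cannot interpret model of type {type(model)!r}")


def _as_frame(background) -> pd.DataFrame:
    if isinstance(background, pd.DataFrame):
        return background.reset_index(drop=True)
    return pd.DataFrame(background).reset_index(drop=True)


def _as_row(row, columns) -> pd.Series:
    if isinstance(row, pd.Series):
        return row
    if isinstance(row, Mapping):
        return pd.Series(row)
    return pd.Series(np.asarray(row, dtype=float), index=columns)


def shapley_exact(model, row, background, features: Sequence[str] | None = None,
                  output: str = "probability") -> tuple[pd.Series, float]:
    """Exact Shapley values by coalition enumeration (<= 12 features).

    The value function v(S) is the mean model output when the features in
    S take the explained row's values and all other columns come from the
    background rows.  Returns (attributions, base value) with
    base + sum(attributions) = v(all features), exactly.
    """
    fn, used = _model_fn(model, output)
    bg = _as_frame(background)
    if len(bg) == 0:
        raise ValueError("background set must be non-empty")
    row = _as_row(row, bg.columns)
    if features is None:
        features = sorted(used & set(bg.columns)) if used is not None else list(bg.columns)
    features = list(features)
    k = len(features)
    if k > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{k} features exceed the exact-enumeration limit of "
            f"{MAX_EXACT_FEATURES}; use shapley_sampled instead")
    n_bg = len(bg)
    if k == 0:
        base = float(np.mean(fn(bg)))
        return pd.Series(dtype=float), base

    # stacked evaluation in chunks: blocks of the background with coalition
    # columns overwritten by the explained row's values
    cols = list(bg.columns)
    bgv = bg.to_numpy(dtype=float)
    rowv = np.asarray([float(row[c]) for c in cols])
    fidx = [cols.index(f) for f in features]
    v = np.empty(2 ** k)
    chunk = max(1, 2 ** 15 // n_bg)
    for start in range(0, 2 ** k, chunk):
        subsets = range(start, min(start + chunk, 2 ** k))
        block = np.tile(bgv, (len(subsets), 1, 1))
        for b, s in enumerate(subsets):
            for i in range(k):
                if s >> i & 1:
                    block[b, :, fidx[i]] = rowv[fidx[i]]
        out = fn(pd.DataFrame(block.reshape(-1, len(cols)), columns=cols))
        v[start:start + len(subsets)] = out.reshape(len(subsets), n_bg).mean(axis=1)

    fact = [math.factorial(i) for i in range(k + 1)]
    phi = np.zeros(k)
    for s in range(2 ** k):
        size = bin(s).count("1")
        w = fact[size] * fact[k - size - 1] / fact[k]
        for i in range(k):
            if not s >> i & 1:
                phi[i] += w * (v[s | (1 << i)] - v[s])
    return pd.Series(phi, index=features), float(v[0])


def shapley_sampled(model, row, background, n_permutations: int = 2000,
                    seed: int = 0, features: Sequence[str] | None = None,
                    output: str = "probability",
                    ) -> tuple[pd.Series, float, pd.Series]:
    """Permutation-sampling Shapley estimate with Monte Carlo SEs.

    Each permutation draws one background row and walks the features in
    random order, switching them to the explained row's values; the
    output jumps are per-feature marginal contributions.  The estimator
    is unbiased for the exact enumeration value.  A final residual
    correction (spread proportionally to |attribution|) restores exact
    additivity against the full-coalition value.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    fn, used = _model_fn(model, output)
    bg = _as_frame(background)
    if len(bg) == 0:
        raise ValueError("background set must be non-empty")
    row = _as_row(row, bg.columns)
    if features is None:
        features = sorted(used & set(bg.columns)) if used is not None else list(bg.columns)
    features = list(features)
    k = len(features)
    base = float(np.mean(fn(bg)))
    if k == 0:
        return pd.Series(dtype=float), base, pd.Series(dtype=float)

    rng = substream(seed, "shap")
    bg_idx = rng.integers(len(bg), size=n_permutations)
    orders = np.array([rng.permutation(k) for _ in range(n_permutations)])

    cols = list(bg.columns)
    bgv = bg.to_numpy(dtype=float)
    rowv = np.asarray([float(row[c]) for c in cols])
    fidx = np.asarray([cols.index(f) for f in features])
    # pos[p, i]: step at which feature i switches to the explained row
    pos = np.argsort(orders, axis=1)
    steps = np.arange(k + 1)[None, :]

    # every intermediate hybrid: (n_permutations, k + 1, n_cols)
    contrib = np.zeros((n_permutations, k))
    chunk = max(1, 2 ** 17 // (k + 1))
    for start in range(0, n_permutations, chunk):
        stop = min(start + chunk, n_permutations)
        block = bgv[bg_idx[start:stop], None, :].repeat(k + 1, axis=1)
        for i in range(k):
            switched = pos[start:stop, i:i + 1] < steps  # (chunk, k+1)
            block[:, :, fidx[i]] = np.where(switched, rowv[fidx[i]],
                                            block[:, :, fidx[i]])
        out = fn(pd.DataFrame(block.reshape(-1, len(cols)), columns=cols))
        deltas = np.diff(out.reshape(stop - start, k + 1), axis=1)
        np.put_along_axis(contrib[start:stop], orders[start:stop], deltas, axis=1)
    phi = contrib.mean(axis=0)
    se = (contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
          if n_permutations > 1 else np.zeros(k))

    # additivity correction against the full-coalition value
    full = bg.copy()
    for f in features:
        full[f] = row[f]
    v_full = float(np.mean(fn(full)))
    residual = (v_full - base) - phi.sum()
    denom = np.abs(phi).sum()
    if denom > 0:
        phi = phi + residual * np.abs(phi) / denom
    elif k:
        phi = phi + residual / k
    return pd.Series(phi, index=features), base, pd.Series(se, index=features)


@dataclass
class ShapReport:
    """Per-patient per-feature attributions plus the data to rank and
    plot them (value/attribution pairs per feature)."""

    base_value: float
    attributions: pd.DataFrame           # patients x features
    feature_values: pd.DataFrame         # aligned with attributions
    output: str = "probability"
    se: pd.DataFrame | None = None
    model_outputs: np.ndarray | None = None

    def importance(self) -> pd.DataFrame:
        return summarize_importance(self.attributions, self.feature_values)


def summarize_importance(attributions: pd.DataFrame,
                         feature_values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rank features by mean |attribution|; the direction column is the
    correlation between a feature's attribution and its value across
    patients (positive: higher values push risk up)."""
    if len(attributions) == 0:
        raise ValueError("need at least one patient report")
    mean_abs = attributions.abs().mean(axis=0)
    directions = {}
    for col in attributions.columns:
        d = 0.0
        if feature_values is not None and col in feature_values.columns:
            a = attributions[col].to_numpy(dtype=float)
            x = feature_values[col].to_numpy(dtype=float)
            if len(a) > 1 and a.std() > 0 and x.std() > 0:
                d = float(np.corrcoef(x, a)[0, 1])
        directions[col] = d
    table = pd.DataFrame({
        "feature": mean_abs.index,
        "mean_abs_attribution": mean_abs.to_numpy(),
        "direction": [directions[c] for c in mean_abs.index],
    })
    table = table.sort_values(["mean_abs_attribution", "feature"],
                              ascending=[False, True], ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def explain_model(model, X: pd.DataFrame, background: pd.DataFrame,
                  output: str = "probability", seed: int = 0,
                  n_permutations: int = 2000) -> ShapReport:
    """Attribute every row of ``X``.

    Features the model provably never references receive attribution 0
    (null-player axiom) without being enumerated; the remaining features
    go through exact enumeration when they number <= 12, otherwise
    through the permutation sampler.
    """
    fn, used = _model_fn(model, output)
    bg = _as_frame(background)
    active = sorted(used & set(X.columns)) if used is not None else list(X.columns)
    exact = len(active) <= MAX_EXACT_FEATURES
    attr = pd.DataFrame(0.0, index=range(len(X)), columns=list(X.columns))
    ses = pd.DataFrame(0.0, index=range(len(X)), columns=list(X.columns))
    base = float(np.mean(fn(bg)))
    for i in range(len(X)):
        row = X.iloc[i]
        if exact:
            phi, base = shapley_exact(model, row, bg, features=active, output=output)
        else:
            phi, base, se = shapley_sampled(model, row, bg,
                                            n_permutations=n_permutations,
                                            seed=seed + i, features=active,
                                            output=output)
            ses.loc[i, phi.index] = se
        attr.loc[i, phi.index] = phi
    return ShapReport(base_value=base, attributions=attr,
                      feature_values=X.reset_index(drop=True), output=output,
                      se=None if exact else ses,
                      model_outputs=fn(X))
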