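"""End-to-end study protocols used for validation and reproduction.

These functions bundle the pipeline stages into the runs the package's
validation is built around: recovery of a planted two-feature logistic
signal, recovery of the planted risk directions on the default synthetic
cohort, and a full train/evaluate pass.  Problem sizes default to
desk-scale settings chosen so a run finishes in seconds to a few minutes
on one CPU; docs/methods.md discusses the choices.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .cohort import (OUTCOME_COLUMN, default_config, sample_cohort,
                     sample_planted_logistic)
from .estimator import MOSRClassifier
from .evaluation import evaluate_probabilities, overfit_gap, repeated_test_eval
from .explain import explain_model
from .preprocess import (CohortPreprocessor, SplitSpec, complete_case_filter,
                         stratified_split)

__all__ = [
    "planted_recovery_trial",
    "direction_recovery_trial",
    "default_cohort_run",
    "generator_prevalence",
]


def planted_recovery_trial(seed: int, n: int = 2000,
                           population_size: int = 100,
                           generations: int = 50) -> float:
    """Test-set F1 after evolving on a strong planted logistic signal.

    Data carry two features with logit coefficients +3/-3 at prevalence
    ~0.5 (Bayes-limit F1 ~ 0.94); the cohort is split 80/20 stratified
    and the final model is selected on the training portion.
    """
    X, y = sample_planted_logistic(n, coefficients=(3.0, -3.0), seed=seed)
    df = X.copy()
    df[OUTCOME_COLUMN] = y
    train, test = stratified_split(df, SplitSpec(seed=seed))
    cols = list(X.columns)
    clf = MOSRClassifier(population_size=population_size,
                         generations=generations, random_state=seed)
    clf.fit(train[cols], train[OUTCOME_COLUMN])
    rep = evaluate_probabilities(test[OUTCOME_COLUMN],
                                 clf.predict_proba(test[cols])[:, 1])
    return float(rep.f1 if rep.f1 is not None else 0.0)


def direction_recovery_trial(seed: int, n_patients: int = 6000,
                             population_size: int = 250,
                             generations: int = 80,
                             n_explain: int = 50, background_size: int = 100,
                             n_permutations: int = 400) -> dict:
    """Train on a default-condition cohort and read the planted risk
    directions back out of the selected model's Shapley attributions.

    The final model is selected on an inner 90/10 validation split so
    front members that overfit the training noise lose.  Returns the
    top-ranked feature and the attribution-vs-value directions for the
    planted effects.
    """
    cfg = default_config(n_patients=n_patients, seed=seed)
    cohort = sample_cohort(cfg)
    complete, _ = complete_case_filter(cohort)
    train, _test = stratified_split(complete, SplitSpec(seed=seed))
    inner_train, inner_val = stratified_split(
        train, SplitSpec(fraction=0.9, seed=seed + 1))
    prep = CohortPreprocessor(cfg.schema()).fit(inner_train)
    Xt = prep.transform_matrix(inner_train)
    Xv = prep.transform_matrix(inner_val)
    clf = MOSRClassifier(population_size=population_size,
                         generations=generations, random_state=seed)
    clf.fit(Xt.X, Xt.y, X_val=Xv.X, y_val=Xv.y)

    rng = substream(seed, "background")
    Xall = prep.transform_matrix(train)
    bg = Xall.X.iloc[rng.choice(len(Xall.X), background_size, replace=False)]
    rows = Xall.X.iloc[rng.choice(len(Xall.X), n_explain, replace=False)]
    report = explain_model(clf, rows.reset_index(drop=True), bg,
                           seed=seed, n_permutations=n_permutations)
    imp = report.importance().set_index("feature")

    def direction(feature):
        return float(imp.loc[feature, "direction"]) if feature in imp.index else 0.0

    return {
        "top_feature": imp.index[0],
        "ve_vco2_direction": direction("peak_ve_vco2"),
        "bmi_direction": direction("bmi"),
        "formula": clf.formula_,
        "n_used_features": len(clf.used_features()),
    }


def default_cohort_run(seed: int, n_patients: int = 1190,
                       population_size: int = 150,
                       generations: int = 60) -> dict:
    """Full pipeline on one default cohort: returns the train metric panel,
    the repeated-test summary and the train-test gaps.  The front member is
    selected on an inner 90/10 validation split, mirroring the tuning
    protocol."""
    cfg = default_config(n_patients=n_patients, seed=seed)
    cohort = sample_cohort(cfg)
    complete, _ = complete_case_filter(cohort)
    train, test = stratified_split(complete, SplitSpec(seed=seed))
    inner_train, inner_val = stratified_split(
        train, SplitSpec(fraction=0.9, seed=seed + 1))
    prep = CohortPreprocessor(cfg.schema()).fit(train)
    Xtr = prep.transform_matrix(train)
    Xte = prep.transform_matrix(test)
    Xit = prep.transform_matrix(inner_train)
    Xiv = prep.transform_matrix(inner_val)
    clf = MOSRClassifier(population_size=population_size,
                         generations=generations, random_state=seed)
    clf.fit(Xit.X, Xit.y, X_val=Xiv.X, y_val=Xiv.y)
    train_rep = evaluate_probabilities(Xtr.y, clf.predict_proba(Xtr.X)[:, 1])
    summary, _ = repeated_test_eval(clf, Xte.X, Xte.y, runs=10, fraction=0.9,
                                    seed=seed)
    return {
        "train": train_rep.scalars(),
        "test": {m: summary[m]["mean"] for m in summary},
        "gap": overfit_gap(train_rep, summary),
        "formula": clf.formula_,
    }


def generator_prevalence(seeds, n: int = 5000) -> float:
    """Mean observed outcome prevalence of default cohorts over seeds."""
    rates = []
    for seed in seeds:
        cfg = default_config(n_patients=n, seed=int(seed))
        rates.append(float(sample_cohort(cfg)[OUTCOME_COLUMN].mean()))
    return float(np.mean(rates))
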