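"""Synthetic perioperative cohort generator.

Emulates the statistical structure of a single-institution cohort of
patients who underwent cardiopulmonary exercise testing (CPET) before
major elective surgery: 39 clinical parameters (demographics,
comorbidities, medications, laboratory values, surgical specialty), 46
summary CPET parameters, and a binary 1-year mortality outcome at ~5.5%
prevalence.

Continuous marginals are truncated normals parameterised from published
median/IQR/range summaries (the IQR match is therefore approximate);
binary and categorical features are Bernoulli/multinomial.  A Gaussian
copula induces rank correlation between declared feature pairs (by
default peak oxygen uptake and the anaerobic threshold, rho = 0.7).
The outcome is generated by a logistic-additive mechanism whose planted
effects reproduce the qualitative risk directions of interest: higher
peak VE/VCO2 (poorer ventilatory efficiency) raises risk, BMI above
28 kg/m2 and peak VE/VO2 above 38 lower it, and previous myocardial
ischaemia raises it.  The intercept is calibrated by Monte Carlo so the
marginal outcome prevalence hits its target.

Missingness, when injected, is MCAR and never touches the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm, truncnorm

from ._rng import substream

__all__ = [
    "TruncNormal",
    "Bernoulli",
    "Categorical",
    "Effect",
    "CohortSchema",
    "GeneratorConfig",
    "ConfigError",
    "CohortParseError",
    "default_config",
    "calibrate_baseline_logit",
    "sample_cohort",
    "outcome_probability",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "sample_planted_logistic",
    "make_fixture",
    "FIXTURES",
    "ID_COLUMN",
    "OUTCOME_COLUMN",
]

ID_COLUMN = "patient_id"
OUTCOME_COLUMN = "death_1y"


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the feature."""


class CohortParseError(ValueError):
    """Malformed cohort file; the message carries row/column location."""


# ---------------------------------------------------------------------------
# marginal families

@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal parameterised by its centre (median), spread and
    hard range; used for every continuous feature."""
    median: float
    sd: float
    low: float
    high: float

    def validate(self, name: str) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ConfigError(f"{name}: truncation bounds must be finite with low < high")
        if self.sd <= 0:
            raise ConfigError(f"{name}: sd must be positive")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a = (self.low - self.median) / self.sd
        b = (self.high - self.median) / self.sd
        return truncnorm.ppf(u, a, b, loc=self.median, scale=self.sd)


@dataclass(frozen=True)
class Bernoulli:
    p: float

    def validate(self, name: str) -> None:
        if not 0 <= self.p <= 1:
            raise ConfigError(f"{name}: Bernoulli probability {self.p} outside [0, 1]")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        # monotone in u so copula correlation carries the right sign
        return (u >= 1 - self.p).astype(int)


@dataclass(frozen=True)
class Categorical:
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def validate(self, name: str) -> None:
        if len(self.levels) != len(self.probs) or not self.levels:
            raise ConfigError(f"{name}: levels and probabilities must align and be non-empty")
        if any(p < 0 or p > 1 for p in self.probs):
            raise ConfigError(f"{name}: category probability outside [0, 1]")
        if abs(sum(self.probs) - 1) > 1e-6:
            raise ConfigError(f"{name}: category probabilities sum to {sum(self.probs)}, not 1")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        cum = np.cumsum(self.probs)
        idx = np.searchsorted(cum, u, side="right")
        idx = np.clip(idx, 0, len(self.levels) - 1)
        return np.asarray(self.levels, dtype=object)[idx]


@dataclass(frozen=True)
class Effect:
    """One additive term of the outcome logit.

    ``linear``: coef * (x - threshold) — threshold acts as the centring
    value; ``threshold_above``: coef * 1[x > threshold];
    ``threshold_below``: coef * 1[x < threshold].
    """
    feature: str
    transform: str
    threshold: float
    coef: float

    def validate(self) -> None:
        if self.transform not in ("linear", "threshold_above", "threshold_below"):
            raise ConfigError(f"{self.feature}: unknown transform {self.transform!r}")

    def contribution(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.transform == "linear":
            return self.coef * (x - self.threshold)
        if self.transform == "threshold_above":
            return self.coef * (x > self.threshold)
        return self.coef * (x < self.threshold)


@dataclass(frozen=True)
class CohortSchema:
    continuous: tuple[str, ...]
    binary: tuple[str, ...]
    categorical: Mapping[str, tuple[str, ...]]
    id_column: str = ID_COLUMN
    outcome_column: str = OUTCOME_COLUMN

    @property
    def feature_columns(self) -> list[str]:
        return list(self.continuous) + list(self.binary) + list(self.categorical)

    @property
    def columns(self) -> list[str]:
        return [self.id_column, *self.feature_columns, self.outcome_column]


@dataclass
class GeneratorConfig:
    n_patients: int = 1190
    seed: int = 0
    baseline_logit: float = 0.0
    effects: tuple[Effect, ...] = ()
    marginals: dict[str, object] = field(default_factory=dict)
    missing_rate: float = 0.0
    # (feature_a, feature_b, rho) pairs, Gaussian-copula correlation
    correlations: tuple[tuple[str, str, float], ...] = ()
    clinical_features: tuple[str, ...] = ()
    fitness_features: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        for name, spec in self.marginals.items():
            spec.validate(name)
        for eff in self.effects:
            eff.validate()
            if eff.feature not in self.marginals:
                raise ConfigError(f"effect names unknown feature {eff.feature!r}")
        for a, b, rho in self.correlations:
            for f in (a, b):
                if f not in self.marginals:
                    raise ConfigError(f"correlation names unknown feature {f!r}")
            if not -1 < rho < 1:
                raise ConfigError(f"correlation ({a}, {b}): rho {rho} outside (-1, 1)")

    @property
    def feature_order(self) -> list[str]:
        return list(self.marginals)

    def schema(self) -> CohortSchema:
        cont, binary, cat = [], [], {}
        for name, spec in self.marginals.items():
            if isinstance(spec, TruncNormal):
                cont.append(name)
            elif isinstance(spec, Bernoulli):
                binary.append(name)
            else:
                cat[name] = tuple(spec.levels)
        return CohortSchema(tuple(cont), tuple(binary), cat)


def _iqr_sd(q1: float, q3: float) -> float:
    # normal-theory spread implied by an interquartile range
    return (q3 - q1) / 1.349


def _default_marginals() -> dict[str, object]:
    m: dict[str, object] = {}
    # --- clinical (39 features) ----------------------------------------
    m["age"] = TruncNormal(71, _iqr_sd(61, 79), 45, 89)
    m["sex"] = Categorical(("male", "female"), (0.69, 0.31))
    m["bmi"] = TruncNormal(26.5, _iqr_sd(23.3, 30.0), 14.0, 39.0)
    m["asa"] = TruncNormal(2.3, 0.7, 0, 4)
    m["dasi"] = TruncNormal(46.2, _iqr_sd(32.2, 58.2), 31.4, 58.2)
    m["ethnicity"] = Categorical(
        ("white", "asian", "arabic", "black", "mixed_other"),
        (0.80, 0.05, 0.03, 0.07, 0.05))
    m["surgical_specialty"] = Categorical(
        ("colorectal", "upper_gastrointestinal", "genito_urinary",
         "head_and_neck", "thoracic", "others"),
        (0.20, 0.17, 0.34, 0.21, 0.04, 0.04))
    for name, p in [
        ("hypertension", 0.35), ("diabetes", 0.11), ("angina", 0.04),
        ("coronary_stent", 0.05), ("cabg", 0.03),
        ("chronic_cardiac_failure", 0.10), ("peripheral_vascular_disease", 0.02),
        ("cva_tia", 0.04), ("copd", 0.06), ("asthma", 0.08),
        ("pulmonary_embolism", 0.02), ("pulmonary_fibrosis", 0.01),
        ("smoking", 0.36), ("previous_myocardial_ischaemia", 0.08),
        ("beta_blocker", 0.20), ("nitrates", 0.03),
        ("ace_inhibitor", 0.18), ("statin", 0.30),
    ]:
        m[name] = Bernoulli(p)
    # pre-operative laboratory values (plausible adult reference ranges)
    for name, med, sd, lo, hi in [
        ("haemoglobin", 13.2, 1.8, 6.0, 19.0),
        ("creatinine", 82, 25, 30, 400),
        ("sodium", 139, 3, 120, 152),
        ("potassium", 4.2, 0.4, 2.8, 6.2),
        ("albumin", 40, 5, 15, 55),
        ("urea", 6.0, 2.5, 1.0, 30.0),
        ("white_cell_count", 7.5, 2.2, 2.0, 25.0),
        ("platelets", 260, 80, 50, 800),
        ("crp", 6, 12, 0, 200),
        ("hba1c", 40, 9, 20, 110),
        ("egfr", 78, 18, 10, 120),
        ("bilirubin", 10, 5, 2, 60),
        ("alt", 24, 12, 5, 200),
        ("alkaline_phosphatase", 85, 30, 20, 400),
    ]:
        m[name] = TruncNormal(med, sd, lo, hi)
    # --- cardiopulmonary fitness (46 features) -------------------------
    m["mets"] = TruncNormal(4.5, _iqr_sd(3.7, 5.5), 1.47, 10.7)
    m["at_vo2"] = TruncNormal(10.5, _iqr_sd(9.0, 12.4), 2.9, 25.0)
    m["peak_vo2"] = TruncNormal(17.0, _iqr_sd(14.0, 20.5), 8.2, 46.0)
    m["peak_ve_vco2"] = TruncNormal(34.5, _iqr_sd(31.4, 38.8), 17.5, 56.0)
    for name, med, sd, lo, hi in [
        ("at_ve_vco2", 33.0, 5.0, 18, 60), ("rest_ve_vco2", 38.0, 6.0, 20, 70),
        ("peak_ve_vo2", 36.0, 6.5, 16, 65), ("at_ve_vo2", 29.0, 5.0, 14, 55),
        ("rest_ve_vo2", 33.0, 6.0, 15, 65),
        ("peak_petco2", 4.6, 0.6, 2.5, 7.0), ("at_petco2", 5.0, 0.6, 3.0, 7.5),
        ("rest_petco2", 4.8, 0.5, 3.0, 7.0),
        ("peak_peto2", 15.5, 0.9, 12.0, 18.5), ("at_peto2", 14.4, 0.9, 11.0, 18.0),
        ("rest_peto2", 14.9, 0.9, 11.5, 18.0),
        ("peak_o2_pulse", 10.5, 3.0, 3.0, 25.0), ("at_o2_pulse", 8.5, 2.5, 2.5, 22.0),
        ("rest_o2_pulse", 4.0, 1.3, 1.0, 12.0),
        ("peak_hr", 128, 20, 70, 190), ("at_hr", 103, 16, 55, 170),
        ("rest_hr", 76, 12, 40, 130),
        ("heart_rate_reserve", 52, 22, 0, 120),
        ("peak_rer", 1.12, 0.10, 0.80, 1.50), ("at_rer", 0.92, 0.07, 0.70, 1.20),
        ("rest_rer", 0.84, 0.07, 0.60, 1.15),
        ("peak_workload", 104, 35, 20, 280), ("at_workload", 62, 24, 5, 200),
        ("peak_ve", 58, 17, 18, 140), ("at_ve", 33, 10, 10, 90),
        ("rest_ve", 11, 3, 4, 28),
        ("peak_vt", 1.9, 0.55, 0.6, 4.0), ("at_vt", 1.4, 0.40, 0.4, 3.2),
        ("rest_vt", 0.75, 0.22, 0.3, 2.0),
        ("peak_bf", 32, 7, 14, 60), ("at_bf", 24, 6, 10, 50),
        ("rest_bf", 15, 4, 6, 35),
        ("peak_vco2", 1.65, 0.55, 0.4, 4.5), ("at_vco2", 0.90, 0.30, 0.2, 2.8),
        ("rest_vco2", 0.26, 0.07, 0.1, 0.7),
        ("rest_vo2", 0.30, 0.08, 0.1, 0.8),
        ("vo2_work_slope", 9.8, 1.4, 5.0, 15.0),
        ("oues", 1.9, 0.6, 0.5, 4.5),
        ("bp_systolic_rest", 134, 17, 85, 210), ("bp_diastolic_rest", 79, 10, 45, 120),
        ("spo2_rest", 97, 1.4, 88, 100), ("spo2_peak", 96, 2.0, 80, 100),
    ]:
        m[name] = TruncNormal(med, sd, lo, hi)
    return m


_CLINICAL = (
    "age", "sex", "bmi", "asa", "dasi", "ethnicity", "surgical_specialty",
    "hypertension", "diabetes", "angina", "coronary_stent", "cabg",
    "chronic_cardiac_failure", "peripheral_vascular_disease", "cva_tia",
    "copd", "asthma", "pulmonary_embolism", "pulmonary_fibrosis", "smoking",
    "previous_myocardial_ischaemia", "beta_blocker", "nitrates",
    "ace_inhibitor", "statin", "haemoglobin", "creatinine", "sodium",
    "potassium", "albumin", "urea", "white_cell_count", "platelets", "crp",
    "hba1c", "egfr", "bilirubin", "alt", "alkaline_phosphatase",
)

DEFAULT_EFFECTS = (
    Effect("peak_ve_vco2", "linear", 34.5, 0.15),
    Effect("bmi", "threshold_above", 28.0, -0.8),
    Effect("peak_ve_vo2", "threshold_above", 38.0, -0.6),
    Effect("previous_myocardial_ischaemia", "linear", 0.0, 0.7),
)

DEFAULT_CORRELATIONS = (("peak_vo2", "at_vo2", 0.7),)

DEFAULT_PREVALENCE = 0.055

_calibration_cache: dict = {}


def calibrate_baseline_logit(config: GeneratorConfig,
                             target_prevalence: float = DEFAULT_PREVALENCE,
                             n_mc: int = 100_000) -> float:
    """Solve for the intercept making E[expit(b + eta)] hit the target.

    The effect-term distribution eta is estimated once by Monte Carlo from
    the configured marginals (effect features are sampled independently —
    the default correlation pairs do not link effect features); the
    intercept then comes from a deterministic root find.  The internal
    sampling seed is fixed so calibration is a property of the config, not
    of the user's simulation seed.
    """
    key = (tuple(config.effects), target_prevalence, n_mc,
           tuple((f, config.marginals[f]) for e in config.effects
                 for f in (e.feature,)))
    if key in _calibration_cache:
        return _calibration_cache[key]
    rng = substream(987654321, "calibrate")
    eta = np.zeros(n_mc)
    for eff in config.effects:
        u = rng.random(n_mc)
        x = config.marginals[eff.feature].ppf(u)
        eta += eff.contribution(np.asarray(x, dtype=float))

    def excess(b):
        return float(np.mean(expit(b + eta))) - target_prevalence

    b = brentq(excess, -30, 30, xtol=1e-10)
    _calibration_cache[key] = b
    return b


def default_config(n_patients: int = 1190, seed: int = 0,
                   missing_rate: float = 0.0,
                   target_prevalence: float = DEFAULT_PREVALENCE) -> GeneratorConfig:
    """The study-condition configuration: Table-style marginals, planted
    risk directions, intercept calibrated to ~5.5% 1-year mortality."""
    marginals = _default_marginals()
    cfg = GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        baseline_logit=0.0,
        effects=DEFAULT_EFFECTS,
        marginals=marginals,
        missing_rate=missing_rate,
        correlations=DEFAULT_CORRELATIONS,
        clinical_features=_CLINICAL,
        fitness_features=tuple(f for f in marginals if f not in _CLINICAL),
    )
    cfg.baseline_logit = calibrate_baseline_logit(cfg, target_prevalence)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# sampling

def _copula_matrix(config: GeneratorConfig) -> np.ndarray:
    names = config.feature_order
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for a, b, rho in config.correlations:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ConfigError("correlation specification is not positive definite") from None


def sample_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort table: id column, features in config order, outcome.

    Deterministic under (config, seed); marginals flow through a Gaussian
    copula so declared pairs are rank-correlated and everything else is
    independent.
    """
    config.validate()
    names = config.feature_order
    n = config.n_patients
    schema = config.schema()
    if n == 0:
        data = {config.schema().id_column: pd.Series([], dtype=object)}
        for name in names:
            spec = config.marginals[name]
            dtype = float if isinstance(spec, TruncNormal) else (
                int if isinstance(spec, Bernoulli) else object)
            data[name] = pd.Series([], dtype=dtype)
        data[OUTCOME_COLUMN] = pd.Series([], dtype=int)
        return pd.DataFrame(data)

    L = _copula_matrix(config)
    rng = substream(config.seed, "cohort")
    z = rng.standard_normal((n, len(names))) @ L.T
    u = norm.cdf(z)

    data: dict[str, object] = {
        schema.id_column: [f"P{i:06d}" for i in range(1, n + 1)]}
    for j, name in enumerate(names):
        data[name] = config.marginals[name].ppf(u[:, j])
    df = pd.DataFrame(data)

    eta = np.full(n, config.baseline_logit)
    for eff in config.effects:
        eta += eff.contribution(df[eff.feature].to_numpy(dtype=float))
    p = expit(eta)
    df[OUTCOME_COLUMN] = (substream(config.seed, "outcome").random(n) < p).astype(int)

    if config.missing_rate > 0:
        df = inject_missingness(df, config.missing_rate, config.seed)
    return df


def outcome_probability(record: Mapping[str, float],
                        config: GeneratorConfig) -> float:
    """P(death within 1 year) for one patient record under the planted
    logistic mechanism; strictly inside (0, 1)."""
    eta = config.baseline_logit
    for eff in config.effects:
        if eff.feature not in record:
            raise KeyError(f"record is missing required feature {eff.feature!r}")
        x = record[eff.feature]
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise ValueError(f"required feature {eff.feature!r} is missing (NaN)")
        eta += float(eff.contribution(np.asarray([x], dtype=float))[0])
    return float(expit(eta))


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set each non-id, non-outcome cell missing independently with
    probability ``rate`` (MCAR); seed-reproducible."""
    if not 0 <= rate < 1:
        raise ValueError(f"missing rate {rate} outside [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = substream(seed, "missing")
    cols = [c for c in table.columns if c not in (ID_COLUMN, OUTCOME_COLUMN)]
    mask = rng.random((len(table), len(cols))) < rate
    for j, c in enumerate(cols):
        col = out[c]
        if mask[:, j].any():
            if col.dtype.kind in "iub":
                col = col.astype(float)
            out[c] = col.mask(pd.Series(mask[:, j], index=out.index))
    return out


# ---------------------------------------------------------------------------
# CSV round trip

def write_cohort(table: pd.DataFrame, path) -> None:
    """UTF-8 CSV, '.' decimal separator, missing cells as empty fields."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path, schema: CohortSchema | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    With a schema: enforces column set, category labels and dtypes.
    Always enforces the outcome invariant (present, never missing, 0/1).
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise CohortParseError(f"cannot parse cohort file {path}: {exc}") from exc
    if OUTCOME_COLUMN not in df.columns:
        raise CohortParseError(f"missing outcome column {OUTCOME_COLUMN!r}")
    bad = df.index[df[OUTCOME_COLUMN].isna()]
    if len(bad):
        raise CohortParseError(
            f"missing outcome value at row {int(bad[0])} "
            f"(column {OUTCOME_COLUMN!r})")
    if not df[OUTCOME_COLUMN].isin((0, 1)).all():
        bad = df.index[~df[OUTCOME_COLUMN].isin((0, 1))][0]
        raise CohortParseError(
            f"outcome value outside {{0,1}} at row {int(bad)}")
    df[OUTCOME_COLUMN] = df[OUTCOME_COLUMN].astype(int)
    if schema is not None:
        missing_cols = set(schema.columns) - set(df.columns)
        if missing_cols:
            raise CohortParseError(f"missing columns: {sorted(missing_cols)}")
        for col, levels in schema.categorical.items():
            vals = df[col].dropna()
            unknown = set(vals) - set(levels)
            if unknown:
                label = sorted(unknown)[0]
                row = int(df.index[df[col] == label][0])
                raise CohortParseError(
                    f"unknown category label {label!r} in column {col!r} "
                    f"at row {row}")
        for col in schema.continuous:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                                    & df[col].notna()]
                loc = int(bad_rows[0]) if len(bad_rows) else -1
                raise CohortParseError(
                    f"non-numeric value in continuous column {col!r} at row {loc}")
        for col in schema.binary:
            vals = df[col].dropna()
            if not vals.isin((0, 1)).all():
                row = int(df.index[~df[col].isin((0, 1)) & df[col].notna()][0])
                raise CohortParseError(
                    f"non-binary value in column {col!r} at row {row}")
        df = df[schema.columns]
    return df


# ---------------------------------------------------------------------------
# planted test beds

def sample_planted_logistic(n: int, coefficients: Sequence[float] = (3.0, -3.0),
                            intercept: float = 0.0, feature_sd: float = 2.0,
                            n_noise: int = 0, seed: int = 0,
                            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Logistic data with a known planted linear signal.

    Signal features x1..xk ~ N(0, feature_sd^2) carry the given logit
    coefficients; optional noise features carry none.  The default spread
    (sd 2) makes the coefficient-3 signal strong: the Bayes-optimal
    classifier reaches F1 ~ 0.94 at prevalence 0.5.
    """
    rng = substream(seed, "fixture")
    k = len(coefficients)
    X = rng.normal(0.0, feature_sd, size=(n, k + n_noise))
    eta = intercept + X[:, :k] @ np.asarray(coefficients, dtype=float)
    y = (rng.random(n) < expit(eta)).astype(int)
    cols = [f"x{i + 1}" for i in range(k + n_noise)]
    return pd.DataFrame(X, columns=cols), y


def _fixture_separable(seed: int):
    """n = 200, y = 1 iff x1 > 0, class margin 0.5 around the boundary;
    one noise feature."""
    rng = substream(seed, "fixture")
    n = 200
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    x1 = sign * (0.25 + rng.random(n))  # |x1| in [0.25, 1.25] -> margin 0.5
    x2 = rng.normal(0, 1, n)
    y = (x1 > 0).astype(int)
    return pd.DataFrame({"x1": x1, "x2": x2}), y


def _fixture_null(seed: int):
    """n = 200, prevalence 10%, no association between features and outcome."""
    rng = substream(seed, "fixture")
    n = 200
    X = pd.DataFrame(rng.normal(0, 1, size=(n, 3)), columns=["x1", "x2", "x3"])
    y = (rng.random(n) < 0.10).astype(int)
    return X, y


def _fixture_imbalanced(seed: int):
    """n = 200, ~10% prevalence, one planted linear signal on x1."""
    X, y = sample_planted_logistic(200, coefficients=(3.0,), intercept=-3.0,
                                   feature_sd=1.0, n_noise=2, seed=seed)
    return X, y


FIXTURES = {
    "separable": (_fixture_separable, 1),
    "null": (_fixture_null, 1),
    "imbalanced": (_fixture_imbalanced, 1),
}


def make_fixture(name: str, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Small deterministic datasets used by the test suite and CLI."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    fn, version = FIXTURES[name]
    X, y = fn(seed)
    return X, y, {"name": name, "version": version, "seed": seed}
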