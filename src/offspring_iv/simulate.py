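"""Synthetic parent-offspring ("trio") cohorts with known causal structure.

The generator draws, per family, a shared familial factor G (genes plus
shared environment), a confounder U of the BMI / sick-leave relation, and a
latent illness indicator D that lowers the parent's BMI while raising their
hazard (reverse causation).  Parent and offspring BMI z-scores are linear
in these factors with residual variances chosen so both have unit variance;
long-term sick-leave onset is exponential given covariates (constant
baseline hazard, so proportional hazards holds by construction), observed
on the age axis with delayed entry at the baseline age and administrative
censoring.  With ``loading_confounder_offspring = 0`` the offspring z-score
is a valid instrument: correlated with parent BMI through G only,
independent of U and D.

BMI in kg/m2 is obtained by destandardizing the z-scores against built-in
stratum means/SDs (adults) or a synthetic LMS reference (offspring under
18), so the standardization stage can be exercised end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .standardize import age_category, synthetic_lms_reference

__all__ = [
    "CovariateSpec",
    "DEFAULT_COVARIATES",
    "SimulationConfig",
    "expected_instrument_slope",
    "read_trios",
    "simulate_trios",
    "write_trios",
]


EDUCATION_LEVELS = (1, 2, 3, 4, 5, 6)
EGP_LEVELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
SMOKING_LEVELS = ("never", "ex", "occasional", "daily")
ALCOHOL_LEVELS = (
    "never_drunk",
    "none_last_year",
    "monthly_or_less",
    "2_4_per_month",
    "2_3_per_week",
    "4plus_per_week",
)
ACTIVITY_LEVELS = ("inactive", "low", "moderate", "high")

CAUSES = ("musculoskeletal", "mental", "other")


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered-categorical covariate generated from a logistic latent.

    latent = coef_u*U + coef_x*X_parent + coef_g*G + standard-logistic noise;
    the category is the interval of the latent between cut-points placed at
    logistic quantiles of the target marginal probabilities.  Signs of the
    coefficients set the direction of the covariate-BMI associations; a
    loading on G (e.g. smoking) produces associations of opposite sign with
    own and offspring BMI.
    """

    name: str
    levels: tuple
    probs: tuple
    coef_u: float = 0.0
    coef_x: float = 0.0
    coef_g: float = 0.0

    def __post_init__(self):
        if len(self.levels) != len(self.probs):
            raise ValueError(f"{self.name}: levels/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) <= 0:
            raise ValueError(f"{self.name}: probs must be positive and sum to 1")


# Defaults reproduce the direction of the observed covariate-BMI patterns:
# low education, lower-status occupation and low physical activity go with
# higher BMI (positive confounder loading), frequent alcohol with lower BMI,
# and smoking with lower own BMI but higher offspring BMI (via the shared
# familial factor).
DEFAULT_COVARIATES = (
    CovariateSpec("education", EDUCATION_LEVELS,
                  (0.02, 0.28, 0.30, 0.08, 0.22, 0.10), coef_u=-0.5, coef_x=-0.15),
    CovariateSpec("occupation_egp", EGP_LEVELS,
                  (0.12, 0.18, 0.18, 0.10, 0.06, 0.06, 0.15, 0.15),
                  coef_u=0.5, coef_x=0.10),
    CovariateSpec("smoking", SMOKING_LEVELS,
                  (0.45, 0.30, 0.05, 0.20), coef_x=-0.35, coef_g=0.45),
    CovariateSpec("alcohol", ALCOHOL_LEVELS,
                  (0.03, 0.05, 0.30, 0.40, 0.17, 0.05), coef_u=-0.45, coef_x=-0.10),
    CovariateSpec("physical_activity", ACTIVITY_LEVELS,
                  (0.08, 0.30, 0.42, 0.20), coef_u=-0.45, coef_x=-0.15),
)

# Built-in destandardization references (kg/m2): sex-specific base mean/SD
# plus additive shifts by age category and survey wave (secular trend).
PARENT_BMI_BASE = {"F": (26.6, 4.7), "M": (27.7, 3.6)}
OFFSPRING_BMI_BASE = {"F": (24.8, 4.6), "M": (24.7, 4.6)}
AGE_CAT_SHIFT = {"<30": -1.2, "30-39.9": -0.4, "40-49.9": 0.2, ">=50": 0.6}
WAVE_SHIFT = {3: 0.0, 4: 0.4}


@dataclass
class SimulationConfig:
    """Structural parameters of the synthetic cohort.

    Loadings are on the z-score (SD) scale; ``beta_true``,
    ``gamma_confounder`` and ``delta_illness_hazard`` are log hazard ratios;
    ``baseline_rate`` is in events per person-year.
    """

    n_families: int = 10_000
    seed: int = 0
    loading_familial: float = float(np.sqrt(0.24))
    loading_confounder_parent: float = 0.3
    loading_confounder_offspring: float = 0.0
    beta_true: float = 0.15
    gamma_confounder: float = 0.3
    p_illness: float = 0.08
    delta_illness_bmi: float = -0.4
    delta_illness_hazard: float = 0.5
    baseline_rate: float = 0.08
    entry_age_range: tuple = (25.0, 60.0)
    max_age: float = 65.0
    admin_censor_years: float = 9.0
    cause_mix: tuple = (0.45, 0.16, 0.39)  # musculoskeletal, mental, other
    max_siblings: int = 1
    female_fraction: float = 0.56
    wave4_fraction: float = 0.5
    offspring_age_mean: float = 23.5
    offspring_age_sd: float = 8.0
    offspring_age_range: tuple = (13.0, 45.0)
    missing_covariate_rate: float = 0.0
    offspring_missing_rate: float = 0.0
    baseline_exclusion_rate: float = 0.0
    covariates: tuple = DEFAULT_COVARIATES

    def __post_init__(self):
        self.validate()

    # residual variances implied by unit-variance z-scores
    @property
    def resid_var_parent(self) -> float:
        p = self.p_illness
        return (
            1.0
            - self.loading_familial**2
            - self.loading_confounder_parent**2
            - self.delta_illness_bmi**2 * p * (1.0 - p)
        )

    @property
    def resid_var_offspring(self) -> float:
        return 1.0 - self.loading_familial**2 - self.loading_confounder_offspring**2

    def validate(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.p_illness <= 1.0:
            raise ValueError("p_illness must lie in [0, 1]")
        if abs(sum(self.cause_mix) - 1.0) > 1e-12 or min(self.cause_mix) < 0:
            raise ValueError("cause_mix must be non-negative and sum to 1")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        lo, hi = self.entry_age_range
        if not (18.0 < lo < hi < self.max_age):
            raise ValueError(
                f"entry_age_range {self.entry_age_range} must lie within "
                f"(18, max_age={self.max_age})"
            )
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be positive")
        if self.max_siblings < 1:
            raise ValueError("max_siblings must be >= 1")
        if self.resid_var_parent <= 0:
            raise ValueError(
                "loadings imply non-positive residual variance for the parent "
                f"z-score ({self.resid_var_parent:.4f}); reduce the loadings"
            )
        if self.resid_var_offspring <= 0:
            raise ValueError(
                "loadings imply non-positive residual variance for the "
                f"offspring z-score ({self.resid_var_offspring:.4f})"
            )

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = [dataclasses.asdict(c) for c in self.covariates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = tuple(
                CovariateSpec(**{**c, "levels": tuple(c["levels"]),
                                 "probs": tuple(c["probs"])})
                for c in d["covariates"]
            )
        for key in ("entry_age_range", "offspring_age_range", "cause_mix"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=False)


def expected_instrument_slope(config: SimulationConfig) -> float:
    """Closed-form slope of parent z on offspring z.

    cov(X_p, X_o) = a^2 + b_p*b_o with unit variances on both sides, so the
    regression slope (and the correlation) equals the covariance.
    """
    return (
        config.loading_familial**2
        + config.loading_confounder_parent * config.loading_confounder_offspring
    )


def _draw_ordinal(rng, spec: CovariateSpec, U, Xp, G, var_lp: float):
    lp = spec.coef_u * U + spec.coef_x * Xp + spec.coef_g * G
    noise = rng.logistic(size=len(U))
    latent = lp + noise
    # cut-points at logistic quantiles of the cumulative target probabilities,
    # inflated for the extra latent variance so marginals stay near target
    cum = np.cumsum(spec.probs)[:-1]
    scale = np.sqrt(1.0 + 3.0 * var_lp / np.pi**2)
    cuts = scale * np.log(cum / (1.0 - cum))
    idx = np.searchsorted(cuts, latent, side="right")
    return np.asarray(spec.levels, dtype=object)[idx]


def simulate_trios(config: SimulationConfig) -> pd.DataFrame:
    """Generate a trio cohort; one row per parent-offspring pair.

    With ``max_siblings > 1`` each parent contributes 1..max_siblings
    offspring rows (sibling sets sharing G and U), to exercise downstream
    offspring selection.  Fixing (seed, n_families) reproduces the dataset
    bit for bit.
    """
    config.validate()
    rng = np.random.default_rng((int(config.seed), int(config.n_families)))
    n = config.n_families
    a = config.loading_familial
    bp = config.loading_confounder_parent
    bo = config.loading_confounder_offspring

    G = rng.normal(size=n)
    U = rng.normal(size=n)
    D = (rng.uniform(size=n) < config.p_illness).astype(float)
    Xp = (
        a * G
        + bp * U
        + config.delta_illness_bmi * D
        + rng.normal(0.0, np.sqrt(config.resid_var_parent), n)
    )

    lo, hi = config.entry_age_range
    entry = rng.uniform(lo, hi, n)
    hazard = config.baseline_rate * np.exp(
        config.beta_true * Xp
        + config.gamma_confounder * U
        + config.delta_illness_hazard * D
    )
    event_age = entry + rng.exponential(1.0, n) / hazard
    censor_age = np.minimum(entry + config.admin_censor_years, config.max_age)
    event = event_age <= censor_age
    exit_age = np.where(event, event_age, censor_age)

    cause = np.full(n, "none", dtype=object)
    cause[event] = rng.choice(CAUSES, size=int(event.sum()), p=config.cause_mix)
    censor_reason = np.where(
        event, "event", np.where(censor_age >= config.max_age, "age65", "admin")
    )

    parent_sex = np.where(rng.uniform(size=n) < config.female_fraction, "F", "M")
    wave = np.where(rng.uniform(size=n) < config.wave4_fraction, 4, 3)

    # parent BMI: destandardize within (sex, age category, wave) strata
    cat = age_category(entry)
    p_mean = np.array([PARENT_BMI_BASE[s][0] for s in parent_sex])
    p_sd = np.array([PARENT_BMI_BASE[s][1] for s in parent_sex])
    p_mean = p_mean + np.array([AGE_CAT_SHIFT[c] for c in cat])
    p_mean = p_mean + np.array([WAVE_SHIFT[w] for w in wave])
    parent_bmi = p_mean + p_sd * Xp

    var_lp_cache = {}

    def var_lp(spec):
        if spec.name not in var_lp_cache:
            # Var(cu*U + cx*Xp + cg*G) from the structural covariances
            var_lp_cache[spec.name] = (
                spec.coef_u**2
                + spec.coef_x**2
                + spec.coef_g**2
                + 2.0 * spec.coef_u * spec.coef_x * bp
                + 2.0 * spec.coef_x * spec.coef_g * a
            )
        return var_lp_cache[spec.name]

    covariate_cols = {
        spec.name: _draw_ordinal(rng, spec, U, Xp, G, var_lp(spec))
        for spec in config.covariates
    }

    disability = rng.uniform(size=n) < config.baseline_exclusion_rate

    # offspring: sibling sets share G and U
    if config.max_siblings > 1:
        n_off = rng.integers(1, config.max_siblings + 1, size=n)
    else:
        n_off = np.ones(n, dtype=int)
    rep = np.repeat(np.arange(n), n_off)
    m = len(rep)
    Xo = (
        a * G[rep]
        + bo * U[rep]
        + rng.normal(0.0, np.sqrt(config.resid_var_offspring), m)
    )
    off_age = np.clip(
        rng.normal(config.offspring_age_mean, config.offspring_age_sd, m),
        *config.offspring_age_range,
    )
    off_sex = np.where(rng.uniform(size=m) < 0.5, "F", "M")
    off_wave = np.where(rng.uniform(size=m) < config.wave4_fraction, 4, 3)

    off_bmi = np.empty(m)
    adult = off_age >= 18.0
    if adult.any():
        o_cat = age_category(off_age[adult])
        o_mean = np.array([OFFSPRING_BMI_BASE[s][0] for s in off_sex[adult]])
        o_sd = np.array([OFFSPRING_BMI_BASE[s][1] for s in off_sex[adult]])
        o_mean = o_mean + np.array([AGE_CAT_SHIFT[c] for c in o_cat])
        o_mean = o_mean + np.array([WAVE_SHIFT[w] for w in off_wave[adult]])
        off_bmi[adult] = o_mean + o_sd * Xo[adult]
    if (~adult).any():
        lms = synthetic_lms_reference()
        off_bmi[~adult] = lms.destandardize(
            np.clip(Xo[~adult], -4.0, 4.0), off_sex[~adult], off_age[~adult]
        )

    if config.offspring_missing_rate > 0:
        off_bmi = np.where(
            rng.uniform(size=m) < config.offspring_missing_rate, np.nan, off_bmi
        )

    df = pd.DataFrame(
        {
            "family_id": np.array([f"F{i:06d}" for i in rep]),
            "parent_id": np.array([f"P{i:06d}" for i in rep]),
            "parent_sex": parent_sex[rep],
            "survey_wave": wave[rep],
            "baseline_age": entry[rep],
            "parent_bmi": parent_bmi[rep],
            "offspring_id": np.array(
                [f"O{i:06d}_{k}" for i, k in zip(rep, _sibling_rank(rep))]
            ),
            "offspring_age": off_age,
            "offspring_sex": off_sex,
            "offspring_wave": off_wave,
            "offspring_bmi": off_bmi,
            **{k: v[rep] for k, v in covariate_cols.items()},
            "entry_age": entry[rep],
            "exit_age": exit_age[rep],
            "event": event[rep].astype(int),
            "cause": cause[rep],
            "censor_reason": censor_reason[rep],
            "disability_at_baseline": disability[rep].astype(int),
            "parent_z_true": Xp[rep],
            "offspring_z_true": Xo,
            "confounder_true": U[rep],
            "illness_true": D[rep].astype(int),
        }
    )

    if config.missing_covariate_rate > 0:
        for spec in config.covariates:
            mask = rng.uniform(size=m) < config.missing_covariate_rate
            col = df[spec.name].astype(object)
            col[mask] = np.nan
            df[spec.name] = col
    return df


def _sibling_rank(rep: np.ndarray) -> np.ndarray:
    """0, 1, 2... within runs of equal parent index (rep is sorted)."""
    if len(rep) == 0:
        return rep
    starts = np.r_[0, np.flatnonzero(np.diff(rep)) + 1]
    return np.arange(len(rep)) - np.repeat(starts, np.diff(np.r_[starts, len(rep)]))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_trios(df: pd.DataFrame, path, config: SimulationConfig | None = None):
    """Write a trio table as CSV (UTF-8, header row, missing = empty field).

    If the generating config is supplied, it is recorded (seed included) in
    a ``<path>.meta.json`` sidecar so the dataset is reproducible.
    """
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        meta = {"config": _jsonable(config.to_dict()), "n_rows": int(len(df))}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )


def read_trios(path) -> pd.DataFrame:
    return pd.read_csv(path)
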