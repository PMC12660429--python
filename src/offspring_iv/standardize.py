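"""BMI standardization: stratified adult z-scores, LMS z-scores, categories.

Adults are z-scored within strata of age category at baseline (<30,
30-39.9, 40-49.9, >=50 years), sex, and survey wave, using the stratum
sample mean and SD.  Under-18 offspring are z-scored against an external
LMS (Box-Cox lambda / median / coefficient-of-variation) growth reference,
interpolated linearly in age.  BMI categories follow the conventional
six-band clinical cut-points with 20.0-24.9 kg/m2 as the reference band.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGE_CATEGORIES",
    "BMI_CATEGORIES",
    "BMI_REFERENCE_CATEGORY",
    "StratumStats",
    "age_category",
    "bmi_category",
    "destandardize",
    "fit_strata",
    "lms_destandardize",
    "lms_zscore",
    "LmsReference",
    "StratumZScorer",
    "synthetic_lms_reference",
    "zscore",
]

AGE_CATEGORIES = ("<30", "30-39.9", "40-49.9", ">=50")
_AGE_EDGES = (30.0, 40.0, 50.0)

BMI_CATEGORIES = ("<18.5", "18.5-19.9", "20.0-24.9", "25.0-29.9", "30.0-34.9", ">=35.0")
BMI_REFERENCE_CATEGORY = "20.0-24.9"
_BMI_EDGES = (18.5, 20.0, 25.0, 30.0, 35.0)


def age_category(age):
    """Age category at baseline; intervals are closed left, open right.

    An age of exactly 30, 40 or 50 falls in the higher category.
    """
    age = np.asarray(age, float)
    idx = np.searchsorted(_AGE_EDGES, age, side="right")
    if np.ndim(idx) == 0:
        return AGE_CATEGORIES[int(idx)]
    return np.asarray(AGE_CATEGORIES)[idx]


def bmi_category(bmi):
    """Six-band BMI category; intervals closed left, open right."""
    bmi = np.asarray(bmi, float)
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    idx = np.searchsorted(_BMI_EDGES, bmi, side="right")
    if np.ndim(idx) == 0:
        return BMI_CATEGORIES[int(idx)]
    return np.asarray(BMI_CATEGORIES)[idx]


@dataclass(frozen=True)
class StratumStats:
    """Sample mean and SD of BMI within one (age category, sex, wave) stratum."""

    age_category: str
    sex: str
    survey_wave: int
    mean_bmi: float
    sd_bmi: float
    n: int

    def __post_init__(self):
        if self.sd_bmi <= 0:
            raise ValueError(f"stratum {self._key()} has non-positive SD")
        if self.n < 2:
            raise ValueError(f"stratum {self._key()} has n={self.n} < 2")

    def _key(self):
        return (self.age_category, self.sex, self.survey_wave)


def fit_strata(
    df: pd.DataFrame,
    *,
    bmi_col: str = "bmi",
    age_col: str = "age",
    sex_col: str = "sex",
    wave_col: str = "survey_wave",
) -> list[StratumStats]:
    """Per-stratum sample mean and SD (denominator n-1) of BMI.

    Every record must fall in exactly one stratum; a stratum with fewer
    than two records or zero variance raises an error naming the stratum.
    """
    work = pd.DataFrame(
        {
            "bmi": np.asarray(df[bmi_col], float),
            "age_category": age_category(df[age_col]),
            "sex": df[sex_col].to_numpy(),
            "survey_wave": df[wave_col].to_numpy(),
        }
    )
    if work["bmi"].isna().any():
        raise ValueError("missing BMI values; exclude them before fitting strata")
    out = []
    for key, grp in work.groupby(["age_category", "sex", "survey_wave"], sort=True):
        if len(grp) < 2:
            raise ValueError(f"stratum {key} has only {len(grp)} record(s)")
        sd = float(grp["bmi"].std(ddof=1))
        if sd == 0:
            raise ValueError(f"stratum {key} has zero BMI variance")
        out.append(
            StratumStats(
                age_category=key[0],
                sex=str(key[1]),
                survey_wave=int(key[2]),
                mean_bmi=float(grp["bmi"].mean()),
                sd_bmi=sd,
                n=len(grp),
            )
        )
    return out


def zscore(bmi, stats: StratumStats):
    """z = (bmi - stratum mean) / stratum SD."""
    return (np.asarray(bmi, float) - stats.mean_bmi) / stats.sd_bmi


def destandardize(z, stats: StratumStats):
    """Inverse of :func:`zscore`: bmi = mean + z * SD (exact round trip)."""
    return stats.mean_bmi + np.asarray(z, float) * stats.sd_bmi


def strata_to_frame(strata: list[StratumStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in strata])


def strata_from_frame(df: pd.DataFrame) -> list[StratumStats]:
    return [
        StratumStats(
            age_category=r.age_category,
            sex=r.sex,
            survey_wave=int(r.survey_wave),
            mean_bmi=float(r.mean_bmi),
            sd_bmi=float(r.sd_bmi),
            n=int(r.n),
        )
        for r in df.itertuples()
    ]


class StratumZScorer:
    """Transformer mapping raw BMI to within-stratum z-scores.

    scikit-learn style: ``fit`` learns the stratum means/SDs from a
    DataFrame with BMI, age, sex and wave columns; ``transform`` returns
    the z-scores; ``inverse_transform`` destandardizes exactly.  The fitted
    table is exposed as ``strata_`` and can be persisted via
    :func:`strata_to_frame` so z-scoring is reproducible across runs.
    """

    def __init__(
        self,
        bmi_col: str = "bmi",
        age_col: str = "age",
        sex_col: str = "sex",
        wave_col: str = "survey_wave",
    ):
        self.bmi_col = bmi_col
        self.age_col = age_col
        self.sex_col = sex_col
        self.wave_col = wave_col

    def get_params(self, deep: bool = True) -> dict:
        return {
            "bmi_col": self.bmi_col,
            "age_col": self.age_col,
            "sex_col": self.sex_col,
            "wave_col": self.wave_col,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        self.strata_ = fit_strata(
            X,
            bmi_col=self.bmi_col,
            age_col=self.age_col,
            sex_col=self.sex_col,
            wave_col=self.wave_col,
        )
        self._lookup_ = {s._key(): s for s in self.strata_}
        return self

    def _stats_for(self, X: pd.DataFrame) -> list[StratumStats]:
        keys = zip(
            age_category(X[self.age_col]),
            X[self.sex_col].astype(str),
            X[self.wave_col].astype(int),
        )
        out = []
        for key in keys:
            if key not in self._lookup_:
                raise ValueError(f"no fitted stratum for {key}")
            out.append(self._lookup_[key])
        return out

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        stats = self._stats_for(X)
        bmi = np.asarray(X[self.bmi_col], float)
        mean = np.array([s.mean_bmi for s in stats])
        sd = np.array([s.sd_bmi for s in stats])
        return (bmi - mean) / sd

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, X: pd.DataFrame, z: np.ndarray) -> np.ndarray:
        stats = self._stats_for(X)
        mean = np.array([s.mean_bmi for s in stats])
        sd = np.array([s.sd_bmi for s in stats])
        return mean + np.asarray(z, float) * sd


# ---------------------------------------------------------------------------
# LMS (Box-Cox) z-scores for under-18 offspring
# ---------------------------------------------------------------------------

_L_ZERO_TOL = 1e-12


def lms_zscore(bmi, L, M, S):
    """LMS z-score: ((bmi/M)^L - 1) / (L*S), or ln(bmi/M)/S when L ~ 0.

    The two branches agree in the L -> 0 limit; the switch happens at
    |L| < 1e-12 where they are numerically indistinguishable.
    """
    bmi = np.asarray(bmi, float)
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("LMS reference requires M > 0 and S > 0")
    ratio = bmi / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pow = (np.power(ratio, L) - 1.0) / (L * S)
    z_log = np.log(ratio) / S
    return np.where(np.abs(L) < _L_ZERO_TOL, z_log, z_pow)


def lms_destandardize(z, L, M, S):
    """Inverse LMS transform: bmi = M*(1 + L*S*z)^(1/L), or M*exp(S*z)."""
    z = np.asarray(z, float)
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    base = 1.0 + L * S * z
    if np.any((np.abs(L) >= _L_ZERO_TOL) & (base <= 0)):
        raise ValueError("z-score outside the domain of the Box-Cox inverse")
    with np.errstate(divide="ignore", invalid="ignore"):
        b_pow = M * np.power(base, 1.0 / L)
    b_log = M * np.exp(S * z)
    return np.where(np.abs(L) < _L_ZERO_TOL, b_log, b_pow)


class LmsReference:
    """An age/sex-tabulated LMS reference with linear interpolation in age.

    Expects a table with columns ``sex`` (F/M), ``age`` (years), ``L``,
    ``M``, ``S``; ages must be strictly increasing within sex.  Ages are
    clamped to the tabulated range (the grid should cover the ages you
    score).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age", "L", "M", "S"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("LMS reference requires M > 0 and S > 0")
        self._grids = {}
        for sex, grp in table.groupby("sex"):
            grp = grp.reset_index(drop=True)
            ages = grp["age"].to_numpy(float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"ages not strictly increasing for sex {sex!r}")
            self._grids[str(sex)] = (
                ages,
                grp["L"].to_numpy(float),
                grp["M"].to_numpy(float),
                grp["S"].to_numpy(float),
            )
        self.table = table.copy()

    @classmethod
    def from_csv(cls, path) -> "LmsReference":
        return cls(pd.read_csv(path))

    def lookup(self, sex, age):
        sex = np.atleast_1d(np.asarray(sex, dtype=object))
        age = np.atleast_1d(np.asarray(age, float))
        L = np.empty_like(age)
        M = np.empty_like(age)
        S = np.empty_like(age)
        for s in np.unique(sex):
            if str(s) not in self._grids:
                raise ValueError(f"no LMS reference for sex {s!r}")
            grid_age, gL, gM, gS = self._grids[str(s)]
            mask = sex == s
            a = np.clip(age[mask], grid_age[0], grid_age[-1])
            L[mask] = np.interp(a, grid_age, gL)
            M[mask] = np.interp(a, grid_age, gM)
            S[mask] = np.interp(a, grid_age, gS)
        return L, M, S

    def zscore(self, bmi, sex, age):
        L, M, S = self.lookup(sex, age)
        z = lms_zscore(np.atleast_1d(np.asarray(bmi, float)), L, M, S)
        return z if np.ndim(bmi) else float(z[0])

    def destandardize(self, z, sex, age):
        L, M, S = self.lookup(sex, age)
        bmi = lms_destandardize(np.atleast_1d(np.asarray(z, float)), L, M, S)
        return bmi if np.ndim(z) else float(bmi[0])


_SYNTHETIC_LMS_CSV = """sex,age,L,M,S
F,13.0,-1.65,19.00,0.120
F,14.0,-1.60,19.75,0.118
F,15.0,-1.55,20.40,0.116
F,16.0,-1.50,20.95,0.114
F,17.0,-1.45,21.40,0.112
F,18.0,-1.40,21.75,0.110
M,13.0,-1.80,18.70,0.122
M,14.0,-1.75,19.50,0.120
M,15.0,-1.70,20.30,0.117
M,16.0,-1.65,21.00,0.114
M,17.0,-1.60,21.60,0.111
M,18.0,-1.55,22.10,0.108
"""


def synthetic_lms_reference() -> LmsReference:
    """A small synthetic LMS growth reference for adolescents (ages 13-18).

    Synthetic stand-in with the qualitative shape of published BMI-for-age
    references (median rising through adolescence, negative Box-Cox power,
    coefficient of variation shrinking with age); it is NOT a published
    reference table and must not be used to score real data.
    """
    return LmsReference(pd.read_csv(io.StringIO(_SYNTHETIC_LMS_CSV)))
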