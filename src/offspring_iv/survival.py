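"""Proportional-hazards estimation on the age time axis.

Subjects enter the risk set at their baseline age (left truncation) and
leave at the age of first long-term sick leave or censoring.  All models
adjust, at minimum, for baseline age as a restricted cubic spline with five
knots interacted with survey wave (a separate smooth age curve per wave,
plus the wave main effect); the full adjustment appends dummy indicators
for education, occupation class, smoking, alcohol and physical activity.
Competing events (disability, death, reaching the administrative age bound)
are treated as censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._cox import ConvergenceError, CoxFit, cox_fit
from .simulate import (
    ACTIVITY_LEVELS,
    ALCOHOL_LEVELS,
    EDUCATION_LEVELS,
    EGP_LEVELS,
    SMOKING_LEVELS,
)
from .standardize import BMI_CATEGORIES, BMI_REFERENCE_CATEGORY

__all__ = [
    "HazardRatioEstimate",
    "IncidenceRate",
    "PhSplitResult",
    "SplineWaveBasis",
    "build_adjustment",
    "categorical_hr",
    "default_knots",
    "episode_split",
    "fit_cox",
    "incidence_rate",
    "natural_spline_basis",
    "ph_split_test",
]

_Z95 = 1.959963984540054  # Phi^-1(0.975)

COVARIATE_LEVELS = {
    "education": EDUCATION_LEVELS,
    "occupation_egp": EGP_LEVELS,
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "physical_activity": ACTIVITY_LEVELS,
}


@dataclass(frozen=True)
class HazardRatioEstimate:
    """Log hazard ratio with model-based SE and Wald 95% CI."""

    log_hr: float
    se: float
    n: int
    n_events: int
    label: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci95(self) -> tuple:
        return (
            float(np.exp(self.log_hr - _Z95 * self.se)),
            float(np.exp(self.log_hr + _Z95 * self.se)),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "log_hr": self.log_hr,
            "se": self.se,
            "hr": self.hr,
            "ci95": [lo, hi],
            "n": self.n,
            "n_events": self.n_events,
            "label": self.label,
        }


def default_knots(ages) -> np.ndarray:
    """Five-knot placement at the 5th/27.5th/50th/72.5th/95th percentiles."""
    ages = np.asarray(ages, float)
    knots = np.percentile(ages, [5.0, 27.5, 50.0, 72.5, 95.0])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate age distribution: knots are not distinct")
    return knots


def natural_spline_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    For K strictly increasing knots the basis has K-1 columns: the identity
    ``x`` plus K-2 cubic terms constrained to be linear beyond the boundary
    knots (zero second derivative there).  Cubic terms are scaled by
    (t_K - t_1)^2 for conditioning, the usual convention.
    """
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spline argument must be finite")
    knots = np.asarray(knots, float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need at least three knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = len(knots)
    tK, tK1 = knots[-1], knots[-2]
    scale = (knots[-1] - knots[0]) ** 2

    def tp3(t):
        return np.maximum(x - t, 0.0) ** 3

    cols = [x]
    for j in range(K - 2):
        tj = knots[j]
        term = (
            tp3(tj)
            - tp3(tK1) * (tK - tj) / (tK - tK1)
            + tp3(tK) * (tK1 - tj) / (tK - tK1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineWaveBasis:
    """Age spline crossed with survey wave: one smooth age curve per wave.

    Columns: the wave main effect (indicator of the second wave) followed by
    the spline basis within each wave.  The spline main effect is absorbed
    by the per-wave blocks, so the minimal adjustment has
    1 + 2*(K-1) = 9 columns for K = 5 knots and two waves.
    """

    knots: tuple
    waves: tuple = (3, 4)

    def __post_init__(self):
        if len(self.waves) != 2:
            raise ValueError("exactly two survey waves are supported")

    @classmethod
    def from_ages(cls, ages, waves=(3, 4)) -> "SplineWaveBasis":
        return cls(knots=tuple(default_knots(ages)), waves=tuple(waves))

    @property
    def basis_dim(self) -> int:
        return 1 + 2 * (len(self.knots) - 1)

    def matrix(self, age, wave):
        age = np.asarray(age, float)
        wave = np.asarray(wave)
        unseen = set(np.unique(wave)) - set(self.waves)
        if unseen:
            raise ValueError(f"unseen survey wave level(s): {sorted(unseen)}")
        spl = natural_spline_basis(age, np.asarray(self.knots))
        w1 = (wave == self.waves[1]).astype(float)
        cols = [w1[:, None], spl * (1.0 - w1)[:, None], spl * w1[:, None]]
        names = [f"wave{self.waves[1]}"]
        names += [f"age_s{i+1}:wave{self.waves[0]}" for i in range(spl.shape[1])]
        names += [f"age_s{i+1}:wave{self.waves[1]}" for i in range(spl.shape[1])]
        return np.hstack(cols), names


def _dummies(values, levels, name):
    values = np.asarray(values, dtype=object)
    unseen = set(pd.unique(values)) - set(levels)
    if unseen:
        raise ValueError(f"unseen {name} level(s): {sorted(map(str, unseen))}")
    cols = [(values == lev).astype(float) for lev in levels[1:]]
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0)), names


def build_adjustment(
    df: pd.DataFrame,
    basis: SplineWaveBasis,
    full: bool = False,
    *,
    age_col: str = "baseline_age",
    wave_col: str = "survey_wave",
):
    """Adjustment design matrix: age-spline-by-wave, plus covariate dummies.

    ``full=False`` gives the minimal model (9 columns); ``full=True``
    appends reference-coded dummies for the five lifestyle/socioeconomic
    covariates (23 columns).  Returns (matrix, column names).
    """
    mat, names = basis.matrix(df[age_col], df[wave_col])
    if full:
        blocks, bnames = [mat], list(names)
        for cov, levels in COVARIATE_LEVELS.items():
            if df[cov].isna().any():
                raise ValueError(
                    f"missing values in {cov}; apply exclusions before modelling"
                )
            dm, dn = _dummies(df[cov].to_numpy(), levels, cov)
            blocks.append(dm)
            bnames.extend(dn)
        mat = np.hstack(blocks)
        names = bnames
    return mat, names


def _design(df, exposure, adjustment, entry_col, exit_col, event_col):
    if isinstance(exposure, str):
        label = exposure
        xvec = np.asarray(df[exposure], float)
    else:
        label = "exposure"
        xvec = np.asarray(exposure, float)
    cols = [xvec[:, None]]
    names = [label]
    if adjustment is not None:
        adj, adj_names = (
            adjustment if isinstance(adjustment, tuple) else (adjustment, None)
        )
        adj = np.asarray(adj, float)
        cols.append(adj)
        names += adj_names or [f"adj{i}" for i in range(adj.shape[1])]
    X = np.hstack(cols)
    return (
        np.asarray(df[entry_col], float),
        np.asarray(df[exit_col], float),
        np.asarray(df[event_col]),
        X,
        names,
        label,
    )


def fit_cox(
    df: pd.DataFrame,
    exposure,
    *,
    adjustment=None,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
    ties: str = "efron",
) -> HazardRatioEstimate:
    """Hazard ratio per unit of ``exposure`` from a left-truncated Cox fit.

    ``exposure`` is a column name or an array; ``adjustment`` an optional
    design matrix (or ``(matrix, names)`` pair) from
    :func:`build_adjustment`.  Returns the estimate for the exposure
    coefficient; use :func:`offspring_iv._cox.cox_fit` directly for the full
    coefficient vector.
    """
    entry, exit_, event, X, names, label = _design(
        df, exposure, adjustment, entry_col, exit_col, event_col
    )
    fit = cox_fit(entry, exit_, event, X, ties=ties, names=names)
    return HazardRatioEstimate(
        log_hr=float(fit.params[0]),
        se=float(fit.se[0]),
        n=fit.n,
        n_events=fit.n_events,
        label=label,
    )


def categorical_hr(
    df: pd.DataFrame,
    category_col: str,
    *,
    categories=BMI_CATEGORIES,
    reference: str = BMI_REFERENCE_CATEGORY,
    adjustment=None,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> dict:
    """HR per BMI category versus the reference band, from one joint fit.

    Empty non-reference categories are omitted with a warning; an empty
    reference category is an error.
    """
    values = df[category_col].to_numpy()
    if not (values == reference).any():
        raise ValueError(f"reference category {reference!r} is empty")
    events = np.asarray(df[event_col]).astype(bool)
    present = []
    for cat in categories:
        if cat == reference:
            continue
        members = values == cat
        if not members.any():
            warnings.warn(f"category {cat!r} is empty; estimate omitted")
        elif not (members & events).any():
            # no events: the partial-likelihood maximum is at -infinity
            warnings.warn(f"category {cat!r} has no events; estimate omitted")
        else:
            present.append(cat)
    if not present:
        warnings.warn("all subjects in the reference category; nothing to estimate")
        return {}
    dummies = np.column_stack([(values == c).astype(float) for c in present])
    names = [f"{category_col}[{c}]" for c in present]
    if adjustment is not None:
        adj, adj_names = (
            adjustment if isinstance(adjustment, tuple) else (adjustment, None)
        )
        X = np.hstack([dummies, np.asarray(adj, float)])
        names = names + (adj_names or [f"adj{i}" for i in range(np.asarray(adj).shape[1])])
    else:
        X = dummies
    fit = cox_fit(
        np.asarray(df[entry_col], float),
        np.asarray(df[exit_col], float),
        np.asarray(df[event_col]),
        X,
        names=names,
    )
    out = {}
    for i, cat in enumerate(present):
        out[cat] = HazardRatioEstimate(
            log_hr=float(fit.params[i]),
            se=float(fit.se[i]),
            n=fit.n,
            n_events=fit.n_events,
            label=f"{cat} vs {reference}",
        )
    return out


@dataclass(frozen=True)
class IncidenceRate:
    rate_per_1000py: float
    person_years: float
    n_events: int

    def to_dict(self) -> dict:
        return {
            "rate_per_1000py": self.rate_per_1000py,
            "person_years": self.person_years,
            "n_events": self.n_events,
        }


def incidence_rate(
    df: pd.DataFrame,
    *,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> IncidenceRate:
    """Events per 1000 person-years at risk: 1000 * sum(events) / sum(time)."""
    time = np.asarray(df[exit_col], float) - np.asarray(df[entry_col], float)
    py = float(time.sum())
    if py <= 0:
        raise ValueError("zero person-time")
    n_ev = int(np.asarray(df[event_col]).sum())
    return IncidenceRate(1000.0 * n_ev / py, py, n_ev)


def episode_split(
    df: pd.DataFrame,
    split_time: float,
    *,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> pd.DataFrame:
    """Split every record at ``split_time`` of follow-up (exit - entry).

    Returns episode rows with a 0/1 ``late`` column.  A record whose
    follow-up ends on or before the split contributes a single early
    episode (an event exactly at the split time counts as early: the early
    period is closed on the right).
    """
    entry = np.asarray(df[entry_col], float)
    exit_ = np.asarray(df[exit_col], float)
    event = np.asarray(df[event_col]).astype(int)
    follow = exit_ - entry

    early = df.copy()
    early[exit_col] = np.minimum(exit_, entry + split_time)
    early[event_col] = np.where(follow <= split_time, event, 0)
    early["late"] = 0

    has_late = follow > split_time
    late = df.loc[has_late].copy()
    late[entry_col] = entry[has_late] + split_time
    late["late"] = 1
    return pd.concat([early, late], ignore_index=True)


@dataclass(frozen=True)
class PhSplitResult:
    """Early/late-period HRs and the Wald test of their log difference."""

    hr_early: float
    hr_late: float
    z: float
    p_value: float
    split_time: float
    n_events_early: int
    n_events_late: int
    estimates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hr_early": self.hr_early,
            "hr_late": self.hr_late,
            "z": self.z,
            "p_value": self.p_value,
            "split_time": self.split_time,
            "n_events_early": self.n_events_early,
            "n_events_late": self.n_events_late,
        }


def ph_split_test(
    df: pd.DataFrame,
    exposure: str,
    *,
    adjustment=None,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> PhSplitResult:
    """Proportional-hazards check: split follow-up at the median time to event.

    Episode-splits every record at the median follow-up time among events,
    fits a single model with an exposure-by-period interaction, and reports
    the period-specific HRs with the Wald z for their log difference.  A
    large |z| indicates the exposure effect changes over follow-up.
    """
    event = np.asarray(df[event_col]).astype(bool)
    if not event.any():
        raise ValueError("no events: cannot locate the median time to event")
    follow = np.asarray(df[exit_col], float) - np.asarray(df[entry_col], float)
    split = float(np.median(follow[event]))

    episodes = episode_split(
        df, split, entry_col=entry_col, exit_col=exit_col, event_col=event_col
    )
    n_early = int(episodes.loc[episodes["late"] == 0, event_col].sum())
    n_late = int(episodes.loc[episodes["late"] == 1, event_col].sum())
    if n_early == 0 or n_late == 0:
        raise ValueError("all events fall in one follow-up period")

    x = np.asarray(episodes[exposure], float)
    late = episodes["late"].to_numpy(float)
    cols = [x[:, None], (x * late)[:, None]]
    names = [exposure, f"{exposure}:late"]
    if adjustment is not None:
        # re-derive the adjustment on the episode rows
        basis, full = adjustment
        adj, adj_names = build_adjustment(episodes, basis, full)
        cols.append(adj)
        names += adj_names
    X = np.hstack(cols)
    fit = cox_fit(
        np.asarray(episodes[entry_col], float),
        np.asarray(episodes[exit_col], float),
        np.asarray(episodes[event_col]),
        X,
        names=names,
    )
    b0, b1 = fit.params[0], fit.params[1]
    se1 = fit.se[1]
    z = float(b1 / se1)
    return PhSplitResult(
        hr_early=float(np.exp(b0)),
        hr_late=float(np.exp(b0 + b1)),
        z=z,
        p_value=float(2.0 * sps.norm.sf(abs(z))),
        split_time=split,
        n_events_early=n_early,
        n_events_late=n_late,
        estimates={
            "log_hr_early": float(b0),
            "log_hr_interaction": float(b1),
            "se_interaction": float(se1),
        },
    )
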