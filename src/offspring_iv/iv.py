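"""Instrumental-variable ratio (Wald) estimation with delta-method CIs.

The causal log hazard ratio of the outcome per SD of own BMI is estimated
as the ratio of two ingredients: the numerator is the log HR of the outcome
per SD of offspring BMI (the reduced form, from a Cox model) and the
denominator is the mean difference in own BMI z-score per SD of offspring
BMI (from OLS with the same adjustment).  The standard error of the ratio
comes from a first-order Taylor (delta-method) expansion treating the two
ingredients as independent.  Instrument strength is summarized by the
partial R-squared and partial F of the instrument given the adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .survival import HazardRatioEstimate, build_adjustment, fit_cox, SplineWaveBasis

__all__ = [
    "InstrumentStrength",
    "IvEstimate",
    "OffspringIvEstimator",
    "WeakInstrumentError",
    "WeakInstrumentWarning",
    "denominator_regression",
    "instrument_strength",
    "iv_ratio",
    "partial_f_from_r2",
    "se_from_ci95",
    "taylor_se",
]

_Z95 = 1.959963984540054


class WeakInstrumentError(ValueError):
    """The instrument-exposure association is indistinguishable from zero."""


class WeakInstrumentWarning(UserWarning):
    """The instrument is usable but weak; the ratio may be unstable."""


def se_from_ci95(lower: float, upper: float, scale: str = "identity") -> float:
    """Back-calculate a standard error from a printed 95% CI.

    ``scale="log"`` for ratio estimates printed as HR/OR (the CI is symmetric
    on the log scale): se = (ln upper - ln lower)/3.92.  ``"identity"`` for
    mean differences: se = (upper - lower)/3.92.
    """
    if scale == "log":
        if lower <= 0 or upper <= lower:
            raise ValueError("need 0 < lower < upper for a log-scale CI")
        return float((np.log(upper) - np.log(lower)) / 3.92)
    if scale == "identity":
        if upper <= lower:
            raise ValueError("need lower < upper")
        return float((upper - lower) / 3.92)
    raise ValueError(f"unknown scale {scale!r}")


def taylor_se(num: float, num_se: float, den: float, den_se: float) -> float:
    """First-order delta-method SE of the ratio num/den (independent parts).

    se = sqrt(num_se^2/den^2 + num^2 * den_se^2 / den^4).
    """
    if den == 0:
        raise ValueError("denominator must be non-zero")
    return float(
        np.sqrt(num_se**2 / den**2 + num**2 * den_se**2 / den**4)
    )


@dataclass(frozen=True)
class IvEstimate:
    """Wald ratio estimate: numerator, denominator, ratio, Taylor SE/CI."""

    numerator_loghr: float
    numerator_se: float
    denominator_md: float
    denominator_se: float

    @property
    def beta_iv(self) -> float:
        return self.numerator_loghr / self.denominator_md

    @property
    def se_iv(self) -> float:
        return taylor_se(
            self.numerator_loghr,
            self.numerator_se,
            self.denominator_md,
            self.denominator_se,
        )

    @property
    def hr_iv(self) -> float:
        return float(np.exp(self.beta_iv))

    @property
    def ci95(self) -> tuple:
        return (
            float(np.exp(self.beta_iv - _Z95 * self.se_iv)),
            float(np.exp(self.beta_iv + _Z95 * self.se_iv)),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "numerator_loghr": self.numerator_loghr,
            "numerator_se": self.numerator_se,
            "denominator_md": self.denominator_md,
            "denominator_se": self.denominator_se,
            "beta_iv": self.beta_iv,
            "se_iv": self.se_iv,
            "hr_iv": self.hr_iv,
            "ci95": [lo, hi],
        }


def iv_ratio(numerator, denominator, *, weak_se_ratio: float = 10.0) -> IvEstimate:
    """Form the IV ratio from (log HR, se) and (mean difference, se) pairs.

    Raises :class:`WeakInstrumentError` when |md| <= md_se (the ratio is
    undefined in practice); warns when |md|/md_se is below ``weak_se_ratio``
    (default 10, roughly F < 100).
    """
    loghr, num_se = float(numerator[0]), float(numerator[1])
    md, den_se = float(denominator[0]), float(denominator[1])
    if abs(md) <= den_se:
        raise WeakInstrumentError(
            f"instrument-exposure association {md:.4g} does not exceed its "
            f"SE {den_se:.4g}; the ratio is undefined in practice"
        )
    if den_se > 0 and abs(md) / den_se < weak_se_ratio:
        warnings.warn(
            f"weak instrument: |md|/se = {abs(md)/den_se:.1f} < {weak_se_ratio:g}; "
            "the ratio estimate may be unstable",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    return IvEstimate(loghr, num_se, md, den_se)


def _ols_design(offspring_z, adjustment):
    z = np.asarray(offspring_z, float)
    cols = [np.ones_like(z)[:, None], z[:, None]]
    names = ["const", "offspring_z"]
    if adjustment is not None:
        adj, adj_names = (
            adjustment if isinstance(adjustment, tuple) else (adjustment, None)
        )
        adj = np.asarray(adj, float)
        cols.append(adj)
        names += adj_names or [f"adj{i}" for i in range(adj.shape[1])]
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns from the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    return X, names


def denominator_regression(parent_z, offspring_z, adjustment=None):
    """OLS mean difference in parent z per SD of offspring z, with its SE.

    The adjustment must match the one used in the corresponding numerator
    Cox model.  Returns ``(md, se)``.
    """
    y = np.asarray(parent_z, float)
    X, _ = _ols_design(offspring_z, adjustment)
    if len(y) < X.shape[1] + 1:
        raise ValueError("too few records for the denominator regression")
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])


@dataclass(frozen=True)
class InstrumentStrength:
    """Partial R-squared (percent) and partial F of the instrument."""

    partial_r2: float
    partial_f: float
    n: int

    def to_dict(self) -> dict:
        return {"partial_r2": self.partial_r2, "partial_f": self.partial_f, "n": self.n}


def instrument_strength(parent_z, offspring_z, adjustment=None) -> InstrumentStrength:
    """Exposure variance explained by the instrument beyond the adjustment.

    partial R^2 = (RSS_reduced - RSS_full)/RSS_reduced (in percent), where
    the reduced model drops the instrument; partial F is the one-degree
    F statistic for adding it, RSS_full/(n - p_full) in the denominator with
    p_full counting the intercept.
    """
    y = np.asarray(parent_z, float)
    X_full, _ = _ols_design(offspring_z, adjustment)
    X_red = np.delete(X_full, 1, axis=1)
    rss_full = float(sm.OLS(y, X_full).fit().ssr)
    rss_red = float(sm.OLS(y, X_red).fit().ssr)
    n, p_full = X_full.shape
    partial_r2 = (rss_red - rss_full) / rss_red
    partial_f = (rss_red - rss_full) / (rss_full / (n - p_full))
    return InstrumentStrength(100.0 * partial_r2, partial_f, n)


def partial_f_from_r2(partial_r2_percent: float, n: int, p_full: int) -> float:
    """Single-instrument identity: F = (r2/(1-r2)) * (n - p_full).

    Recovers the partial F from a printed partial R-squared (in percent),
    the sample size, and the full-model parameter count (intercept
    included).
    """
    r2 = partial_r2_percent / 100.0
    if not 0 <= r2 < 1:
        raise ValueError("partial R-squared must lie in [0, 100) percent")
    return float(r2 / (1.0 - r2) * (n - p_full))


class OffspringIvEstimator:
    """Offspring-BMI-as-instrument estimator for one sex/outcome analysis.

    scikit-learn style: configure with ``adjustment`` ("none", "minimal" =
    age-spline-by-wave, or "full" = minimal plus lifestyle/socioeconomic
    dummies) and an ``outcome`` cause ("all", "musculoskeletal", "mental");
    ``fit`` expects a prepared analysis frame with ``parent_z``,
    ``offspring_z``, ``entry_age``, ``exit_age``, ``event``, ``cause`` and
    the covariate columns.  Cause-specific outcomes censor events of other
    causes.

    Fitted attributes: ``conventional_`` (HR per SD own BMI),
    ``reduced_form_`` (HR per SD offspring BMI), ``denominator_md_`` /
    ``denominator_se_``, ``strength_``, and ``estimate_`` (the IV ratio).
    """

    def __init__(
        self,
        adjustment: str = "minimal",
        outcome: str = "all",
        weak_se_ratio: float = 10.0,
    ):
        self.adjustment = adjustment
        self.outcome = outcome
        self.weak_se_ratio = weak_se_ratio

    def get_params(self, deep: bool = True) -> dict:
        return {
            "adjustment": self.adjustment,
            "outcome": self.outcome,
            "weak_se_ratio": self.weak_se_ratio,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _adjustment_matrix(self, df):
        if self.adjustment == "none":
            return None
        if self.adjustment in ("minimal", "full"):
            basis = SplineWaveBasis.from_ages(df["baseline_age"])
            return build_adjustment(df, basis, full=self.adjustment == "full")
        raise ValueError(f"unknown adjustment {self.adjustment!r}")

    def fit(self, df: pd.DataFrame, y=None) -> "OffspringIvEstimator":
        if self.outcome not in ("all", "musculoskeletal", "mental"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        work = df.copy()
        if self.outcome != "all":
            work["event"] = (
                (work["event"].astype(bool)) & (work["cause"] == self.outcome)
            ).astype(int)
        adj = self._adjustment_matrix(work)

        self.reduced_form_ = fit_cox(work, "offspring_z", adjustment=adj)
        self.conventional_ = fit_cox(work, "parent_z", adjustment=adj)
        md, md_se = denominator_regression(
            work["parent_z"], work["offspring_z"], adjustment=adj
        )
        self.denominator_md_ = md
        self.denominator_se_ = md_se
        self.strength_ = instrument_strength(
            work["parent_z"], work["offspring_z"], adjustment=adj
        )
        self.estimate_ = iv_ratio(
            (self.reduced_form_.log_hr, self.reduced_form_.se),
            (md, md_se),
            weak_se_ratio=self.weak_se_ratio,
        )
        self.n_ = int(len(work))
        self.n_events_ = int(work["event"].sum())
        return self

    def results_(self) -> dict:
        return {
            "conventional": self.conventional_.to_dict(),
            "reduced_form": self.reduced_form_.to_dict(),
            "iv": self.estimate_.to_dict(),
            "instrument_strength": self.strength_.to_dict(),
            "n": self.n_,
            "n_events": self.n_events_,
            "adjustment": self.adjustment,
            "outcome": self.outcome,
        }
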