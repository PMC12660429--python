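"""Bias component plot: paired conventional and IV covariate associations.

For each measured covariate, regress the covariate on the exposure proxy
with no adjustment — own BMI z for the conventional arm, offspring BMI z
(divided by the unadjusted instrument-exposure slope) for the IV arm —
using logistic regression for dichotomized covariates and OLS for
continuous ones.  Each pair is then rescaled by the absolute magnitude of
its larger member, so components are comparable between the two methods
within a covariate (and only there: never across covariates or strata).
The scaled components are proportional to the confounding bias each method
would incur from omitting that covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .iv import denominator_regression, taylor_se

__all__ = [
    "BiasComponent",
    "DICHOTOMIZERS",
    "bias_component_table",
    "covariate_association",
    "dichotomize",
    "scale_pair",
]

_Z95 = 1.959963984540054

# Cut-points for dichotomizing the categorical covariates:
# low education = below university level; occupation class III or lower
# status; current smoker = daily or occasional; high alcohol = at least 2-3
# times a week; low physical activity = under 3 h light and no hard activity.
DICHOTOMIZERS = {
    "low_education": lambda df: (df["education"].astype(float) <= 4).astype(int),
    "egp_class_ge_III": lambda df: (
        ~df["occupation_egp"].isin(["I", "II"])
    ).astype(int),
    "current_smoker": lambda df: df["smoking"]
    .isin(["daily", "occasional"])
    .astype(int),
    "high_alcohol": lambda df: df["alcohol"]
    .isin(["2_3_per_week", "4plus_per_week"])
    .astype(int),
    "low_physical_activity": lambda df: df["physical_activity"]
    .isin(["inactive", "low"])
    .astype(int),
}

CONTINUOUS_COVARIATES = {"participation_age": "baseline_age"}


def dichotomize(df: pd.DataFrame) -> pd.DataFrame:
    """Binary versions of the categorical covariates at the standard cut-points."""
    return pd.DataFrame({name: fn(df) for name, fn in DICHOTOMIZERS.items()})


def covariate_association(values, z, kind: str):
    """Unadjusted association of a covariate with a BMI z-score.

    ``kind="binary"``: logistic regression, log-odds per SD.
    ``kind="continuous"``: OLS, mean difference per SD.
    Returns ``(est, se)``.
    """
    y = np.asarray(values, float)
    z = np.asarray(z, float)
    X = sm.add_constant(z)
    if kind == "binary":
        uniq = np.unique(y)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("binary covariate must be coded {0, 1}")
        if len(uniq) < 2:
            raise ValueError("binary covariate is constant")
        res = sm.Logit(y, X).fit(disp=0)
        return float(res.params[1]), float(res.bse[1])
    if kind == "continuous":
        res = sm.OLS(y, X).fit()
        return float(res.params[1]), float(res.bse[1])
    raise ValueError(f"unknown kind {kind!r}")


def scale_pair(conv_est: float, iv_est: float):
    """Scale factor for a component pair: the larger absolute magnitude.

    Returns ``(scaled_conv, scaled_iv, factor, degenerate)``; a pair that is
    identically zero is flagged degenerate and left unscaled.
    """
    factor = max(abs(conv_est), abs(iv_est))
    if factor == 0.0:
        return 0.0, 0.0, 0.0, True
    return conv_est / factor, iv_est / factor, factor, False


@dataclass(frozen=True)
class BiasComponent:
    """One covariate's paired conventional and IV association components."""

    covariate: str
    kind: str
    conv_est: float
    conv_se: float
    iv_est: float
    iv_se: float
    scale_factor: float
    degenerate: bool

    @property
    def conv_ci(self):
        return (self.conv_est - _Z95 * self.conv_se, self.conv_est + _Z95 * self.conv_se)

    @property
    def iv_ci(self):
        return (self.iv_est - _Z95 * self.iv_se, self.iv_est + _Z95 * self.iv_se)

    @property
    def scaled_conv(self) -> float:
        return 0.0 if self.degenerate else self.conv_est / self.scale_factor

    @property
    def scaled_iv(self) -> float:
        return 0.0 if self.degenerate else self.iv_est / self.scale_factor

    def to_row(self) -> dict:
        c_lo, c_hi = self.conv_ci
        i_lo, i_hi = self.iv_ci
        s = self.scale_factor if not self.degenerate else 1.0
        return {
            "covariate": self.covariate,
            "kind": self.kind,
            "conv_est": self.conv_est,
            "conv_lo": c_lo,
            "conv_hi": c_hi,
            "iv_est": self.iv_est,
            "iv_lo": i_lo,
            "iv_hi": i_hi,
            "scaled_conv": self.scaled_conv,
            "scaled_conv_lo": c_lo / s,
            "scaled_conv_hi": c_hi / s,
            "scaled_iv": self.scaled_iv,
            "scaled_iv_lo": i_lo / s,
            "scaled_iv_hi": i_hi / s,
            "scale_factor": self.scale_factor,
            "degenerate": self.degenerate,
        }


def bias_component_table(
    df: pd.DataFrame,
    *,
    parent_col: str = "parent_z",
    offspring_col: str = "offspring_z",
    extra_covariates: dict | None = None,
) -> list[BiasComponent]:
    """Bias components for the standard covariate set (plus any extras).

    The IV association for covariate C is the reduced-form association of C
    with offspring z divided by the unadjusted instrument-exposure slope
    (the plot is specified with no adjustment); its SE propagates both parts
    through the delta method.  ``extra_covariates`` maps name ->
    (values, kind) for additional components.
    """
    parent_z = np.asarray(df[parent_col], float)
    offspring_z = np.asarray(df[offspring_col], float)
    md, md_se = denominator_regression(parent_z, offspring_z, adjustment=None)

    items: list[tuple[str, np.ndarray, str]] = []
    for name, col in CONTINUOUS_COVARIATES.items():
        if col in df.columns:
            items.append((name, np.asarray(df[col], float), "continuous"))
    binary = dichotomize(df)
    for name in binary.columns:
        items.append((name, binary[name].to_numpy(float), "binary"))
    for name, (values, kind) in (extra_covariates or {}).items():
        items.append((name, np.asarray(values, float), kind))

    out = []
    for name, values, kind in items:
        conv_est, conv_se = covariate_association(values, parent_z, kind)
        red_est, red_se = covariate_association(values, offspring_z, kind)
        iv_est = red_est / md
        iv_se = taylor_se(red_est, red_se, md, md_se)
        _, _, factor, degenerate = scale_pair(conv_est, iv_est)
        out.append(
            BiasComponent(
                covariate=name,
                kind=kind,
                conv_est=conv_est,
                conv_se=conv_se,
                iv_est=iv_est,
                iv_se=iv_se,
                scale_factor=factor,
                degenerate=degenerate,
            )
        )
    return out


def components_to_frame(components: list[BiasComponent]) -> pd.DataFrame:
    """Tabular export, one row per covariate (grouped by covariate, never
    totalled across covariates — components are only comparable within a
    pair)."""
    return pd.DataFrame([c.to_row() for c in components])
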