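"""Optional figure helpers (presentation only; the tables are canonical)."""

from __future__ import annotations

import numpy as np

from .standardize import BMI_CATEGORIES, BMI_REFERENCE_CATEGORY


def bias_component_plot(components, ax=None):
    """Dot-and-whisker plot of scaled conventional vs IV bias components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.6 * len(components) + 1))
    ypos = np.arange(len(components))[::-1]
    for y, comp in zip(ypos, components):
        row = comp.to_row()
        ax.errorbar(
            row["scaled_conv"], y + 0.12,
            xerr=[[row["scaled_conv"] - row["scaled_conv_lo"]],
                  [row["scaled_conv_hi"] - row["scaled_conv"]]],
            fmt="o", color="tab:blue",
            label="conventional" if y == ypos[0] else None,
        )
        ax.errorbar(
            row["scaled_iv"], y - 0.12,
            xerr=[[row["scaled_iv"] - row["scaled_iv_lo"]],
                  [row["scaled_iv_hi"] - row["scaled_iv"]]],
            fmt="s", color="tab:orange",
            label="instrumental variable" if y == ypos[0] else None,
        )
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels([c.covariate for c in components])
    ax.set_xlabel("scaled bias component (comparable within covariate only)")
    ax.legend(loc="best", fontsize="small")
    return ax


def categorical_hr_plot(curves: dict, ax=None, category_means: dict | None = None):
    """HR-by-BMI-category curves (e.g. conventional vs reduced form).

    ``curves`` maps a label to a {category: HazardRatioEstimate} dict; the
    reference band is drawn at HR = 1.  ``category_means`` optionally maps
    category label to the mean BMI to plot on the x axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    default_x = {c: i for i, c in enumerate(BMI_CATEGORIES)}
    for label, curve in curves.items():
        xs, ys, lo, hi = [], [], [], []
        for cat in BMI_CATEGORIES:
            x = (category_means or default_x).get(cat)
            if x is None:
                continue
            if cat == BMI_REFERENCE_CATEGORY:
                xs.append(x), ys.append(1.0), lo.append(1.0), hi.append(1.0)
            elif cat in curve:
                est = curve[cat]
                xs.append(x), ys.append(est.hr)
                lo.append(est.ci95[0]), hi.append(est.ci95[1])
        order = np.argsort(xs)
        xs, ys = np.asarray(xs)[order], np.asarray(ys)[order]
        lo, hi = np.asarray(lo)[order], np.asarray(hi)[order]
        ax.errorbar(xs, ys, yerr=[ys - lo, hi - ys], fmt="o-", capsize=3, label=label)
    ax.axhline(1.0, color="0.6", lw=0.8)
    ax.set_yscale("log")
    if category_means is None:
        ax.set_xticks(list(default_x.values()))
        ax.set_xticklabels(list(default_x.keys()), rotation=30)
        ax.set_xlabel("BMI category (kg/m$^2$)")
    else:
        ax.set_xlabel("BMI (kg/m$^2$)")
    ax.set_ylabel(f"hazard ratio vs {BMI_REFERENCE_CATEGORY}")
    ax.legend()
    return ax
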