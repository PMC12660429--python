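"""End-to-end analysis pipeline: selection, exclusions, all estimates.

Mirrors the cohort workflow: pick one offspring per parent (earliest
participation wave, then oldest), apply the eligibility exclusions with a
per-reason tally, standardize BMI to z-scores, then for each sex and
outcome fit the conventional, reduced-form and IV models together with the
instrument-strength table, bias components, categorical HR curves,
incidence rates and the proportional-hazards split test.  Reports are
plain dicts (JSON-serializable) so runs with identical inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import bias_component_table, components_to_frame
from .iv import OffspringIvEstimator
from .standardize import LmsReference, StratumZScorer, bmi_category
from .survival import (
    SplineWaveBasis,
    build_adjustment,
    categorical_hr,
    incidence_rate,
    ph_split_test,
)

__all__ = [
    "AnalysisConfig",
    "apply_exclusions",
    "prepare_analysis_frame",
    "run_all",
    "select_offspring",
    "write_report",
]

OUTCOMES = ("all", "musculoskeletal", "mental")
SENSITIVITIES = ("none", "offspring_ge20", "z_within_2")
_COMPLETE_CASE_COLS = ("education", "smoking", "alcohol", "physical_activity")


@dataclass
class AnalysisConfig:
    """What to run: adjustment set, outcomes, sensitivity filter."""

    input_path: str | None = None
    output_dir: str | None = None
    adjustment: str = "minimal"
    outcomes: tuple = OUTCOMES
    sensitivity: str = "none"
    seed: int = 0
    lms_reference: str | None = None

    def __post_init__(self):
        if self.adjustment not in ("none", "minimal", "full"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if not self.outcomes:
            raise ValueError("outcomes must be non-empty")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcome(s): {sorted(unknown)}")
        if self.sensitivity not in SENSITIVITIES:
            raise ValueError(f"unknown sensitivity {self.sensitivity!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "outcomes" in d:
            d["outcomes"] = tuple(d["outcomes"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcomes"] = list(self.outcomes)
        return d


def select_offspring(df: pd.DataFrame) -> pd.DataFrame:
    """One offspring per parent: earliest participation wave, then oldest.

    Deterministic: rows are ordered by (offspring wave ascending, offspring
    age descending) within parent and the first is kept.  Parents without
    any offspring record are dropped (they are counted by
    :func:`apply_exclusions`).
    """
    ordered = df.sort_values(
        ["parent_id", "offspring_wave", "offspring_age"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    return ordered.drop_duplicates("parent_id", keep="first").reset_index(drop=True)


def apply_exclusions(df: pd.DataFrame, max_baseline_age: float = 60.0):
    """Eligibility filters, applied in order, with a per-reason tally.

    Order: baseline age above the inclusion bound; missing offspring BMI;
    missing own covariates (complete-case: education, smoking, alcohol,
    physical activity); disability benefit or ongoing long-term sick leave
    at participation (columns ``disability_at_baseline`` /
    ``sick_listed_at_baseline``, if present).  The tally plus the retained
    count always equals the input count.
    """
    tally: dict[str, int] = {}
    kept = df

    def drop(mask, reason):
        nonlocal kept
        mask = np.asarray(mask).astype(bool)
        tally[reason] = int(mask.sum())
        kept = kept.loc[~mask]

    drop(kept["baseline_age"] > max_baseline_age, "age_over_60")
    drop(kept["offspring_bmi"].isna(), "no_offspring_bmi")
    present = [c for c in _COMPLETE_CASE_COLS if c in kept.columns]
    drop(kept[present].isna().any(axis=1), "missing_covariates")
    for col, reason in (
        ("disability_at_baseline", "disability_at_baseline"),
        ("sick_listed_at_baseline", "sick_listed_at_baseline"),
    ):
        if col in kept.columns:
            drop(kept[col].fillna(0).astype(int) == 1, reason)
    tally["retained"] = int(len(kept))
    return kept.reset_index(drop=True), tally


def prepare_analysis_frame(
    df: pd.DataFrame, lms_reference: LmsReference | None = None
) -> pd.DataFrame:
    """Add z-scores and BMI categories to an eligible trio table.

    Parents are z-scored within (age category, sex, wave) strata fitted on
    the parents; offspring aged 18+ within offspring strata; offspring
    under 18 against the LMS reference when one is supplied (otherwise the
    adult strata cover them, with a warning).
    """
    out = df.copy()
    parent_scorer = StratumZScorer(
        bmi_col="parent_bmi", age_col="baseline_age",
        sex_col="parent_sex", wave_col="survey_wave",
    )
    out["parent_z"] = parent_scorer.fit_transform(out)

    off = out.rename(
        columns={
            "offspring_bmi": "bmi",
            "offspring_age": "age",
            "offspring_sex": "sex",
            "offspring_wave": "wave",
        }
    )[["bmi", "age", "sex", "wave"]]
    minor = off["age"] < 18.0
    z = np.full(len(off), np.nan)
    if minor.any() and lms_reference is None:
        warnings.warn(
            "offspring under 18 scored against adult strata; supply an LMS "
            "reference for growth-chart z-scores"
        )
        minor = np.zeros(len(off), bool)
    if (~minor).any():
        adult_scorer = StratumZScorer(
            bmi_col="bmi", age_col="age", sex_col="sex", wave_col="wave"
        )
        z[~minor] = adult_scorer.fit_transform(off.loc[~minor])
    if minor.any():
        sub = off.loc[minor]
        z[minor] = lms_reference.zscore(
            sub["bmi"].to_numpy(), sub["sex"].to_numpy(), sub["age"].to_numpy()
        )
    out["offspring_z"] = z
    out["parent_bmi_cat"] = bmi_category(out["parent_bmi"])
    out["offspring_bmi_cat"] = bmi_category(out["offspring_bmi"])
    return out


def _apply_sensitivity(df: pd.DataFrame, sensitivity: str) -> pd.DataFrame:
    if sensitivity == "none":
        return df
    if sensitivity == "offspring_ge20":
        return df.loc[df["offspring_age"] >= 20.0].reset_index(drop=True)
    if sensitivity == "z_within_2":
        return df.loc[df["offspring_z"].abs() < 2.0].reset_index(drop=True)
    raise ValueError(f"unknown sensitivity {sensitivity!r}")


def run_all(
    trios: pd.DataFrame,
    config: AnalysisConfig | None = None,
    *,
    lms_reference: LmsReference | None = None,
) -> dict:
    """Run the full analysis bundle on a raw trio table.

    Returns a nested dict: exclusion tally, then per sex the instrument
    strength, per-outcome conventional / reduced-form / IV estimates with
    incidence rates, the all-cause categorical HR curves (own and offspring
    BMI), bias components, and the PH split test.
    """
    config = config or AnalysisConfig()
    if lms_reference is None and config.lms_reference:
        lms_reference = LmsReference.from_csv(config.lms_reference)

    n_input = int(len(trios))
    selected = select_offspring(trios)
    n_parents = int(len(selected))
    eligible, tally = apply_exclusions(selected)
    prepared = prepare_analysis_frame(eligible, lms_reference=lms_reference)
    analysed = _apply_sensitivity(prepared, config.sensitivity)

    report: dict = {
        "metadata": {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest()[:16],
            "seed": config.seed,
            "n_input_rows": n_input,
            "n_parents": n_parents,
            "exclusions": tally,
            "n_analysed": int(len(analysed)),
            "note": "both-parent families contribute to both sex strata; "
            "sex-specific results are not independent",
        },
        "by_sex": {},
    }

    for sex in ("F", "M"):
        sub = analysed.loc[analysed["parent_sex"] == sex].reset_index(drop=True)
        if len(sub) == 0:
            continue
        sex_report: dict = {"n": int(len(sub))}

        outcomes = {}
        for outcome in config.outcomes:
            est = OffspringIvEstimator(
                adjustment=config.adjustment, outcome=outcome
            ).fit(sub)
            res = est.results_()
            ev = sub["event"].astype(bool)
            if outcome != "all":
                ev = ev & (sub["cause"] == outcome)
            inc = incidence_rate(sub.assign(event=ev.astype(int)))
            res["incidence"] = inc.to_dict()
            outcomes[outcome] = res
        sex_report["outcomes"] = outcomes

        if config.adjustment == "none":
            adj = None
            basis = None
        else:
            basis = SplineWaveBasis.from_ages(sub["baseline_age"])
            adj = build_adjustment(sub, basis, full=config.adjustment == "full")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            conv_curve = categorical_hr(sub, "parent_bmi_cat", adjustment=adj)
            reduced_curve = categorical_hr(sub, "offspring_bmi_cat", adjustment=adj)
        sex_report["categorical_all_cause"] = {
            "conventional_own_bmi": {k: v.to_dict() for k, v in conv_curve.items()},
            "reduced_form_offspring_bmi": {
                k: v.to_dict() for k, v in reduced_curve.items()
            },
        }

        sex_report["bias_components"] = [
            c.to_row() for c in bias_component_table(sub)
        ]
        ph_adj = None if basis is None else (basis, config.adjustment == "full")
        sex_report["ph_split_all_cause"] = ph_split_test(
            sub, "parent_z", adjustment=ph_adj
        ).to_dict()

        report["by_sex"][sex] = sex_report
    return report


def _round_floats(obj, ndigits):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(report: dict, output_dir) -> None:
    """Write the report bundle: full-precision JSON plus display CSVs.

    CSV numbers are rounded to two decimals for display; the JSON keeps
    full precision.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    rows = []
    for sex, sex_rep in report.get("by_sex", {}).items():
        for outcome, res in sex_rep.get("outcomes", {}).items():
            conv, red, iv = res["conventional"], res["reduced_form"], res["iv"]
            rows.append(
                {
                    "sex": sex,
                    "outcome": outcome,
                    "n": res["n"],
                    "n_events": res["n_events"],
                    "incidence_per_1000py": res["incidence"]["rate_per_1000py"],
                    "hr_conventional": conv["hr"],
                    "hr_conventional_lo": conv["ci95"][0],
                    "hr_conventional_hi": conv["ci95"][1],
                    "hr_reduced_form": red["hr"],
                    "hr_reduced_form_lo": red["ci95"][0],
                    "hr_reduced_form_hi": red["ci95"][1],
                    "hr_iv": iv["hr_iv"],
                    "hr_iv_lo": iv["ci95"][0],
                    "hr_iv_hi": iv["ci95"][1],
                    "denominator_md": iv["denominator_md"],
                    "partial_r2": res["instrument_strength"]["partial_r2"],
                    "partial_f": res["instrument_strength"]["partial_f"],
                }
            )
    if rows:
        pd.DataFrame(_round_floats(rows, 2)).to_csv(
            outdir / "estimates.csv", index=False
        )

    bias_rows = []
    for sex, sex_rep in report.get("by_sex", {}).items():
        for row in sex_rep.get("bias_components", []):
            bias_rows.append({"sex": sex, **row})
    if bias_rows:
        pd.DataFrame(_round_floats(bias_rows, 4)).to_csv(
            outdir / "bias_components.csv", index=False
        )
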