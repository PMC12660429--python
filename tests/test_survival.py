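"""Spline adjustment, left-truncated Cox fits, incidence, PH diagnostic."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from offspring_iv import (
    SimulationConfig,
    SplineWaveBasis,
    build_adjustment,
    categorical_hr,
    default_knots,
    fit_cox,
    incidence_rate,
    natural_spline_basis,
    ph_split_test,
    simulate_trios,
)
from offspring_iv._cox import ConvergenceError, cox_fit
from offspring_iv.survival import episode_split

KNOTS = np.array([30.0, 38.0, 45.0, 52.0, 60.0])


class TestNaturalSplineBasis:
    def test_dimension_and_identity_column(self):
        x = np.linspace(25, 65, 7)
        B = natural_spline_basis(x, KNOTS)
        assert B.shape == (7, 4)  # K-1 columns for K=5 knots
        assert np.allclose(B[:, 0], x)

    def test_linear_below_first_knot(self):
        x = np.array([20.0, 24.0, 28.0])  # all below the first knot
        B = natural_spline_basis(x, KNOTS)
        second_diff = B[2] - 2 * B[1] + B[0]  # equally spaced
        assert np.allclose(second_diff, 0.0, atol=1e-12)

    def test_linear_above_last_knot(self):
        x = np.array([61.0, 63.0, 65.0])
        B = natural_spline_basis(x, KNOTS)
        assert np.allclose(B[2] - 2 * B[1] + B[0], 0.0, atol=1e-10)

    def test_zero_second_derivative_at_boundary_knots(self):
        h = 1e-4
        for t in (KNOTS[0], KNOTS[-1]):
            pts = natural_spline_basis(np.array([t - h, t, t + h]), KNOTS)
            f2 = (pts[2] - 2 * pts[1] + pts[0]) / h**2
            assert np.max(np.abs(f2)) < 1e-6

    def test_spans_natural_cubic_interpolants(self, rng):
        """Independent oracle: scipy natural cubic splines through the knots
        lie exactly in the span of [1, basis]."""
        from scipy.interpolate import CubicSpline

        values = rng.normal(size=len(KNOTS))
        f = CubicSpline(KNOTS, values, bc_type="natural")
        grid = np.linspace(KNOTS[0], KNOTS[-1], 200)
        design = np.column_stack([np.ones_like(grid), natural_spline_basis(grid, KNOTS)])
        coef, *_ = np.linalg.lstsq(design, f(grid), rcond=None)
        assert np.max(np.abs(design @ coef - f(grid))) < 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.array([np.nan]), KNOTS)
        with pytest.raises(ValueError):
            natural_spline_basis(np.array([40.0]), [30.0, 30.0, 50.0, 55.0, 60.0])

    def test_default_knot_percentiles(self, rng):
        ages = rng.uniform(25, 60, 10_000)
        knots = default_knots(ages)
        expected = np.percentile(ages, [5, 27.5, 50, 72.5, 95])
        assert np.allclose(knots, expected)


def _adjustment_frame():
    return pd.DataFrame(
        {
            "baseline_age": [40.0, 40.0, 52.0],
            "survey_wave": [3, 4, 3],
            "education": [1, 1, 3],
            "occupation_egp": ["I", "I", "IV"],
            "smoking": ["never", "never", "daily"],
            "alcohol": ["never_drunk", "never_drunk", "2_4_per_month"],
            "physical_activity": ["inactive", "inactive", "high"],
        }
    )


class TestBuildAdjustment:
    def test_minimal_dimension_and_wave_block(self):
        basis = SplineWaveBasis(knots=tuple(KNOTS))
        mat, names = build_adjustment(_adjustment_frame(), basis, full=False)
        assert mat.shape[1] == 9  # wave main effect + 4 spline cols per wave
        # rows 0 and 1 are identical except for the wave: every differing
        # column belongs to the wave-interaction block
        differ = np.where(mat[0] != mat[1])[0]
        assert len(differ) > 0
        assert all("wave" in names[i] for i in differ)

    def test_full_appends_23_covariate_dummies(self):
        basis = SplineWaveBasis(knots=tuple(KNOTS))
        minimal, _ = build_adjustment(_adjustment_frame(), basis, full=False)
        full, names = build_adjustment(_adjustment_frame(), basis, full=True)
        # (6-1)+(8-1)+(4-1)+(6-1)+(4-1) = 23 dummies
        assert full.shape[1] - minimal.shape[1] == 23

    def test_reference_level_record_has_zero_dummies(self):
        basis = SplineWaveBasis(knots=tuple(KNOTS))
        full, names = build_adjustment(_adjustment_frame(), basis, full=True)
        dummy_cols = [i for i, nm in enumerate(names) if "[" in nm]
        assert np.allclose(full[0, dummy_cols], 0.0)  # all-reference record
        assert full[2, dummy_cols].sum() > 0

    def test_unseen_level_is_reported(self):
        basis = SplineWaveBasis(knots=tuple(KNOTS))
        df = _adjustment_frame()
        df.loc[0, "smoking"] = "pipe"
        with pytest.raises(ValueError, match="pipe"):
            build_adjustment(df, basis, full=True)


def _brute_force_partial_likelihood(entry, exit_, event, x):
    """Independent oracle: loop over event times and risk-set members."""

    def neg_log_pl(beta):
        ll = 0.0
        for i in np.where(event)[0]:
            t = exit_[i]
            at_risk = (entry < t) & (exit_ >= t)
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
        return -ll

    return neg_log_pl


class TestCoxEngine:
    def test_toy_risk_set_matches_grid_oracle(self):
        """Closed/brute-force partial-likelihood maximum on a toy risk set,
        including a delayed-entry subject."""
        entry = np.array([0.0, 0.0, 0.0, 0.0, 1.5])
        exit_ = np.array([1.0, 2.0, 2.5, 3.0, 2.2])
        event = np.array([1, 1, 0, 0, 0])
        x = np.array([1.0, 0.0, 1.0, -1.0, 0.5])
        oracle = minimize_scalar(
            _brute_force_partial_likelihood(entry, exit_, event, x),
            bounds=(-4, 4), method="bounded",
            options={"xatol": 1e-10},
        )
        fit = cox_fit(entry, exit_, event, x)
        assert fit.params[0] == pytest.approx(oracle.x, abs=1e-6)

    def test_matches_lifelines_with_ties_and_truncation(self):
        """Independent implementation check: Efron ties, delayed entry."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 800
        X = rng.normal(size=(n, 2))
        entry = rng.uniform(30, 55, n)
        h = 0.15 * np.exp(0.4 * X[:, 0] - 0.25 * X[:, 1])
        T = entry + rng.exponential(1.0, n) / h
        C = entry + rng.uniform(2, 10, n)
        event = (T <= C).astype(int)
        exit_ = np.ceil(np.minimum(T, C))  # whole-year exits -> heavy ties
        fit = cox_fit(entry, exit_, event, X)
        df = pd.DataFrame(
            dict(en=entry, ex=exit_, ev=event, x0=X[:, 0], x1=X[:, 1])
        )
        cph = lifelines.CoxPHFitter().fit(
            df, duration_col="ex", event_col="ev", entry_col="en"
        )
        assert np.allclose(fit.params, cph.params_.values, atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-7)

    def test_efron_equals_breslow_without_ties(self, rng):
        n = 400
        x = rng.normal(size=n)
        entry = rng.uniform(30, 50, n)
        exit_ = entry + rng.exponential(8.0, n)
        event = rng.uniform(size=n) < 0.6
        fe = cox_fit(entry, exit_, event, x, ties="efron")
        fb = cox_fit(entry, exit_, event, x, ties="breslow")
        assert np.allclose(fe.params, fb.params, atol=1e-8)

    def test_no_events_is_error(self, rng):
        n = 20
        with pytest.raises(ValueError, match="no events"):
            cox_fit(
                np.zeros(n), np.ones(n), np.zeros(n), rng.normal(size=n)
            )

    def test_exposure_rescaling_is_exact(self, small_trios):
        base = fit_cox(small_trios, "parent_z_true")
        scaled = fit_cox(
            small_trios, 2.5 * small_trios["parent_z_true"].to_numpy()
        )
        assert scaled.log_hr == pytest.approx(base.log_hr / 2.5, abs=1e-8)
        assert scaled.se == pytest.approx(base.se / 2.5, abs=1e-8)

    def test_late_entrant_leaves_estimate_unchanged(self, small_trios):
        """A subject entering after the last event joins no risk set."""
        base = fit_cox(small_trios, "parent_z_true")
        max_event_age = small_trios.loc[
            small_trios["event"] == 1, "exit_age"
        ].max()
        extra = small_trios.iloc[[0]].copy()
        extra["entry_age"] = max_event_age + 0.5
        extra["exit_age"] = max_event_age + 1.0
        extra["event"] = 0
        aug = pd.concat([small_trios, extra], ignore_index=True)
        fit = fit_cox(aug, "parent_z_true")
        assert fit.log_hr == pytest.approx(base.log_hr, abs=1e-8)

    def test_permuted_exposure_is_null(self, small_trios, rng):
        perm = rng.permutation(small_trios["parent_z_true"].to_numpy())
        fit = fit_cox(small_trios, perm)
        assert abs(fit.log_hr) < 2 * fit.se

    def test_parameter_recovery_without_confounding(self):
        """Mean conditional-model estimate over replicates hits beta_true."""
        beta_true = 0.15
        cfg = SimulationConfig(
            n_families=20_000, beta_true=beta_true,
            gamma_confounder=0.0, p_illness=0.0,
        )
        estimates = []
        for rep in range(100):
            df = simulate_trios(cfg.replace(seed=5000 + rep))
            estimates.append(fit_cox(df, "parent_z_true").log_hr)
        estimates = np.array(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert estimates.mean() == pytest.approx(beta_true, abs=2 * mc_se)


class TestCategoricalHr:
    def test_all_reference_warns_and_returns_empty(self, small_trios):
        df = small_trios.copy()
        df["cat"] = "20.0-24.9"
        with pytest.warns(UserWarning, match="reference"):
            assert categorical_hr(df, "cat") == {}

    def test_empty_category_omitted_with_warning(self, prepared_small):
        df = prepared_small.copy()
        df.loc[df["parent_bmi_cat"] == "<18.5", "parent_bmi_cat"] = "18.5-19.9"
        with pytest.warns(UserWarning, match="<18.5"):
            out = categorical_hr(df, "parent_bmi_cat")
        assert "<18.5" not in out
        assert "25.0-29.9" in out

    def test_null_config_categories_near_one(self):
        cfg = SimulationConfig(
            n_families=12_000, seed=31, beta_true=0.0,
            gamma_confounder=0.0, p_illness=0.0,
        )
        df = simulate_trios(cfg)
        from offspring_iv.standardize import bmi_category

        df["cat"] = bmi_category(df["parent_bmi"])
        out = categorical_hr(df, "cat")
        for est in out.values():
            assert abs(est.log_hr) < 2.8 * est.se, est.label


class TestIncidenceRate:
    def test_hand_arithmetic(self):
        df = pd.DataFrame(
            {"entry_age": [40.0, 50.0], "exit_age": [52.0, 58.0], "event": [1, 1]}
        )
        inc = incidence_rate(df)
        assert inc.rate_per_1000py == pytest.approx(100.0)
        assert inc.person_years == pytest.approx(20.0)

    def test_no_events_gives_zero(self):
        df = pd.DataFrame(
            {"entry_age": [40.0], "exit_age": [45.0], "event": [0]}
        )
        assert incidence_rate(df).rate_per_1000py == 0.0

    def test_zero_person_time_is_error(self):
        df = pd.DataFrame({"entry_age": [], "exit_age": [], "event": []})
        with pytest.raises(ValueError, match="person-time"):
            incidence_rate(df)

    def test_tuned_rate_reproduced(self):
        """Constant-hazard cohorts at 115/1000 PY: the empirical rate is an
        unbiased ratio estimate of the hazard (replicate-averaged)."""
        cfg = SimulationConfig(
            beta_true=0.0, gamma_confounder=0.0, p_illness=0.0,
            baseline_rate=0.115, n_families=5_000,
        )
        rates = np.array(
            [
                incidence_rate(simulate_trios(cfg.replace(seed=40 + rep))).rate_per_1000py
                for rep in range(30)
            ]
        )
        mc_se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert rates.mean() == pytest.approx(115.0, abs=3 * mc_se)


class TestEpisodeSplit:
    def test_short_follow_up_contributes_only_early(self):
        df = pd.DataFrame(
            {
                "entry_age": [40.0, 45.0],
                "exit_age": [42.0, 53.0],
                "event": [1, 1],
                "x": [0.3, -0.2],
            }
        )
        episodes = episode_split(df, 5.0)
        early = episodes[episodes["late"] == 0]
        late = episodes[episodes["late"] == 1]
        assert len(early) == 2 and len(late) == 1
        # the short record keeps its event in the early period
        assert early.loc[early["entry_age"] == 40.0, "event"].item() == 1
        # the long record's event moves to the late episode
        assert early.loc[early["entry_age"] == 45.0, "event"].item() == 0
        assert late["event"].item() == 1
        assert late["entry_age"].item() == pytest.approx(50.0)

    def test_event_at_split_counts_as_early(self):
        df = pd.DataFrame(
            {"entry_age": [40.0], "exit_age": [45.0], "event": [1]}
        )
        episodes = episode_split(df, 5.0)
        assert len(episodes) == 1
        assert episodes["event"].item() == 1 and episodes["late"].item() == 0


class TestPhSplitTest:
    def test_size_under_proportional_hazards(self):
        """Under exact PH the Wald z should rarely exceed 1.96."""
        cfg = SimulationConfig(n_families=1500, gamma_confounder=0.0, p_illness=0.0)
        rejections = 0
        for rep in range(100):
            df = simulate_trios(cfg.replace(seed=7000 + rep))
            res = ph_split_test(df, "parent_z_true")
            rejections += abs(res.z) >= 1.96
        assert rejections <= 10

    def test_detects_reversing_effect(self, rng):
        """Exposure effect flips sign midway: the split test must flag it."""
        n = 4000
        x = rng.normal(size=n)
        entry = rng.uniform(30, 50, n)
        flip = 4.0
        h1 = 0.10 * np.exp(0.6 * x)
        h2 = 0.10 * np.exp(-0.6 * x)
        t1 = rng.exponential(1.0, n) / h1
        t2 = flip + rng.exponential(1.0, n) / h2
        time_to_event = np.where(t1 <= flip, t1, t2)
        censor = 10.0
        event = time_to_event <= censor
        df = pd.DataFrame(
            {
                "entry_age": entry,
                "exit_age": entry + np.minimum(time_to_event, censor),
                "event": event.astype(int),
                "x": x,
            }
        )
        res = ph_split_test(df, "x")
        assert abs(res.z) > 3.0
        assert res.hr_early > 1.0 > res.hr_late

    def test_no_events_is_error(self):
        df = pd.DataFrame(
            {"entry_age": [40.0], "exit_age": [45.0], "event": [0], "x": [0.1]}
        )
        with pytest.raises(ValueError, match="no events"):
            ph_split_test(df, "x")
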