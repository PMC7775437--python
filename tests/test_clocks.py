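"""Trajectories, CpG selection, clock training, evaluation, acceleration."""

import numpy as np
import pandas as pd
import pytest

import readclock as rc
from readclock.clocks import (
    MethylationMatrix,
    cpg_age_correlation_profile,
    evaluate,
    fit_acceleration_curve,
    fit_cpg_trajectory,
    glmnet_lambda_grid,
    lasso_objective,
    predict_age,
    select_top_cpgs,
    train_lasso,
    train_multivariable,
)

from _oracles import ista_lasso
from _oracles import lasso_objective as oracle_objective


def _matrix(betas: dict, ages: dict) -> MethylationMatrix:
    return MethylationMatrix(pd.DataFrame(betas), pd.Series(ages))


class TestTrajectory:
    def test_exact_line(self):
        t = fit_cpg_trajectory([0.10, 0.20, 0.30], [0, 100, 200])
        assert t.slope == pytest.approx(0.001)
        assert t.intercept == pytest.approx(0.10)
        assert t.pearson_r == pytest.approx(1.0)

    def test_normal_equations_on_noisy_points(self):
        # Sxy = 15.8 fraction*weeks, Sxx = 8000 weeks^2
        t = fit_cpg_trajectory([0.12, 0.25, 0.20, 0.40], [10, 50, 90, 130])
        assert t.slope == pytest.approx(0.001975, rel=1e-9)
        assert t.intercept == pytest.approx(0.10425, rel=1e-9)
        assert t.pearson_r == pytest.approx(0.8653, abs=5e-5)
        assert t.r_squared == pytest.approx(t.pearson_r**2)

    def test_constant_betas_flagged_undefined(self):
        t = fit_cpg_trajectory([0.3, 0.3, 0.3], [0, 50, 100])
        assert t.slope == 0.0
        assert not t.defined

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            fit_cpg_trajectory([0.1, np.nan, 0.2], [0, 50, 100])

    def test_predicted_beta_clipped_to_unit_interval(self):
        t = fit_cpg_trajectory([0.5, 0.7, 0.9], [0, 100, 200])
        assert t.predict_beta(1000.0) == 1.0


class TestSelectTopCpgs:
    def test_one_per_amplicon_gives_three_cpgs(self, train_matrix):
        cpgs = select_top_cpgs(train_matrix, per_amplicon=1)
        assert len(cpgs) == 3
        assert {c.rsplit(":", 1)[0] for c in cpgs} == {"Prima1", "Hsf4", "Kcns1"}

    def test_strongest_cpg_wins(self):
        ages = {"a": 0.0, "b": 50.0, "c": 100.0, "d": 150.0}
        m = _matrix(
            {
                "amp:0": {"a": 0.5, "b": 0.3, "c": 0.6, "d": 0.4},  # noise
                "amp:1": {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4},  # clean signal
            },
            ages,
        )
        assert select_top_cpgs(m) == ["amp:1"]

    def test_tied_correlations_break_to_lower_index(self):
        ages = {"a": 0.0, "b": 50.0, "c": 100.0}
        col = {"a": 0.1, "b": 0.2, "c": 0.3}
        m = _matrix({"amp:0": col, "amp:1": col}, ages)
        assert select_top_cpgs(m) == ["amp:0"]

    def test_degenerate_amplicon_excluded_with_warning(self):
        ages = {"a": 0.0, "b": 50.0, "c": 100.0}
        m = _matrix(
            {"flat:0": {"a": 0.2, "b": 0.2, "c": 0.2}, "ok:0": {"a": 0.1, "b": 0.2, "c": 0.3}},
            ages,
        )
        with pytest.warns(UserWarning, match="flat"):
            assert select_top_cpgs(m) == ["ok:0"]


class TestMultivariable:
    def test_single_cpg_inverts_the_trajectory(self):
        ages = {"a": 0.0, "b": 100.0, "c": 200.0}
        m = _matrix({"x:0": {"a": 0.1, "b": 0.2, "c": 0.3}}, ages)
        model = train_multivariable(m, ["x:0"])
        assert model.terms[0][1] == pytest.approx(1000.0)  # 1 / 0.001
        assert model.intercept == pytest.approx(-100.0)

    def test_noise_free_cohort_recovered_exactly(self):
        # age defined by a known linear combination of independent betas:
        # OLS must recover that inverse model and interpolate exactly
        rng = np.random.default_rng(0)
        X = rng.uniform(0.05, 0.95, size=(12, 3))
        coefs, inter = np.array([150.0, -80.0, 60.0]), 12.0
        ages = inter + X @ coefs
        m = MethylationMatrix(
            pd.DataFrame(X, index=[f"s{i}" for i in range(12)], columns=["a:0", "b:0", "c:0"]),
            pd.Series(ages, index=[f"s{i}" for i in range(12)]),
        )
        model = train_multivariable(m, ["a:0", "b:0", "c:0"])
        np.testing.assert_allclose([c for _, c in model.terms], coefs, atol=1e-9)
        preds = [predict_age(model, m.betas.loc[s]) for s in m.sample_ids]
        np.testing.assert_allclose(preds, ages, atol=1e-9)

    def test_duplicate_column_raises_collinearity_error(self):
        ages = {"a": 0.0, "b": 100.0, "c": 200.0, "d": 50.0}
        col = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.15}
        m = _matrix({"x:0": col, "x:1": col}, ages)
        with pytest.raises(ValueError, match="collinear"):
            train_multivariable(m, ["x:0", "x:1"])

    def test_more_cpgs_than_samples_rejected(self):
        ages = {"a": 0.0, "b": 100.0, "c": 200.0}
        m = _matrix(
            {f"x:{i}": {"a": 0.1 * i, "b": 0.15 * i, "c": 0.2 * i} for i in range(4)}, ages
        )
        with pytest.raises(ValueError, match="more samples"):
            train_multivariable(m, [f"x:{i}" for i in range(4)])


class TestLasso:
    def _cohort(self, n=20, p=8, seed=0, noise=0.02):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(5, 120, size=n)
        slopes = rng.uniform(-0.003, 0.004, size=p)
        inter = rng.uniform(0.1, 0.6, size=p)
        X = np.clip(inter + np.outer(ages, slopes) + rng.normal(0, noise, (n, p)), 0, 1)
        idx = [f"s{i}" for i in range(n)]
        cols = [f"a:{i}" for i in range(p)]
        return MethylationMatrix(pd.DataFrame(X, index=idx, columns=cols), pd.Series(ages, index=idx))

    def test_huge_penalty_shrinks_to_mean_age(self):
        m = self._cohort()
        model = train_lasso(m, lambda_grid=[1e6], n_folds=5, seed=1)
        assert model.terms == []
        assert model.intercept == pytest.approx(m.ages.mean())

    def test_zero_penalty_matches_ols(self):
        m = self._cohort(n=30, p=4)
        model = train_lasso(m, lambda_grid=[0.0], n_folds=5, seed=1)
        ols = train_multivariable(m, m.cpg_ids)
        got = dict(model.terms)
        for cpg, coef in ols.terms:
            assert got[cpg] == pytest.approx(coef, abs=1e-6)
        assert model.intercept == pytest.approx(ols.intercept, abs=1e-6)

    def test_objective_never_worse_than_proximal_gradient_oracle(self):
        """The returned coefficients minimise the lasso objective at the
        chosen penalty at least as well as an independent ISTA solver."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            n, p = int(rng.integers(8, 21)), int(rng.integers(2, 16))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Xs = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
            yc = y - y.mean()
            lam = float(rng.uniform(0.01, 0.5))
            from readclock.clocks import _lasso_fit_std

            b_impl = _lasso_fit_std(Xs, yc, lam)
            b_orc = ista_lasso(Xs, yc, lam)
            assert oracle_objective(Xs, yc, b_impl, lam) <= oracle_objective(Xs, yc, b_orc, lam) + 1e-6

    def test_fold_assignment_deterministic_under_seed(self):
        m = self._cohort()
        a = train_lasso(m, n_folds=5, seed=7)
        b = train_lasso(m, n_folds=5, seed=7)
        assert a.terms == b.terms and a.meta["lambda"] == b.meta["lambda"]

    def test_too_few_samples_for_folds_rejected(self):
        m = self._cohort(n=6)
        with pytest.raises(ValueError, match="folds"):
            train_lasso(m, n_folds=10)

    def test_wide_panel_lasso_beats_three_cpg_clock(self):
        """On a 15-CpG five-amplicon cohort (pyrosequencing-panel layout),
        the cross-validated lasso attains lower validation median error
        than the 3-CpG model built from the first three amplicons."""
        from readclock.simulate import make_panel, simulate_cohort

        cfg = {
            "amplicons": [
                {"name": n, "n_cpgs": 3, "peak_slope": s, "profile_width": 2.0}
                for n, s in [
                    ("Prima1", 0.004), ("Hsf4", 0.004), ("Kcns1", 0.004),
                    ("Gm9312", 0.003), ("Gm7325", 0.003),
                ]
            ]
        }
        panel = make_panel(cfg)
        train = simulate_cohort(panel, 24, seed=21, id_prefix="T").beta_matrix()
        val = simulate_cohort(panel, 21, seed=22, id_prefix="V").beta_matrix()
        sub = MethylationMatrix(
            train.betas[[c for c in train.cpg_ids if c.split(":")[0] in ("Prima1", "Hsf4", "Kcns1")]],
            train.ages,
        )
        three = train_multivariable(sub, select_top_cpgs(sub))
        lasso = train_lasso(train, seed=5)
        ages = val.ages.to_numpy()
        e3 = evaluate(rc.predict_matrix(three, val).to_numpy(), ages)
        el = evaluate(rc.predict_matrix(lasso, val).to_numpy(), ages)
        assert len(lasso.terms) <= 15
        assert el.median_abs_error < e3.median_abs_error


class TestPredictAndEvaluate:
    def test_zero_coefficients_predict_intercept(self):
        model = rc.ClockModel("multivariable-linear", [], 42.0)
        assert predict_age(model, {}) == 42.0

    def test_hand_arithmetic(self):
        model = rc.ClockModel(
            "multivariable-linear",
            [("a:0", 200.0), ("a:1", -100.0), ("a:2", 50.0)],
            10.0,
        )
        assert predict_age(model, {"a:0": 0.2, "a:1": 0.1, "a:2": 0.4}) == pytest.approx(60.0)

    def test_missing_cpg_named_in_error(self):
        model = rc.ClockModel("multivariable-linear", [("a:0", 1.0)], 0.0)
        with pytest.raises(ValueError, match="a:0"):
            predict_age(model, {"b:0": 0.5})

    def test_perfect_predictions(self):
        rep = evaluate([10, 20, 30], [10, 20, 30])
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.median_abs_error == 0.0

    def test_error_metrics_by_hand(self):
        rep = evaluate([10, 20, 30], [12, 25, 41])
        assert rep.median_abs_error == pytest.approx(5.0)
        assert rep.mean_abs_error == pytest.approx(6.0)

    def test_constant_shift_keeps_r_squared(self):
        rep = evaluate([17, 27, 37], [10, 20, 30])
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.median_abs_error == pytest.approx(7.0)

    def test_swap_symmetric_for_pearson_not_identity_r2(self):
        p, c = [12.0, 30.0, 33.0], [10.0, 20.0, 30.0]
        a, b = evaluate(p, c), evaluate(c, p)
        assert a.r_squared == pytest.approx(b.r_squared)
        assert a.median_abs_error == pytest.approx(b.median_abs_error)
        assert a.r_squared_identity != pytest.approx(b.r_squared_identity)

    def test_zero_variance_flagged(self):
        rep = evaluate([5, 5, 5], [1, 2, 3])
        assert np.isnan(rep.r_squared)


class TestProfileAndAcceleration:
    def test_profile_peaks_at_configured_center(self, train_matrix, sim_panel):
        amp = sim_panel.amplicons[2]  # 21 CpGs
        prof = cpg_age_correlation_profile(train_matrix, amp.name)
        rs = np.array([r for _, r in prof])
        assert abs(int(np.argmax(rs)) - amp.center_index) <= 2

    def test_uniform_slopes_give_flat_profile(self):
        from readclock.simulate import SimAmplicon, SimPanel, simulate_cohort

        panel = SimPanel(
            (SimAmplicon("flat", 8, 3.5, np.inf, 0.004, 0.1, 0.0),), 0.0
        )
        m = simulate_cohort(panel, 24, seed=3, reads_per_amplicon=5000).beta_matrix()
        rs = np.array([r for _, r in cpg_age_correlation_profile(m, "flat")])
        assert rs.min() > 0.95  # no noise, equal slopes: all near-perfect

    def test_too_few_samples_error(self):
        ages = {"a": 0.0, "b": 50.0}
        m = _matrix({"x:0": {"a": 0.1, "b": 0.2}}, ages)
        with pytest.raises(ValueError):
            cpg_age_correlation_profile(m, "x")

    def test_identity_predictions_linear_fit(self):
        fit = fit_acceleration_curve([10, 50, 90], [10, 50, 90], "linear")
        assert fit.a == pytest.approx(1.0)
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_logarithmic_recovery(self):
        x = np.linspace(5, 130, 25)
        y = 30 * np.log(x) + 5
        fit = fit_acceleration_curve(y, x, "logarithmic")
        assert fit.a == pytest.approx(30.0, abs=1e-6)
        assert fit.b == pytest.approx(5.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_predictions_give_zero_slope(self):
        fit = fit_acceleration_curve([40, 40, 40], [10, 50, 90], "linear")
        assert fit.a == 0.0

    def test_log_form_rejects_nonpositive_ages(self):
        with pytest.raises(ValueError, match="positive"):
            fit_acceleration_curve([1, 2], [0, 10], "logarithmic")
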