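"""Marginal survival/hazard/density of the frailty model, the censored-data
likelihood, and maximum-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from qxgfrailty import (
    ConvergenceError,
    FrailtySpec,
    QXgFrailtyModel,
    WeibullHazard,
    baseline_hazard,
    simulate_survival_dataset,
    zeta_from_variance,
)
from qxgfrailty.simulate import SimulationDesign

from conftest import quad_marginal_survival


def make_spec(kappa=0.8, rho=0.9, sigma2=0.6, beta=(0.5,), kind="weibull"):
    base = baseline_hazard(kind, kappa, rho)
    return FrailtySpec(base, zeta_from_variance(sigma2), np.asarray(beta))


class TestMarginalSurvival:
    def test_starts_at_one(self):
        spec = make_spec()
        assert spec.survival(1e-300, x=[1.0]) == pytest.approx(1.0)

    def test_equals_laplace_at_cumhazard(self):
        spec = make_spec()
        for t in (0.3, 1.0, 4.0):
            s = spec.baseline.cumulative(t) * np.exp(0.5)
            lap = spec.frailty.laplace(s)[0]
            assert spec.survival(t, x=[1.0]) == pytest.approx(lap, abs=1e-10)

    @pytest.mark.parametrize("t", [0.25, 1.0, 3.0])
    @pytest.mark.parametrize("sigma2", [0.5, 0.75, 1.05])
    @pytest.mark.parametrize("xi_log", [0.0, 0.5, -0.7])
    def test_matches_mixing_integral(self, t, sigma2, xi_log):
        # independent route: integrate exp(-z*Lambda0(t)*xi) over the
        # frailty density by quadrature
        spec = make_spec(sigma2=sigma2, beta=(xi_log,))
        oracle = quad_marginal_survival(
            t, spec.zeta, spec.baseline.cumulative, np.exp(xi_log)
        )
        assert spec.survival(t, x=[1.0]) == pytest.approx(oracle, abs=1e-8)

    def test_strictly_decreasing(self):
        spec = make_spec()
        ts = np.linspace(0.01, 10, 200)
        s = spec.survival(ts, x=np.ones((200, 1)))
        assert np.all(np.diff(s) < 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            make_spec().survival(1.0, x=[1.0, 2.0])
        with pytest.raises(ValueError):
            make_spec().survival(1.0)  # covariates required


class TestMarginalHazard:
    @pytest.mark.parametrize("kind", ["weibull", "gompertz"])
    def test_equals_minus_dlogS(self, kind):
        kappa = 0.8 if kind == "weibull" else 1.07
        spec = make_spec(kappa=kappa, kind=kind)
        eps = 1e-6
        for t in (0.3, 1.0, 2.5):
            num = (
                spec.log_survival(t - eps, [1.0]) - spec.log_survival(t + eps, [1.0])
            ) / (2 * eps)
            assert spec.hazard(t, [1.0]) == pytest.approx(num, rel=1e-5)

    def test_initial_value_is_baseline_hazard(self):
        # at Lambda0 = 0 the zeta-bracket collapses to E[Z] = 1
        spec = make_spec(kappa=1.0, rho=1.0, beta=())
        t = 1e-12
        assert spec.hazard(t) == pytest.approx(spec.baseline.hazard(t), rel=1e-9)

    def test_gamma3_boundary(self):
        # zeta -> 0 is the Gamma(3) frailty: compare against quadrature
        spec = FrailtySpec(WeibullHazard(0.8, 0.9), 1e-12, np.array([]))
        t = 1.0
        surv = quad_marginal_survival(t, 0.0, spec.baseline.cumulative)
        eps = 1e-5
        s_lo = quad_marginal_survival(t - eps, 0.0, spec.baseline.cumulative)
        s_hi = quad_marginal_survival(t + eps, 0.0, spec.baseline.cumulative)
        haz_num = (np.log(s_lo) - np.log(s_hi)) / (2 * eps)
        assert spec.hazard(t) == pytest.approx(haz_num, rel=1e-5)
        assert spec.survival(t) == pytest.approx(surv, abs=1e-8)

    def test_shape_controls_early_monotonicity(self):
        t = np.array([1e-4, 1e-3])
        dec = make_spec(kappa=0.8, beta=()).hazard(t)
        inc = make_spec(kappa=1.5, beta=()).hazard(t)
        assert dec[1] < dec[0]
        assert inc[1] > inc[0]

    def test_sigma2_form_agrees_with_zeta_form(self):
        base = WeibullHazard(0.8, 0.9)
        a = FrailtySpec.from_sigma2(base, 0.6, [0.5])
        b = FrailtySpec(base, zeta_from_variance(0.6), [0.5])
        assert a.hazard(1.3, [1.0]) == pytest.approx(b.hazard(1.3, [1.0]), rel=1e-12)


class TestMarginalDensity:
    def test_density_is_hazard_times_survival(self):
        spec = make_spec()
        t = 1.7
        assert spec.density(t, [1.0]) == pytest.approx(
            spec.hazard(t, [1.0]) * spec.survival(t, [1.0]), rel=1e-10
        )

    def test_integrates_to_one(self):
        spec = make_spec(beta=())
        total, _ = integrate.quad(spec.density, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestLoglik:
    def toy_model(self, kind="weibull"):
        return QXgFrailtyModel(
            time=[1.0, 2.0, 3.0],
            status=[1, 0, 1],
            exog=[[0.0], [1.0], [0.0]],
            baseline=kind,
        )

    def test_composition_oracle(self):
        model = self.toy_model()
        spec = make_spec()
        expected = (
            spec.log_hazard(1.0, [0.0])
            + spec.log_hazard(3.0, [0.0])
            + spec.log_survival(1.0, [0.0])
            + spec.log_survival(2.0, [1.0])
            + spec.log_survival(3.0, [0.0])
        )
        params = [0.8, 0.9, zeta_from_variance(0.6), 0.5]
        assert model.loglike(params) == pytest.approx(expected, abs=1e-10)

    def test_all_censored_and_all_events(self):
        spec = make_spec()
        t = np.array([0.5, 1.5])
        x = np.array([[1.0], [0.0]])
        params = [0.8, 0.9, zeta_from_variance(0.6), 0.5]
        m_cens = QXgFrailtyModel(t, [0, 0], x)
        assert m_cens.loglike(params) == pytest.approx(
            float(np.sum(spec.log_survival(t, x))), abs=1e-12
        )
        m_ev = QXgFrailtyModel(t, [1, 1], x)
        assert m_ev.loglike(params) == pytest.approx(
            float(np.sum(np.log(spec.density(t, x)))), abs=1e-10
        )

    def test_boundary_parameters_give_minus_inf(self):
        model = self.toy_model()
        assert model.loglike([-1.0, 0.9, 1.0, 0.5]) == -np.inf
        assert model.loglike([0.8, 0.9, -2.0, 0.5]) == -np.inf

    def test_loglik_random_points_match_composition(self, rng):
        # audits the likelihood assembly over random interior parameters
        model = self.toy_model()
        for _ in range(20):
            kappa, rho, zeta = rng.uniform(0.3, 2.0, 3)
            beta = rng.normal()
            spec = FrailtySpec(WeibullHazard(kappa, rho), zeta, [beta])
            direct = sum(
                d * float(spec.log_hazard(t, [x])) + float(spec.log_survival(t, [x]))
                for t, d, x in zip(model.time, model.status, model.exog[:, 0])
            )
            assert model.loglike([kappa, rho, zeta, beta]) == pytest.approx(
                direct, abs=1e-8
            )


class TestFit:
    @pytest.mark.parametrize("seed", [5, 8])
    def test_parameter_recovery_weibull(self, seed):
        # the likelihood carries a flat baseline-shape/frailty ridge, so
        # point-wise recovery is noisy even at n=2000; the Wilks-calibrated
        # check is that the truth is not rejected by the likelihood ratio
        design = SimulationDesign(
            n=2000, shape=0.8, scale=0.9, sigma2=0.6, beta=(0.5,), seed=seed
        )
        from scipy import stats as sps

        data = simulate_survival_dataset(design, np.random.default_rng(seed))
        model = QXgFrailtyModel.from_dataframe(data)
        res = model.fit(seed=1)
        assert res.converged
        truth = [0.8, 0.9, design.spec.zeta, 0.5]
        lr = 2.0 * (res.llf - model.loglike(truth))
        assert lr >= -1e-6  # the MLE dominates the truth
        assert lr < sps.chi2.ppf(0.9999, 4)

    def test_refit_from_fitted_values(self):
        design = SimulationDesign(n=800, seed=9)
        data = simulate_survival_dataset(design, np.random.default_rng(9))
        model = QXgFrailtyModel.from_dataframe(data)
        res = model.fit(seed=2)
        res2 = model.fit(start_params=res.params, n_starts=1, seed=2)
        assert res2.llf >= res.llf - 1e-6

    def test_loglik_never_below_start(self):
        design = SimulationDesign(n=300, seed=13)
        data = simulate_survival_dataset(design, np.random.default_rng(13))
        model = QXgFrailtyModel.from_dataframe(data)
        start = model._auto_start()
        res = model.fit(start_params=start, seed=0)
        assert res.llf >= model.loglike(start)

    def test_degenerate_dataset_fails_explicitly(self):
        model = QXgFrailtyModel([1.0], [1], [[0.5]])
        with pytest.raises(ConvergenceError):
            model.fit()

    def test_summary_and_dict(self):
        design = SimulationDesign(n=400, seed=3)
        data = simulate_survival_dataset(design, np.random.default_rng(3))
        res = QXgFrailtyModel.from_dataframe(data).fit(n_starts=1)
        text = res.summary()
        assert "kappa" in text and "sigma2" in text
        d = res.to_dict()
        assert {"kappa", "rho", "sigma2", "loglik", "seed"} <= set(d)

    def test_from_dataframe_covariate_selection(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "status": [1, 1, 0, 1],
             "age": [0.1, 0.4, 0.2, 0.9]}
        )
        m = QXgFrailtyModel.from_dataframe(df)
        assert m.exog_names == ["age"]
        assert m.k_exog == 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            QXgFrailtyModel([1.0, -2.0], [1, 1])
        with pytest.raises(ValueError):
            QXgFrailtyModel([1.0, 2.0], [1, 2])
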