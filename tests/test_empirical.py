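"""Empirical depot models: analytic identities, ODE equivalence, recovery."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mapbpk.empirical import (EmpiricalModelSpec, FitFailureError,
                              canonicalize_flip_flop, estimate_clf_by_curvefit,
                              fit_empirical, kskin_from_two_compartment,
                              predict_empirical)
from mapbpk.engine import ConcentrationSeries, Regimen, simulate_at
from mapbpk.synthetic import (SINGLE_DOSE_SCHEDULE_H, NoiseModel,
                              make_rat_map_study, synth_profile)

ONE_CPT = EmpiricalModelSpec(kind="one_compartment", ka_h=3e-3,
                             cl_ml_h=600.0, v_ml=5000.0, dose_ug=2.5e6)
TWO_CPT = EmpiricalModelSpec(kind="two_compartment", ka_h=3.43e-3,
                             cl_ml_h=2.2, v_ml=40.0, q_ml_h=0.6, v2_ml=30.0,
                             dose_ug=11.72e3)


class TestPrediction:
    def test_starts_at_zero(self):
        for spec in (ONE_CPT, TWO_CPT):
            assert predict_empirical(spec, np.array([0.0]))[0] \
                == pytest.approx(0.0, abs=1e-12)

    def test_bateman_tmax_identity(self):
        # Cmax time = ln(ka/ke)/(ka − ke)
        ka, ke = ONE_CPT.ka_h, ONE_CPT.cl_ml_h / ONE_CPT.v_ml
        t = np.linspace(0, 2000, 400001)
        c = predict_empirical(ONE_CPT, t)
        tmax = np.log(ka / ke) / (ka - ke)
        assert t[c.argmax()] == pytest.approx(tmax, abs=0.01)

    def test_equal_rate_limit(self):
        # ka = ke limit: C(t) = D·ka·t·e^(−ka·t)/V
        spec = EmpiricalModelSpec(kind="one_compartment", ka_h=0.01,
                                  cl_ml_h=1.0, v_ml=100.0, dose_ug=1000.0)
        t = np.array([10.0, 50.0, 200.0])
        expected = 1000.0 * 0.01 * t * np.exp(-0.01 * t) / 100.0
        assert np.allclose(predict_empirical(spec, t), expected, rtol=1e-9)

    @pytest.mark.parametrize("spec", [ONE_CPT, TWO_CPT],
                             ids=["one_cpt", "two_cpt"])
    def test_matches_ode_oracle(self, spec):
        ka, cl, v = spec.ka_h, spec.cl_ml_h, spec.v_ml
        if spec.kind == "one_compartment":
            A = np.array([[-ka, 0.0], [ka, -cl / v]])
            x0 = [spec.dose_ug, 0.0]
        else:
            k12, k21 = spec.q_ml_h / v, spec.q_ml_h / spec.v2_ml
            A = np.array([[-ka, 0, 0], [ka, -(cl / v + k12), k21],
                          [0, k12, -k21]])
            x0 = [spec.dose_ug, 0.0, 0.0]
        t_eval = np.linspace(0, 1000, 60)
        sol = solve_ivp(lambda t, y: A @ y, (0, 1000), x0, t_eval=t_eval,
                        rtol=1e-11, atol=1e-12)
        pred = predict_empirical(spec, t_eval)
        assert np.max(np.abs(pred - sol.y[1] / v)) \
            < 1e-8 * np.max(sol.y[1] / v)

    def test_multi_dose_superposition(self):
        spec3 = EmpiricalModelSpec(kind="two_compartment", ka_h=3.43e-3,
                                   cl_ml_h=2.2, v_ml=40.0, q_ml_h=0.6,
                                   v2_ml=30.0, dose_ug=11.72e3,
                                   dose_times_h=(0.0, 168.0))
        t = np.linspace(0, 800, 50)
        total = predict_empirical(spec3, t)
        single = predict_empirical(TWO_CPT, t)
        shifted = np.where(t >= 168.0,
                           predict_empirical(TWO_CPT,
                                             np.maximum(t - 168.0, 0)), 0.0)
        assert np.allclose(total, single + shifted, rtol=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            predict_empirical(ONE_CPT, np.array([-1.0]))


class TestFlipFlopCanonicalization:
    def test_image_has_identical_curve_and_slowest_ka(self):
        # exchanged representative of the truth: swap roles then canonicalize
        t = np.linspace(1, 1500, 120)
        truth_curve = predict_empirical(TWO_CPT, t)
        exchanged = EmpiricalModelSpec(
            kind="two_compartment", ka_h=0.0146, cl_ml_h=2.2, v_ml=40.0,
            q_ml_h=0.6, v2_ml=30.0, dose_ug=11.72e3)
        canon = canonicalize_flip_flop(exchanged)
        assert canon.ka_h <= exchanged.ka_h
        assert np.allclose(predict_empirical(canon, t),
                           predict_empirical(exchanged, t), rtol=1e-9)

    def test_one_compartment_swap_preserves_curve_and_cl(self):
        fast_ka = EmpiricalModelSpec(kind="one_compartment", ka_h=0.12,
                                     cl_ml_h=600.0, v_ml=5000.0,
                                     dose_ug=2.5e6)
        canon = canonicalize_flip_flop(fast_ka)
        assert canon.ka_h == pytest.approx(0.12)  # ke = 0.12 equals ka
        slow = EmpiricalModelSpec(kind="one_compartment", ka_h=0.5,
                                  cl_ml_h=600.0, v_ml=5000.0, dose_ug=2.5e6)
        canon2 = canonicalize_flip_flop(slow)
        t = np.linspace(0, 100, 200)
        assert canon2.ka_h < slow.ka_h
        assert canon2.cl_ml_h == pytest.approx(slow.cl_ml_h)
        assert np.allclose(predict_empirical(canon2, t),
                           predict_empirical(slow, t), rtol=1e-9)


class TestFitting:
    @pytest.mark.parametrize("truth", [ONE_CPT, TWO_CPT],
                             ids=["one_cpt", "two_cpt"])
    def test_noise_free_recovery(self, truth):
        series, _ = synth_profile(truth, SINGLE_DOSE_SCHEDULE_H,
                                  NoiseModel(0.0, 0.0, seed=1))
        fit = fit_empirical(series, truth.kind, dose_ug=truth.dose_ug,
                            seed=3)
        for name, value in truth.parameters.items():
            assert fit.estimates[name] == pytest.approx(value, rel=1e-3)
        assert fit.rss < 1e-12

    def test_rss_not_worse_than_truth(self):
        noisy, _ = synth_profile(TWO_CPT, SINGLE_DOSE_SCHEDULE_H,
                                 NoiseModel(0.10, 0.01, seed=4))
        fit = fit_empirical(noisy, "two_compartment",
                            dose_ug=TWO_CPT.dose_ug, seed=2)
        truth_res = (predict_empirical(TWO_CPT, noisy.times_h)
                     - noisy.conc_ug_ml)
        assert fit.rss <= truth_res @ truth_res + 1e-12

    def test_noisy_ka_recovery_one_compartment(self):
        # 10 % proportional noise, 12 points: release rate within 5 %
        schedule = np.linspace(24, 1320, 12)
        series, _ = synth_profile(ONE_CPT, schedule,
                                  NoiseModel(0.10, 0.0, seed=6))
        # log-scale objective: the appropriate weighting for proportional
        # measurement error
        fit = fit_empirical(series, "one_compartment",
                            dose_ug=ONE_CPT.dose_ug, seed=1, log_scale=True)
        assert fit.estimates["ka_h"] == pytest.approx(ONE_CPT.ka_h, rel=0.05)

    def test_zero_data_fails_loudly(self):
        series = ConcentrationSeries(times_h=np.linspace(1, 100, 8),
                                     conc_ug_ml=np.zeros(8))
        with pytest.raises(FitFailureError):
            fit_empirical(series, "one_compartment", dose_ug=1e3)

    def test_too_few_points_rejected(self):
        series = ConcentrationSeries(times_h=np.array([1.0, 2.0]),
                                     conc_ug_ml=np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            fit_empirical(series, "two_compartment", dose_ug=1e3)

    def test_kskin_mapping(self):
        series, _ = synth_profile(TWO_CPT, SINGLE_DOSE_SCHEDULE_H,
                                  NoiseModel(0.0, 0.0, seed=1))
        fit = fit_empirical(series, "two_compartment",
                            dose_ug=TWO_CPT.dose_ug, seed=3)
        assert kskin_from_two_compartment(fit) == pytest.approx(
            TWO_CPT.q_ml_h, rel=1e-3)


class TestPBPKCurveFit:
    def test_clf_round_trip(self, rat_im):
        subject, drug = rat_im
        reg = Regimen(route="IM", dose_mg=2.5, n_doses=1, horizon_h=672.0)
        times = np.array(SINGLE_DOSE_SCHEDULE_H)
        observed = ConcentrationSeries(
            times_h=times, conc_ug_ml=simulate_at(subject, drug, reg, times))
        fit = estimate_clf_by_curvefit(subject, drug, reg, observed,
                                       free_params=("clf_l_h",), n_starts=3,
                                       seed=0)
        assert fit.estimates["clf_l_h"] == pytest.approx(0.6, rel=1e-3)

    def test_joint_clf_knp_round_trip(self, rat_im):
        subject, drug = rat_im
        reg = Regimen(route="IM", dose_mg=2.5, n_doses=1, horizon_h=672.0)
        times = np.array(SINGLE_DOSE_SCHEDULE_H)
        observed = ConcentrationSeries(
            times_h=times, conc_ug_ml=simulate_at(subject, drug, reg, times))
        fit = estimate_clf_by_curvefit(
            subject, drug, reg, observed, free_params=("clf_l_h", "knp_h"),
            n_starts=3, seed=0)
        assert fit.estimates["clf_l_h"] == pytest.approx(0.6, rel=1e-3)
        assert fit.estimates["knp_h"] == pytest.approx(3e-3, rel=1e-3)

    def test_one_dimensional_profile_unimodal(self, rat_im):
        # grid scan of the 1-D RSS profile in CL/F around the truth
        subject, drug = rat_im
        from dataclasses import replace

        reg = Regimen(route="IM", dose_mg=2.5, n_doses=1, horizon_h=672.0)
        times = np.array(SINGLE_DOSE_SCHEDULE_H)
        obs = simulate_at(subject, drug, reg, times)
        rss = []
        grid = np.geomspace(0.1, 3.0, 13)
        for clf in grid:
            pred = simulate_at(subject, replace(drug, clf_l_h=clf), reg,
                               times)
            rss.append(np.sum((pred - obs) ** 2))
        rss = np.array(rss)
        i_min = rss.argmin()
        assert grid[i_min] == pytest.approx(0.6, rel=0.2)
        assert np.all(np.diff(rss[: i_min + 1]) <= 0)
        assert np.all(np.diff(rss[i_min:]) >= 0)

    def test_unknown_free_parameter_rejected(self, rat_im):
        subject, drug = rat_im
        reg = Regimen(route="IM", dose_mg=2.5, n_doses=1, horizon_h=672.0)
        obs = ConcentrationSeries(times_h=np.array([1.0, 2.0, 3.0]),
                                  conc_ug_ml=np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            estimate_clf_by_curvefit(subject, drug, reg, obs,
                                     free_params=("volume",))
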