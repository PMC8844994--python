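"""MAP Bayesian estimation, Laplace NLME fitting, bootstrap and residuals."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import log_ndtr
from scipy.stats import norm

import neovanc as nv
from neovanc.estimation import _build_design

from conftest import make_doses


def build_subject(obs, doses=None, wt=1.68, scr=42.0, pma=236.0):
    doses = doses or make_doses(6)
    covs = [nv.CovariateRecord(d.time, body_weight=wt, serum_creatinine=scr,
                               pma=pma + d.time / 24.0) for d in doses]
    return nv.SubjectRecord("T1", dose_events=doses, observations=obs,
                            covariate_series=covs)


class TestNeg2LogPosterior:
    def test_no_observations_prior_only(self, pop):
        s = build_subject([])
        assert nv.neg2log_posterior([0.0, 0.0], s, pop) == pytest.approx(0.0)
        v = nv.neg2log_posterior([0.3, -0.2], s, pop)
        expected = 0.3 ** 2 / pop.omega2_bsv + 0.2 ** 2 / pop.omega2_bov
        assert v == pytest.approx(expected, rel=1e-12)

    def test_blq_term_vanishes_far_below_lloq(self, pop):
        # prediction far below the LLOQ relative to the residual SD:
        # censoring probability -> 1, so the M3 term contributes nothing
        pop = pop.replace(sigma_add=0.05)
        doses = [nv.DoseEvent(0.0, 0.01, 1.0, occasion=1)]
        s_blq = build_subject([nv.ConcObservation(100.0, 1.0, blq=True)],
                              doses=doses)
        s_none = build_subject([], doses=doses)
        v1 = nv.neg2log_posterior([0.0, 0.0], s_blq, pop)
        v0 = nv.neg2log_posterior([0.0, 0.0], s_none, pop)
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_scalar_calculator_fixture(self, pop):
        # one quantified observation: likelihood term assembled by hand from
        # the (ODE-verified) concentration, the combined SD and the prior
        s = build_subject([nv.ConcObservation(23.9, 11.2)])
        etas = np.array([0.11, -0.04])
        pred = float(nv.predict_concentrations(
            s, pop, [23.9], eta_bsv=etas[0], eta_bov_by_occasion={1: etas[1]})[0])
        sd = nv.residual_sd(pred, pop.sigma_prop, pop.sigma_add)
        expected = (((11.2 - pred) / sd) ** 2 + 2 * math.log(sd)
                    + etas[0] ** 2 / pop.omega2_bsv
                    + etas[1] ** 2 / pop.omega2_bov)
        got = nv.neg2log_posterior(etas, s, pop)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_blq_calculator_fixture(self, pop):
        s = build_subject([nv.ConcObservation(47.9, 1.0, blq=True, lloq=1.0)],
                          doses=make_doses(2))
        design = _build_design(s)
        from neovanc.estimation import _dose_params, _predict
        pred = _predict(design, _dose_params(design, pop), [1.0])[0]
        sd = nv.residual_sd(pred, pop.sigma_prop, pop.sigma_add)
        expected = -2.0 * log_ndtr((1.0 - pred) / sd)
        assert nv.neg2log_posterior([0.0, 0.0], s, pop) == pytest.approx(
            expected, rel=1e-9)

    def test_invariant_to_row_order(self, pop):
        rows = [
            dict(ID="A", TIME_H=0.0, EVID=1, AMT_MG=20.0, RATE_MG_H=20.0,
                 WT_KG=1.5, SCR_UMOL_L=40.0, PMA_DAYS=230.0),
            dict(ID="A", TIME_H=9.0, EVID=0, DV_MG_L=12.0, BLQ=0,
                 WT_KG=1.5, SCR_UMOL_L=40.0, PMA_DAYS=230.4),
            dict(ID="A", TIME_H=7.9, EVID=0, DV_MG_L=6.0, BLQ=0,
                 WT_KG=1.5, SCR_UMOL_L=40.0, PMA_DAYS=230.3),
        ]
        from conftest import make_table
        c1 = nv.parse_dataset(make_table(rows))
        c2 = nv.parse_dataset(make_table([rows[0], rows[2], rows[1]]))
        v1 = nv.neg2log_posterior([0.1, 0.05], c1.subjects[0], pop)
        v2 = nv.neg2log_posterior([0.1, 0.05], c2.subjects[0], pop)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestMAP:
    def test_mode_at_zero_for_exact_data(self, pop):
        # with a prediction-independent residual SD the posterior is exactly
        # stationary at zero etas when the data equal the zero-eta prediction
        # (with interaction the 2*ln sd term shifts the mode slightly)
        pop = pop.replace(sigma_prop=0.0)
        s0 = build_subject([])
        preds = nv.predict_concentrations(s0, pop, [23.9, 25.0])
        s = build_subject([nv.ConcObservation(23.9, float(preds[0])),
                           nv.ConcObservation(25.0, float(preds[1]))])
        est = nv.map_estimate(s, pop)
        assert np.all(np.abs(est.etas) < 1e-4)

    def test_matches_grid_search_single_eta(self):
        pop = nv.PopulationParameters().replace(omega2_bov=0.0)
        s = build_subject([nv.ConcObservation(23.9, 15.0),
                           nv.ConcObservation(25.0, 30.0)])
        est = nv.map_estimate(s, pop)
        grid = np.linspace(-1.0, 1.0, 4001)
        vals = [nv.neg2log_posterior([g], s, pop) for g in grid]
        g_best = grid[int(np.argmin(vals))]
        assert est.etas[0] == pytest.approx(g_best, abs=6e-4)

    def test_matches_grid_search_two_etas(self, pop):
        s = build_subject([nv.ConcObservation(23.9, 15.0),
                           nv.ConcObservation(25.0, 30.0)])
        est = nv.map_estimate(s, pop)
        grid = np.linspace(-0.8, 0.8, 161)
        best, arg = np.inf, None
        for a in grid:
            for b in grid:
                v = nv.neg2log_posterior([a, b], s, pop)
                if v < best:
                    best, arg = v, (a, b)
        assert est.etas[0] == pytest.approx(arg[0], abs=0.011)
        assert est.etas[1] == pytest.approx(arg[1], abs=0.011)

    def test_second_observation_never_widens_bsv_posterior(self, pop):
        s1 = build_subject([nv.ConcObservation(23.9, 12.0)])
        s2 = build_subject([nv.ConcObservation(23.9, 12.0),
                            nv.ConcObservation(25.0, 28.0)])
        e1 = nv.map_estimate(s1, pop)
        e2 = nv.map_estimate(s2, pop)
        i = e1.eta_names.index("bsv")
        assert e2.posterior_covariance[i, i] <= e1.posterior_covariance[i, i] + 1e-10

    def test_rich_data_recovers_individual_cl(self, pop):
        # single subject, dense sampling: CL multiplier within 5% of truth
        s0 = build_subject([], doses=make_doses(9))
        times = [float(t) for t in np.linspace(2.0, 70.0, 12)]
        eta_true = 0.25
        preds = nv.predict_concentrations(s0, pop, times, eta_bsv=eta_true)
        obs = [nv.ConcObservation(t, float(p)) for t, p in zip(times, preds)]
        est = nv.map_estimate(build_subject(obs, doses=make_doses(9)), pop)
        mult_hat = math.exp(est.eta_bsv + est.eta_bov_by_occasion[1])
        assert mult_hat == pytest.approx(math.exp(eta_true), rel=0.05)


class TestPosteriorSamples:
    def test_moments_match_laplace_posterior(self, pop):
        s = build_subject([nv.ConcObservation(23.9, 12.0),
                           nv.ConcObservation(25.0, 28.0)])
        est = nv.map_estimate(s, pop)
        draws = nv.posterior_samples(est, 100_000, seed=11)
        assert np.allclose(draws.mean(axis=0), est.etas, atol=0.01)
        assert np.allclose(np.cov(draws.T), est.posterior_covariance,
                           atol=5e-4)

    def test_zero_covariance_collapses_to_mode(self, pop):
        s = build_subject([nv.ConcObservation(23.9, 12.0)])
        est = nv.map_estimate(s, pop)
        est.posterior_covariance = np.zeros_like(est.posterior_covariance)
        draws = nv.posterior_samples(est, 50, seed=3)
        assert np.allclose(draws, est.etas)

    def test_reproducible_under_seed(self, pop):
        s = build_subject([nv.ConcObservation(23.9, 12.0)])
        est = nv.map_estimate(s, pop)
        a = nv.posterior_samples(est, 100, seed=7)
        b = nv.posterior_samples(est, 100, seed=7)
        assert np.array_equal(a, b)


class TestLRT:
    def test_published_comparison_rounds_to_006(self):
        assert round(nv.lrt_pvalue(5.583, 2), 2) == 0.06

    def test_zero_dofv(self):
        assert nv.lrt_pvalue(0.0, 1) == 1.0

    def test_chi2_table_value(self):
        assert nv.lrt_pvalue(3.841, 1) == pytest.approx(0.05, abs=5e-5)

    def test_strictly_decreasing_in_dofv(self):
        vals = [nv.lrt_pvalue(d, 2) for d in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_df_validation(self):
        with pytest.raises(ValueError):
            nv.lrt_pvalue(1.0, 0)


class TestNLMEFit:
    def test_self_consistency_ofv_not_worse_than_truth(self, pop, small_cohort):
        cohort, _ = small_cohort
        model = nv.PopPKModel(cohort, pop,
                              fixed=("tvvc", "tvq", "tvvp", "hill", "mat50",
                                     "scr_exponent", "omega2_bsv",
                                     "omega2_bov", "sigma_prop", "sigma_add"))
        ofv_truth = model.neg2loglike(model._theta0())
        res = model.fit(compute_se=False)
        n = sum(d.n_cont for d in model.designs)
        assert res.ofv <= ofv_truth - n * math.log(2 * math.pi) + 1e-6
        assert res.params.tvcl == pytest.approx(pop.tvcl, rel=0.15)

    def test_summary_and_se(self, pop, small_cohort):
        cohort, _ = small_cohort
        model = nv.PopPKModel(cohort, pop,
                              fixed=("tvvc", "tvq", "tvvp", "hill", "mat50",
                                     "scr_exponent", "omega2_bov",
                                     "sigma_prop", "sigma_add"))
        res = model.fit()
        assert math.isfinite(res.ofv)
        assert res.condition_number >= 1.0
        ci = res.conf_int()
        assert (ci["lower"] <= ci["estimate"]).all()
        assert (ci["estimate"] <= ci["upper"]).all()
        text = res.summary()
        assert "OFV" in text and "tvcl" in text
        sh = res.shrinkage()
        assert "bsv" in sh and sh["bsv"] < 100.0


class TestFreeAllometricExponents:
    def test_free_exponent_never_fits_worse(self, pop, small_cohort):
        """The freely-estimated-exponent model nests the fixed one (dOFV>=0)."""
        cohort, _ = small_cohort
        fixed = tuple(n for n in nv.estimation._FREE_DEFAULT if n != "tvcl")
        base = nv.PopPKModel(cohort, pop, fixed=fixed).fit(compute_se=False)
        free = nv.PopPKModel(cohort, pop, fixed=fixed,
                             free_extra=("wt_exp_cl_q",)).fit(compute_se=False)
        dofv = base.ofv - free.ofv
        assert dofv >= -1e-6
        assert 0.0 < nv.lrt_pvalue(dofv, 1) <= 1.0

    def test_unknown_free_extra_rejected(self, pop, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            nv.PopPKModel(cohort, pop, free_extra=("tvcl",))


class TestBootstrap:
    def test_identical_subjects_zero_width_ci(self, pop):
        s = build_subject([nv.ConcObservation(23.9, 12.0),
                           nv.ConcObservation(25.0, 28.0)])
        subjects = [nv.estimation.replace_id(s, f"C{i}") for i in range(5)]
        fixed = tuple(n for n in nv.estimation._FREE_DEFAULT if n != "tvcl")
        res = nv.bootstrap(nv.Cohort(subjects=subjects), pop, n=4, seed=5,
                           fixed=fixed, maxiter=50)
        lo, hi = res.ci90["tvcl"]
        assert hi - lo < 1e-6

    def test_same_seed_same_resamples(self, pop, small_cohort):
        cohort, _ = small_cohort
        fixed = tuple(n for n in nv.estimation._FREE_DEFAULT if n != "tvcl")
        r1 = nv.bootstrap(cohort, pop, n=3, seed=9, fixed=fixed, maxiter=50)
        r2 = nv.bootstrap(cohort, pop, n=3, seed=9, fixed=fixed, maxiter=50)
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)

    def test_reduced_coverage_of_generating_tvcl(self, pop):
        # 3 independent experiments, 20 resamples each, TVCL free only:
        # the generating TVCL should fall inside the 90% CI most of the time
        fixed = tuple(n for n in nv.estimation._FREE_DEFAULT if n != "tvcl")
        hits = 0
        for k in range(3):
            cohort, truth = nv.generate_cohort(30, seed=500 + k)
            cohort = nv.simulate_observations(cohort, truth, pop,
                                              seed=600 + k)
            res = nv.bootstrap(cohort, pop, n=20, seed=700 + k, fixed=fixed,
                               maxiter=60)
            lo, hi = res.ci90["tvcl"]
            hits += int(lo <= pop.tvcl <= hi)
        assert hits >= 2


class TestCWRES:
    def test_matches_direct_linearization_single_observation(self, pop):
        s = build_subject([nv.ConcObservation(23.9, 12.0)])
        table = nv.cwres(nv.Cohort(subjects=[s]), pop)
        assert len(table) == 1
        est = nv.map_estimate(s, pop)
        h = 1e-5
        def f(etas):
            ebov = {1: etas[1]}
            return float(nv.predict_concentrations(
                s, pop, [23.9], eta_bsv=etas[0], eta_bov_by_occasion=ebov)[0])
        e = est.etas
        g = np.array([(f(e + np.array([h, 0])) - f(e - np.array([h, 0]))) / (2 * h),
                      (f(e + np.array([0, h])) - f(e - np.array([0, h]))) / (2 * h)])
        f_hat = f(e)
        sd = nv.residual_sd(f_hat, pop.sigma_prop, pop.sigma_add)
        var = (g[0] ** 2 * pop.omega2_bsv + g[1] ** 2 * pop.omega2_bov
               + sd ** 2)
        expect = (12.0 - f_hat + float(g @ e)) / math.sqrt(var)
        assert table["cwres"].iloc[0] == pytest.approx(expect, rel=1e-4)

    def test_null_fraction_outside_1p96(self, pop):
        cohort, truth = nv.generate_cohort(
            60, nv.DemographicsConfig(
                sampling=nv.SamplingDesign(troughs_before=(2, 5),
                                           peaks_after=(3, 6))), seed=7)
        cohort = nv.simulate_observations(
            cohort, truth, pop,
            nv.SamplingDesign(troughs_before=(2, 5), peaks_after=(3, 6)),
            seed=8)
        table = nv.cwres(cohort, pop)
        frac = (table["cwres"].abs() > 1.96).mean()
        assert 0.02 <= frac <= 0.09


class TestVarianceExplained:
    def test_empty_subset_is_zero(self, pop, small_cohort):
        cohort, _ = small_cohort
        assert nv.variance_explained(cohort, pop, ()) == pytest.approx(
            0.0, abs=1e-12)

    def test_full_subset_without_random_effects_is_100(self, small_cohort):
        cohort, _ = small_cohort
        pop0 = nv.PopulationParameters().replace(omega2_bsv=0.0,
                                                 omega2_bov=0.0)
        assert nv.variance_explained(cohort, pop0) == pytest.approx(100.0)

    def test_subset_bounded_by_full(self, pop, small_cohort):
        cohort, _ = small_cohort
        full = nv.variance_explained(cohort, pop)
        for sub in (("wt",), ("pma",), ("scr",)):
            assert 0.0 <= nv.variance_explained(cohort, pop, sub)
        assert full <= 100.0
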