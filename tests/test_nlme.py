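import warnings
from dataclasses import replace

import numpy as np
import pytest

from conftest import make_dataset
from oracles import agq_marginal_ofv, exact_log_normcdf
from fviiipk.population_model import (
    CovariateEffect,
    PopulationModel,
    omega_from_cv,
)
from fviiipk.structural_pk import DispositionParams, DoseEvent
from fviiipk.synthetic_cohort import Observation, SubjectRecord, sample_covariates, simulate_subject
from fviiipk.nlme import (
    ErrorModel,
    fit_population,
    laplace_ofv,
    lrt_select,
    bootstrap,
    shrinkage,
    stepwise_covariates,
    subject_loglik,
)


def _record(cov, times, values, blq=None, doses=(DoseEvent(2000.0, 0.0, 0.0),), lloq=0.01):
    blq = blq or [False] * len(times)
    obs = tuple(
        Observation(time=t, value=None if b else v, blq=b, lloq=lloq)
        for t, v, b in zip(times, values, blq)
    )
    return SubjectRecord(id="X", covariates=cov, doses=tuple(doses), observations=obs)


class TestSubjectLoglik:
    def test_point_at_prediction_closed_form(self, simple_1cpt):
        """A non-BLQ point exactly at the model prediction leaves only the
        normalization term log(1/(sqrt(2 pi) sigma_prop f))."""
        cov = sample_covariates(1, seed=0)[0]
        from fviiipk.population_model import typical_values
        from fviiipk.structural_pk import full_profile, micro_to_macro, BaselineSpec

        macro = micro_to_macro(typical_values(simple_1cpt, cov))
        f = full_profile(macro, [DoseEvent(2000.0, 0.0, 0.0)], BaselineSpec(), 6.0)
        rec = _record(cov, [6.0], [f])
        got = subject_loglik(simple_1cpt, rec, (0.0, 0.0))
        want = -np.log(np.sqrt(2 * np.pi) * simple_1cpt.sigma_prop * f)
        assert got == pytest.approx(want, rel=1e-10)

    def test_m3_term_matches_high_precision_cdf(self, simple_1cpt):
        """The censored contribution equals log Phi((LLOQ - f)/sd) computed
        with arbitrary-precision arithmetic."""
        cov = sample_covariates(1, seed=1)[0]
        from fviiipk.population_model import typical_values
        from fviiipk.structural_pk import full_profile, micro_to_macro, BaselineSpec

        macro = micro_to_macro(typical_values(simple_1cpt, cov))
        for t, lloq in [(48.0, 0.01), (72.0, 0.05), (24.0, 0.02)]:
            f = full_profile(macro, [DoseEvent(2000.0, 0.0, 0.0)], BaselineSpec(), t)
            rec = _record(cov, [t], [None], blq=[True], lloq=lloq)
            got = subject_loglik(simple_1cpt, rec, (0.0, 0.0))
            want = exact_log_normcdf((lloq - f) / (simple_1cpt.sigma_prop * f))
            assert got == pytest.approx(want, abs=1e-10)

    def test_blq_far_above_lloq_vanishes(self, simple_1cpt):
        """A censored point while the prediction is far above the LLOQ is
        nearly impossible: the contribution plunges."""
        cov = sample_covariates(1, seed=2)[0]
        rec_early = _record(cov, [0.5], [None], blq=[True])  # f ~ 0.8 >> 0.01
        rec_late = _record(cov, [96.0], [None], blq=[True])
        early = subject_loglik(simple_1cpt, rec_early, (0, 0))
        late = subject_loglik(simple_1cpt, rec_late, (0, 0))
        assert early < -20 < -5 < late
        # contribution diverges as f/LLOQ grows (larger eta_V1 -> larger f)
        larger_f = subject_loglik(simple_1cpt, rec_early, (0, -1.0))
        assert larger_f < early


class TestLaplaceOFV:
    def test_omega_to_zero_limit(self, simple_1cpt, small_1cpt_dataset):
        """With vanishing BSV the Laplace OFV collapses to -2 sum loglik(0):
        the prior normalization and the Hessian log-determinant cancel."""
        tiny = replace(simple_1cpt, omega=np.eye(2) * 1e-10)
        ofv = laplace_ofv(tiny, small_1cpt_dataset)
        direct = -2.0 * sum(
            subject_loglik(tiny, r, (0.0, 0.0)) for r in small_1cpt_dataset
        )
        assert ofv == pytest.approx(direct, abs=1e-4)

    def test_agrees_with_gauss_hermite_single_subject(self, simple_1cpt):
        """Spec of the approximation: within 0.1 of 32-node adaptive
        quadrature for one subject with two observations and no censoring."""
        recs = make_dataset(simple_1cpt, n=1, times=[3.0, 24.0], seed=8)
        assert not any(o.blq for o in recs[0].observations)
        lap = laplace_ofv(simple_1cpt, recs)
        agq = agq_marginal_ofv(simple_1cpt, recs)
        assert lap == pytest.approx(agq, abs=0.1)

    def test_agrees_with_gauss_hermite_small_instances(self, simple_1cpt):
        """Randomized <=3-observation subjects, including censored points:
        Laplace within 0.5 OFV units of the quadrature oracle."""
        for seed in range(4):
            recs = make_dataset(
                simple_1cpt, n=3, times=[1.0, 12.0, 72.0], seed=100 + seed, dose=600.0
            )
            lap = laplace_ofv(simple_1cpt, recs)
            agq = agq_marginal_ofv(simple_1cpt, recs)
            assert lap == pytest.approx(agq, abs=0.5)

    def test_additivity_under_duplication(self, simple_1cpt, small_1cpt_dataset):
        data = small_1cpt_dataset
        doubled = data + [replace(r, id=r.id + "b") for r in data]
        assert laplace_ofv(simple_1cpt, doubled) == pytest.approx(
            2 * laplace_ofv(simple_1cpt, data), rel=1e-9
        )

    def test_subject_order_invariance(self, simple_1cpt, small_1cpt_dataset):
        shuffled = list(reversed(small_1cpt_dataset))
        assert laplace_ofv(simple_1cpt, shuffled) == pytest.approx(
            laplace_ofv(simple_1cpt, small_1cpt_dataset), rel=1e-10
        )

    def test_time_unit_rescaling_invariance(self, simple_1cpt, small_1cpt_dataset):
        """Hours -> days with clearances rescaled leaves the OFV unchanged."""
        c = 24.0
        model_d = replace(
            simple_1cpt, fixed=DispositionParams(CL=simple_1cpt.fixed.CL * c, V1=simple_1cpt.fixed.V1)
        )
        data_d = [
            replace(
                r,
                doses=tuple(
                    DoseEvent(d.amount, d.start / c, d.duration / c) for d in r.doses
                ),
                observations=tuple(
                    replace(o, time=o.time / c) for o in r.observations
                ),
            )
            for r in small_1cpt_dataset
        ]
        assert laplace_ofv(model_d, data_d) == pytest.approx(
            laplace_ofv(simple_1cpt, small_1cpt_dataset), rel=1e-8
        )

    def test_censoring_is_active(self, published):
        """Replacing BLQ flags by LLOQ-valued observations must change the OFV."""
        from fviiipk.synthetic_cohort import development_dataset

        data = development_dataset(n=40, seed=3)
        assert any(o.blq for r in data for o in r.observations)
        uncensored = [
            replace(
                r,
                observations=tuple(
                    replace(o, blq=False, value=o.lloq) if o.blq else o
                    for o in r.observations
                ),
            )
            for r in data
        ]
        a = laplace_ofv(published, data)
        b = laplace_ofv(published, uncensored)
        assert abs(a - b) > 1.0


class TestFitPopulation:
    def test_recovers_generating_parameters(self, simple_1cpt):
        """Dense one-compartment data, n = 200: structural parameters
        recovered within 5%."""
        data = make_dataset(
            simple_1cpt, n=200, times=[1.0, 3.0, 6.0, 12.0, 24.0, 48.0], seed=21
        )
        fit = fit_population(data, structure="1cpt", error="proportional")
        assert fit.converged
        p = fit.params()
        assert p["CL_pop"] == pytest.approx(0.2, rel=0.05)
        assert p["V1_pop"] == pytest.approx(2.5, rel=0.05)
        assert p["sigma_prop"] == pytest.approx(0.15, rel=0.15)
        # dense design: little shrinkage of either BSV term
        assert max(fit.eta_shrinkage) < 0.10

    def test_degenerate_noise_free_data_flagged(self, simple_1cpt):
        """Zero-variance data (eta = eps = 0) has no ML optimum in the
        interior; the fit must not blow up and must not report convergence
        with a sane residual."""
        quiet = replace(simple_1cpt, sigma_prop=1e-9)
        data = [
            simulate_subject(
                quiet, c, [DoseEvent(2000.0, 0.0, 0.0)], [2.0, 10.0, 30.0],
                seed=i, eta=(0.0, 0.0), subject_id=f"Z{i}",
            )
            for i, c in enumerate(sample_covariates(12, seed=31))
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_population(data, structure="1cpt", error="proportional")
        # sigma collapses toward its bound; the result stays finite
        assert np.isfinite(fit.ofv)
        assert fit.params()["sigma_prop"] < 0.05


class TestLrtSelect:
    def test_threshold_inclusive(self):
        a = _fake_fit(ofv=100.0)
        assert lrt_select(a, _fake_fit(ofv=96.16))["significant"] is True
        assert lrt_select(a, _fake_fit(ofv=96.17))["significant"] is False
        assert lrt_select(a, _fake_fit(ofv=100.0)) == {
            "better": "a", "dOFV": 0.0, "significant": False, "df": 1,
        }

    def test_backward_threshold(self):
        a = _fake_fit(ofv=100.0)
        assert lrt_select(a, _fake_fit(ofv=94.0), threshold=6.63)["significant"] is False
        assert lrt_select(a, _fake_fit(ofv=93.0), threshold=6.63)["significant"] is True


def _fake_fit(ofv):
    from fviiipk.nlme import FitResult

    return FitResult(
        model=None, ofv=ofv, ebe=np.zeros((1, 2)), eta_shrinkage=(0, 0),
        eps_shrinkage=0, converged=True, n_blq=0,
    )


class TestStepwise:
    def test_true_covariate_selected_spurious_not(self, simple_1cpt):
        """Data carry a strong FFM effect on CL and no height effect;
        forward/backward selection keeps exactly the real one."""
        gen = replace(
            simple_1cpt,
            effects=(CovariateEffect("CL", "FFM", "power", 0.7, 50.0),),
        )
        data = make_dataset(gen, n=60, times=[2.0, 8.0, 24.0, 48.0], seed=17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = stepwise_covariates(
                data, candidates=[("CL", "FFM"), ("V1", "HT")], structure="1cpt",
            )
        chosen = {(e.parameter, e.covariate) for e in fit.model.effects}
        assert ("CL", "FFM") in chosen
        assert ("V1", "HT") not in chosen
        theta = [e for e in fit.model.effects if e.covariate == "FFM"][0].theta
        assert theta == pytest.approx(0.7, abs=0.25)


class TestShrinkage:
    def test_sparse_data_shrinks_to_prior(self, simple_1cpt):
        """Single-observation subjects leave the EBEs near the prior mean."""
        data = make_dataset(simple_1cpt, n=40, times=[6.0], seed=23)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_population(
                data, structure="1cpt", error="proportional", init=simple_1cpt, maxiter=0,
            )
        d = shrinkage(fit)
        assert d["eta_CL"] > 0.3 or d["eta_V1"] > 0.3
        assert d["overparameterized"] in (True, False)

    def test_all_zero_ebes_give_unit_shrinkage(self, simple_1cpt):
        fit = _fake_fit(0.0)
        fit.model = simple_1cpt
        fit.ebe = np.zeros((10, 2))
        om_sd = np.sqrt(np.diag(simple_1cpt.omega))
        shr = tuple(1.0 - np.std(fit.ebe[:, k], ddof=1) / om_sd[k] for k in range(2))
        assert shr == (1.0, 1.0)


class TestBootstrap:
    def test_zero_runs_rejected(self, small_1cpt_dataset):
        with pytest.raises(ValueError):
            bootstrap(small_1cpt_dataset, n_runs=0)

    def test_stratified_resampling_preserves_strata(self, simple_1cpt, small_1cpt_dataset, monkeypatch):
        seen = []

        def fake_fit(replicate, **kw):
            seen.append(replicate)
            f = _fake_fit(0.0)
            f.model = simple_1cpt
            return f

        import fviiipk.nlme as nlme

        monkeypatch.setattr(nlme, "fit_population", fake_fit)
        res = nlme.bootstrap(small_1cpt_dataset, n_runs=5, strata=(12.0, 18.0), seed=0)
        ages = np.array([r.covariates.age for r in small_1cpt_dataset])
        bins = np.digitize(ages, [12.0, 18.0])
        want = np.bincount(bins, minlength=3)
        for rep in seen:
            got = np.bincount(
                np.digitize([r.covariates.age for r in rep], [12.0, 18.0]), minlength=3
            )
            np.testing.assert_array_equal(got, want)
        assert res.n_runs == 5

    def test_percentile_ci_covers_truth_on_easy_data(self, simple_1cpt):
        data = make_dataset(simple_1cpt, n=30, times=[2.0, 8.0, 24.0], seed=29)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = bootstrap(
                data, n_runs=12, seed=1, structure="1cpt", error="proportional",
                init=simple_1cpt,
            )
        lo, hi = res.ci["CL_pop"]
        assert lo < 0.2 < hi or abs(lo - 0.2) < 0.03 or abs(hi - 0.2) < 0.03
        assert all(l <= h for l, h in res.ci.values())
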