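"""Distribution machinery: likelihoods, MLE fitting, AICc selection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phytossd as p
from phytossd.distributions import anderson_darling

SPEC_STRATEGY = st.sampled_from(p.FAMILIES).flatmap(
    lambda fam: st.tuples(
        st.just(fam),
        st.floats(-1.0, 5.0) if fam == "lognormal" else st.floats(0.3, 8.0),
        st.floats(0.1, 3.0) if fam == "lognormal" else st.floats(5.0, 300.0),
    )
)


def make_spec(family, p1, p2):
    if family == "lognormal":
        return p.DistributionSpec(family, {"meanlog": p1, "sdlog": p2})
    return p.DistributionSpec(family, {"shape": p1, "scale": p2})


class TestLoglik:
    def test_exponential_hand_value(self):
        spec = p.DistributionSpec("gamma", {"shape": 1.0, "scale": 2.0})
        # 3*ln(0.5) - (1+2+3)/2
        assert p.loglik(spec, [1.0, 2.0, 3.0]) == pytest.approx(
            3 * math.log(0.5) - 3.0, abs=1e-12
        )

    @given(SPEC_STRATEGY)
    def test_degenerate_intervals_reproduce_exact_loglik(self, params):
        spec = make_spec(*params)
        x = spec.frozen.ppf([0.2, 0.45, 0.7, 0.9])
        exact = p.loglik(spec, x)
        degenerate = p.loglik(spec, np.c_[x, x])
        assert degenerate == pytest.approx(exact, rel=1e-12)

    def test_zero_probability_interval_is_minus_inf(self):
        spec = p.DistributionSpec("weibull", {"shape": 2.0, "scale": 50.0})
        assert p.loglik(spec, [[1e6, 1e6 + 1.0]]) == -math.inf

    def test_nonpositive_data_rejected(self):
        spec = p.DistributionSpec("gamma", {"shape": 1.0, "scale": 1.0})
        with pytest.raises(ValueError):
            p.loglik(spec, [1.0, -2.0])


class TestExactFits:
    def test_lognormal_closed_form(self):
        fit = p.fit_mle("lognormal", [math.e, math.e**2, math.e**3])
        assert fit.spec.params["meanlog"] == pytest.approx(2.0, abs=1e-12)
        assert fit.spec.params["sdlog"] == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)

    @given(SPEC_STRATEGY, st.integers(0, 2**31 - 1))
    def test_mle_is_a_local_maximum(self, params, seed):
        spec = make_spec(*params)
        x = p.ssd_sample(spec, 60, seed)
        fit = p.fit_mle(spec.family, x)
        if not fit.converged:
            return
        best = fit.loglik
        rng = np.random.default_rng(seed)
        names = sorted(fit.spec.params)
        for _ in range(5):
            perturbed = {
                k: v * float(np.exp(rng.normal(0, 0.05)))
                if k != "meanlog"
                else v + float(rng.normal(0, 0.05))
                for k, v in fit.spec.params.items()
            }
            assert p.loglik(p.DistributionSpec(spec.family, perturbed), x) <= best + 1e-7

    def test_gamma_parameter_recovery(self):
        spec = p.DistributionSpec("gamma", {"shape": 2.0, "scale": 50.0})
        x = p.ssd_sample(spec, 2000, seed=2024)
        fit = p.fit_mle("gamma", x)
        assert fit.spec.params["shape"] == pytest.approx(2.0, rel=0.10)
        assert fit.spec.params["scale"] == pytest.approx(50.0, rel=0.10)

    def test_minimum_observations(self):
        with pytest.raises(ValueError):
            p.fit_mle("gamma", [1.0, 2.0])


class TestCensoredFits:
    @pytest.mark.parametrize("family", p.FAMILIES)
    def test_degenerate_interval_fit_equals_exact_fit(self, family):
        spec = make_spec(family, *((0.5, 0.6) if family == "lognormal" else (2.5, 80.0)))
        x = p.ssd_sample(spec, 40, seed=7)
        exact = p.fit_mle(family, x)
        censored = p.fit_mle(family, np.c_[x, x])
        for name, value in exact.spec.params.items():
            assert censored.spec.params[name] == pytest.approx(value, rel=1e-6, abs=1e-6)

    def test_interval_fit_recovers_generating_distribution(self):
        spec = p.DistributionSpec("lognormal", {"meanlog": 4.5, "sdlog": 0.4})
        x = p.ssd_sample(spec, 500, seed=11)
        intervals = np.c_[x * 0.9, x * 1.1]
        fit = p.fit_mle("lognormal", intervals)
        assert fit.converged
        assert fit.spec.params["meanlog"] == pytest.approx(4.5, abs=0.05)
        assert fit.spec.params["sdlog"] == pytest.approx(0.4, abs=0.05)


class TestModelSelection:
    def test_aicc_identity(self, tephritidae_gamma_fit):
        fit = tephritidae_gamma_fit
        k = 2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, rel=1e-12)
        # with k=2, n=15 the small-sample adjustment is exactly 1
        assert fit.aicc - fit.aic == pytest.approx(1.0, abs=1e-12)

    def test_selection_is_scale_invariant(self):
        spec = p.DistributionSpec("weibull", {"shape": 2.2, "scale": 105.0})
        x = p.ssd_sample(spec, 25, seed=3)
        c = 7.3
        ms1, ms2 = p.fit_all(x), p.fit_all(x * c)
        assert ms1.best.spec.family == ms2.best.spec.family
        # every family's log-likelihood shifts by the same -n*ln(c)
        shift = -len(x) * math.log(c)
        for family in p.FAMILIES:
            assert ms2.fits[family].loglik - ms1.fits[family].loglik == pytest.approx(
                shift, rel=1e-6
            )
        d1 = ms1.fits["gamma"].aicc - ms1.fits["weibull"].aicc
        d2 = ms2.fits["gamma"].aicc - ms2.fits["weibull"].aicc
        assert d1 == pytest.approx(d2, abs=1e-5)

    def test_best_attains_minimum_aicc(self, tephritidae_doses):
        ms = p.fit_all(tephritidae_doses)
        best = ms.best
        assert best.aicc == min(f.aicc for f in ms.fits.values() if f.converged)

    def test_curculionidae_selects_weibull_with_small_differences(
        self, curculionidae_pipeline_report
    ):
        report = curculionidae_pipeline_report
        assert report["selected_family"] == "weibull"
        aiccs = {m["family"]: m["aicc"] for m in report["models"]}
        assert max(aiccs.values()) - min(aiccs.values()) < 5.0


class TestDistributionFunctions:
    def test_lognormal_median(self):
        spec = p.DistributionSpec("lognormal", {"meanlog": 4.0, "sdlog": 0.7})
        assert p.ssd_quantile(spec, 0.5) == pytest.approx(math.exp(4.0), rel=1e-12)

    def test_exponential_quantile_closed_form(self):
        theta = 37.0
        spec = p.DistributionSpec("gamma", {"shape": 1.0, "scale": theta})
        for q in (0.1, 0.5, 0.9, 0.99):
            assert p.ssd_quantile(spec, q) == pytest.approx(
                -theta * math.log1p(-q), rel=1e-12
            )

    @given(SPEC_STRATEGY, st.floats(1e-6, 1 - 1e-6))
    def test_quantile_cdf_round_trip(self, params, q):
        spec = make_spec(*params)
        assert abs(p.ssd_cdf(spec, p.ssd_quantile(spec, q)) - q) < 1e-9

    def test_sampling_reproducible_and_ks_consistent(self):
        spec = p.DistributionSpec("gamma", {"shape": 3.0, "scale": 25.0})
        x1 = p.ssd_sample(spec, 10_000, seed=99)
        x2 = p.ssd_sample(spec, 10_000, seed=99)
        np.testing.assert_array_equal(x1, x2)
        from scipy import stats

        ks = stats.kstest(x1, spec.frozen.cdf)
        assert ks.pvalue > 0.001

    def test_invalid_p_rejected(self):
        spec = p.DistributionSpec("gamma", {"shape": 1.0, "scale": 1.0})
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                p.ssd_quantile(spec, bad)


class TestParametricSSDEstimator:
    def test_sklearn_contract(self, tephritidae_doses):
        from sklearn.base import clone

        ssd = p.ParametricSSD(family="gamma")
        assert ssd.get_params() == {"family": "gamma"}
        clone(ssd)  # must be clonable pre-fit
        ssd.fit(tephritidae_doses)
        assert ssd.family_ == "gamma"
        assert ssd.aicc_ == pytest.approx(ssd.result_.aicc)
        assert 0.0 < ssd.cdf(150.0) < 1.0
        assert ssd.quantile(0.95) > ssd.quantile(0.90)

    def test_auto_selection_matches_fit_all(self, tephritidae_doses):
        ssd = p.ParametricSSD().fit(tephritidae_doses)
        assert ssd.family_ == p.fit_all(tephritidae_doses).best.spec.family

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            p.ParametricSSD().cdf(10.0)


def test_anderson_darling_diagnostic_is_finite_and_small_for_true_model():
    spec = p.DistributionSpec("weibull", {"shape": 2.0, "scale": 100.0})
    x = p.ssd_sample(spec, 200, seed=5)
    ad_true = anderson_darling(spec, x)
    wrong = p.DistributionSpec("weibull", {"shape": 0.5, "scale": 10.0})
    assert 0 < ad_true < anderson_darling(wrong, x)
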