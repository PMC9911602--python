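"""Cox-Snell small-sample correction of the gamma MLE."""

import numpy as np
import pytest
from scipy import special

import phytossd as p
from phytossd.bias_correction import _coxsnell_from_cumulants, _gamma_cumulants


def gamma_mle_rows(X):
    """Row-wise gamma MLE, independent of the package implementation."""
    m = X.mean(axis=1)
    s = np.log(m) - np.log(X).mean(axis=1)
    a = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    for _ in range(80):
        a = a - (np.log(a) - special.digamma(a) - s) / (
            1 / a - special.polygamma(1, a)
        )
    return a, m / a


class TestBiasFormula:
    def test_closed_form_equals_generic_cumulant_machinery(self):
        for a, s, n in [(3.59, 18.56, 15), (1.2, 200.0, 8), (7.0, 3.0, 40)]:
            closed = p.coxsnell_bias_gamma(a, s, n)
            generic = _coxsnell_from_cumulants(*_gamma_cumulants(a, s, n))
            assert closed["shape"] == pytest.approx(generic[0], rel=1e-10)
            assert closed["scale"] == pytest.approx(generic[1], rel=1e-10)

    def test_bias_decays_like_one_over_n(self):
        b15 = p.coxsnell_bias_gamma(3.0, 30.0, 15)
        b150 = p.coxsnell_bias_gamma(3.0, 30.0, 150)
        assert b150["shape"] == pytest.approx(b15["shape"] / 10, rel=1e-12)
        assert b150["scale"] == pytest.approx(b15["scale"] / 10, rel=1e-12)

    def test_scale_equivariance(self):
        b = p.coxsnell_bias_gamma(2.5, 40.0, 20)
        bc = p.coxsnell_bias_gamma(2.5, 40.0 * 7.0, 20)
        assert bc["shape"] == pytest.approx(b["shape"], rel=1e-12)
        assert bc["scale"] == pytest.approx(b["scale"] * 7.0, rel=1e-12)

    def test_matches_parametric_bootstrap_bias_oracle_at_n15(self):
        """First-order bias vs the empirical MLE bias over 2,000 replicates.

        The scale component agrees within Monte-Carlo error; the shape
        component carries a visible O(1/n^2) remainder at n = 15, so its
        check allows that second-order term on top of the MC band.
        """
        truth_a, truth_s, n = 3.0, 30.0, 15
        rng = np.random.default_rng(2718)
        X = rng.gamma(truth_a, truth_s, size=(2000, n))
        a_hat, s_hat = gamma_mle_rows(X)
        analytic = p.coxsnell_bias_gamma(truth_a, truth_s, n)
        se_a = a_hat.std() / np.sqrt(len(a_hat))
        se_s = s_hat.std() / np.sqrt(len(s_hat))
        emp_a = a_hat.mean() - truth_a
        emp_s = s_hat.mean() - truth_s
        assert emp_s == pytest.approx(analytic["scale"], abs=3 * se_s)
        assert emp_a == pytest.approx(
            analytic["shape"], abs=3 * se_a + 0.3 * abs(analytic["shape"])
        )

    def test_matches_bootstrap_bias_oracle_tightly_at_n150(self):
        truth_a, truth_s, n = 3.0, 30.0, 150
        rng = np.random.default_rng(314)
        X = rng.gamma(truth_a, truth_s, size=(40_000, n))
        a_hat, s_hat = gamma_mle_rows(X)
        analytic = p.coxsnell_bias_gamma(truth_a, truth_s, n)
        se_a = a_hat.std() / np.sqrt(len(a_hat))
        se_s = s_hat.std() / np.sqrt(len(s_hat))
        # 3-sigma MC band plus a small second-order allowance
        assert a_hat.mean() - truth_a == pytest.approx(
            analytic["shape"], abs=3 * se_a + 0.003
        )
        assert s_hat.mean() - truth_s == pytest.approx(
            analytic["scale"], abs=3 * se_s + 0.03
        )


class TestCorrection:
    def test_asymptotic_vanishing(self):
        spec = p.DistributionSpec("gamma", {"shape": 3.0, "scale": 30.0})
        fit = p.fit_mle("gamma", p.ssd_sample(spec, 1_000_000, seed=1))
        corrected = p.coxsnell_correct_gamma(fit)
        for name in ("shape", "scale"):
            assert corrected.corrected_params[name] == pytest.approx(
                fit.spec.params[name], rel=1e-4
            )

    def test_correction_reduces_absolute_bias_in_paired_simulation(self):
        truth_a, truth_s, n = 3.0, 30.0, 15
        rng = np.random.default_rng(99)
        X = rng.gamma(truth_a, truth_s, size=(800, n))
        a_hat, s_hat = gamma_mle_rows(X)
        bias = [p.coxsnell_bias_gamma(a, s, n) for a, s in zip(a_hat, s_hat)]
        a_corr = a_hat - np.array([b["shape"] for b in bias])
        s_corr = s_hat - np.array([b["scale"] for b in bias])
        assert abs(a_corr.mean() - truth_a) < abs(a_hat.mean() - truth_a)
        assert abs(s_corr.mean() - truth_s) < abs(s_hat.mean() - truth_s)

    def test_requires_converged_gamma(self, tephritidae_gamma_fit):
        wfit = p.fit_mle("weibull", [30.0, 60.0, 90.0, 120.0])
        with pytest.raises(ValueError, match="gamma"):
            p.coxsnell_correct_gamma(wfit)

    def test_shift_table_matches_quantile_definitions(self, tephritidae_gamma_fit):
        corrected = p.coxsnell_correct_gamma(tephritidae_gamma_fit)
        shifts = p.corrected_shift(corrected, p_list=(0.9, 0.99), dose_list=(150.0,))
        for prob in (0.9, 0.99):
            expected = p.ssd_quantile(
                tephritidae_gamma_fit.spec, prob
            ) - p.ssd_quantile(corrected.corrected_spec, prob)
            assert shifts["gd_drop_gy"][prob] == pytest.approx(expected, abs=1e-9)
        gain = 100 * (
            p.ssd_cdf(corrected.corrected_spec, 150.0)
            - p.ssd_cdf(tephritidae_gamma_fit.spec, 150.0)
        )
        assert shifts["coverage_gain_pp"][150.0] == pytest.approx(gain, abs=1e-9)

    def test_identical_params_give_zero_shift(self, tephritidae_gamma_fit):
        fake = p.BiasCorrectedFit(
            original=tephritidae_gamma_fit,
            corrected_spec=tephritidae_gamma_fit.spec,
            bias={"shape": 0.0, "scale": 0.0},
            n_obs=tephritidae_gamma_fit.n_obs,
        )
        shifts = p.corrected_shift(fake)
        assert all(v == 0.0 for v in shifts["gd_drop_gy"].values())
        assert all(v == 0.0 for v in shifts["coverage_gain_pp"].values())
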