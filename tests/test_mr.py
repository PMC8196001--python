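import math

import numpy as np
import pytest
from scipy import stats as sps

from bilicausal import mr
from bilicausal.simdata import _solve_intercept


def _iv_data(rng, n, r2=0.1, log_or=0.0, prevalence=0.3, eaf=0.49,
             confound=0.0):
    """Minimal instrument -> exposure -> binary outcome generator."""
    z = rng.binomial(2, eaf, n).astype(float)
    zs = (z - z.mean()) / z.std()
    u = rng.standard_normal(n)
    x = math.sqrt(r2) * zs + confound * u + math.sqrt(max(1 - r2 - confound**2, 0)) \
        * rng.standard_normal(n)
    eta = log_or * (x / x.std()) + confound * u
    a = _solve_intercept(eta, prevalence)
    y = (rng.random(n) < 1 / (1 + np.exp(-(a + eta)))).astype(float)
    return z, x, y


class TestFirstStage:
    def test_null_f_has_mean_one(self, rng):
        fs = []
        for _ in range(200):
            z = rng.binomial(2, 0.4, 200).astype(float)
            x = rng.standard_normal(200)
            _, f, _ = mr.first_stage(x, z)
            fs.append(f)
        assert abs(np.mean(fs) - 1.0) < 0.3

    def test_f_r2_identity_no_covariates(self, rng):
        z = rng.binomial(2, 0.3, 500).astype(float)
        x = 0.2 * z + rng.standard_normal(500)
        _, f, r2 = mr.first_stage(x, z)
        assert f == pytest.approx((500 - 2) * r2 / (1 - r2), rel=1e-10)

    def test_strong_instrument_always_passes_f10(self, rng):
        for _ in range(100):
            z, x, _ = _iv_data(rng, 1900, r2=0.12)
            _, f, _ = mr.first_stage(x, z)
            assert f > 10

    def test_constant_instrument_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            mr.first_stage(rng.standard_normal(50), np.ones(50))


class TestSecondStage:
    def test_constant_fitted_exposure_rejected(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        with pytest.raises(ValueError, match="constant"):
            mr.second_stage(y, np.full(100, 1.3))

    def test_wald_ratio_identity_linear(self, rng):
        z = rng.binomial(2, 0.4, 400).astype(float)
        x = 0.5 * z + rng.standard_normal(400)
        y_cont = -0.7 * x + rng.standard_normal(400)
        x_hat, _, _ = mr.first_stage(x, z)
        beta = mr.second_stage_linear(y_cont, x_hat)
        bzy = np.polyfit(z, y_cont, 1)[0]
        bzx = np.polyfit(z, x, 1)[0]
        assert beta == pytest.approx(bzy / bzx, abs=1e-10)

    def test_type_one_error_calibrated(self, rng):
        rej = 0
        reps = 500
        for _ in range(reps):
            z, x, y = _iv_data(rng, 500, r2=0.15, log_or=0.0)
            x_hat, _, _ = mr.first_stage(x, z)
            _, _, _, p, _ = mr.second_stage(y, x_hat)
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.08


class TestExclusionCheck:
    def test_pleiotropy_detected(self, rng):
        detected = 0
        for _ in range(100):
            z, x, _ = _iv_data(rng, 3000, r2=0.12)
            # direct Z -> Y path of log-OR 0.5 per allele on top of the X path
            eta = -0.7 * (x / x.std()) + 0.5 * (z - z.mean())
            a = _solve_intercept(eta, 0.3)
            y = (rng.random(3000) < 1 / (1 + np.exp(-(a + eta)))).astype(float)
            _, ci, _ = mr.exclusion_check(y, z, x)
            detected += not (ci[0] <= 1.0 <= ci[1])
        assert detected >= 80

    def test_irrelevant_instrument_null_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            z = rng.binomial(2, 0.4, 300).astype(float)
            x = rng.standard_normal(300)
            y = (rng.random(300) < 0.3).astype(float)
            _, _, p = mr.exclusion_check(y, z, x)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestIvwMeta:
    def test_single_study_unchanged(self):
        res = mr.ivw_meta([-0.4], [0.2])
        assert res.beta == pytest.approx(-0.4)
        assert res.se == pytest.approx(0.2)
        assert res.q == pytest.approx(0.0)

    def test_two_equal_studies(self):
        res = mr.ivw_meta([-0.4, -0.4], [0.2, 0.2])
        assert res.beta == pytest.approx(-0.4, abs=1e-12)
        assert res.se == pytest.approx(0.2 / math.sqrt(2), rel=1e-12)

    def test_hand_computed_combination(self):
        res = mr.ivw_meta([-1.0, -0.5], [0.5, 0.5])
        assert res.beta == pytest.approx(-0.75, abs=1e-12)
        assert res.se == pytest.approx(0.5 / math.sqrt(2), abs=1e-4)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_convex_hull_property(self, rng):
        for _ in range(20):
            betas = rng.standard_normal(4)
            ses = rng.uniform(0.1, 1.0, 4)
            res = mr.ivw_meta(betas, ses)
            assert betas.min() - 1e-12 <= res.beta <= betas.max() + 1e-12


class TestPower:
    def test_no_instrument_limit_is_alpha(self):
        p = mr.PowerParams(n=1000, alpha=0.05, prevalence=0.3, or_per_sd=0.5, r2=0.0)
        assert mr.mr_power_binary(p) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_n_r2_and_effect(self):
        base = dict(alpha=0.05, prevalence=0.26, or_per_sd=0.7, r2=0.05)
        pw = [mr.mr_power_binary(mr.PowerParams(n=n, **base))
              for n in (200, 500, 1500, 4000)]
        assert all(np.diff(pw) > 0)
        pw = [mr.mr_power_binary(mr.PowerParams(n=800, alpha=0.05, prevalence=0.26,
                                                or_per_sd=0.7, r2=r))
              for r in (0.01, 0.05, 0.1, 0.2)]
        assert all(np.diff(pw) > 0)
        pw = [mr.mr_power_binary(mr.PowerParams(n=800, alpha=0.05, prevalence=0.26,
                                                or_per_sd=o, r2=0.05))
              for o in (0.9, 0.7, 0.5, 0.3)]
        assert all(np.diff(pw) > 0)

    def test_agrees_with_simulation_oracle(self):
        """Analytic power within 0.03 of a 2000-replicate simulation."""
        params = mr.PowerParams(n=500, alpha=0.05, prevalence=0.26,
                                or_per_sd=0.6, r2=0.05)
        analytic = mr.mr_power_binary(params)
        rng = np.random.default_rng(2024)
        rej = 0
        reps = 2000
        for _ in range(reps):
            z, x, y = _iv_data(rng, 500, r2=0.05, log_or=math.log(0.6),
                               prevalence=0.26)
            x_hat, _, _ = mr.first_stage(x, z)
            _, _, _, p, _ = mr.second_stage(y, x_hat)
            rej += p < 0.05
        assert abs(analytic - rej / reps) <= 0.03

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mr.mr_power_binary(mr.PowerParams(n=100, alpha=0.05, prevalence=1.2,
                                              or_per_sd=0.5, r2=0.1))


def test_mr_study_bootstrap_se_close_to_naive(rng):
    z, x, y = _iv_data(rng, 1200, r2=0.12, log_or=-0.7, prevalence=0.3)
    res = mr.mr_study(x, z, y, n_boot=60, seed=8)
    assert res.f_stat > 10
    assert np.isfinite(res.se_boot)
    assert 0.5 < res.se_boot / res.se < 2.0
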