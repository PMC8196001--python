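import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from bilicausal import simdata


class TestSimulateGenotypes:
    def test_bit_identical_reproducibility(self):
        cfg = simdata.SimConfig(n_samples=100, n_variants=200, causal_index=100, seed=77)
        a = simdata.simulate_cohort(cfg)
        b = simdata.simulate_cohort(cfg)
        assert np.array_equal(a.genotypes.dosage, b.genotypes.dosage)
        assert a.phenotypes.df.equals(b.phenotypes.df)

    @pytest.mark.parametrize("field,value", [
        ("causal_eaf", 1.5), ("within_block_rho", 1.0), ("fst", -0.1),
        ("causal_index", 999), ("outcome_prevalence", 0.0),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = simdata.SimConfig(n_samples=50, n_variants=100, causal_index=50)
        setattr(cfg, field, value)
        with pytest.raises(ValueError, match=field.split("_")[0]):
            cfg.validate()

    def test_budget_violation_rejected(self):
        cfg = simdata.SimConfig(target_iv_r2=0.5, polygenic_h2=0.6)
        with pytest.raises(ValueError, match="polygenic_h2"):
            cfg.validate()

    def test_independence_case(self, plain_genotypes):
        # fst=0, no sibs, rho=0: pairwise genotype correlations ~ 0
        dos = plain_genotypes.dosage
        n = dos.shape[0]
        rng = np.random.default_rng(0)
        pairs = rng.choice(dos.shape[1], size=(200, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        rs = [np.corrcoef(dos[:, i], dos[:, j])[0, 1] for i, j in pairs]
        assert np.mean(np.abs(rs) < 3 / math.sqrt(n)) > 0.95

    def test_realized_eaf_near_target(self):
        cfg = simdata.SimConfig(n_samples=5000, n_variants=40, causal_index=20,
                                causal_eaf=0.49, seed=101)
        g = simdata.simulate_genotypes(cfg)
        eaf = g.dosage[:, 20].mean() / 2
        assert abs(eaf - 0.49) < 0.02

    def test_structure_visible_on_leading_pc(self):
        cfg = simdata.SimConfig(n_samples=500, n_variants=1000, causal_index=500,
                                n_subpops=2, fst=0.1, n_sib_pairs=0,
                                within_block_rho=0.0, seed=13)
        g = simdata.simulate_genotypes(cfg)
        dos = g.dosage
        z = (dos - dos.mean(0)) / np.maximum(dos.std(0), 1e-12)
        # PCA oracle: leading left singular vector of standardized genotypes
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        pc1 = u[:, 0]
        labels = g.subpop
        r = np.corrcoef(pc1, labels)[0, 1]
        assert abs(r) > 0.9

    def test_ld_blocks_have_correlation(self, small_cohort):
        dos = small_cohort.genotypes.dosage
        bs = small_cohort.config.ld_block_size
        within = [np.corrcoef(dos[:, i], dos[:, i + 1])[0, 1] ** 2
                  for i in range(0, 10 * bs, bs)]
        across = [np.corrcoef(dos[:, i], dos[:, i + bs])[0, 1] ** 2
                  for i in range(0, 10 * bs, bs)]
        # copula thresholding attenuates the latent correlation (phi < rho),
        # so within-block genotype r^2 is moderate but clearly above background
        assert np.mean(within) > 0.04
        assert np.mean(within) > 5 * np.mean(across)

    def test_sib_pairs_are_related(self):
        cfg = simdata.SimConfig(n_samples=300, n_variants=800, causal_index=400,
                                n_sib_pairs=40, fst=0.0, n_subpops=1, seed=21)
        g = simdata.simulate_genotypes(cfg)
        from bilicausal.assoc import kinship
        k = kinship(g).matrix
        sib = np.mean([k[2 * i, 2 * i + 1] for i in range(40)])
        unrel = np.mean([k[i, j] for i in range(100, 150) for j in range(i + 1, 150)])
        assert sib > 0.25
        assert abs(unrel) < 0.05


class TestSimulatePhenotypes:
    def test_null_odds_ratio_coverage(self):
        # no exposure effect, no confounder: CI for OR per SD of X covers 1
        covered = 0
        for s in range(30):
            cfg = simdata.SimConfig(
                n_samples=1000, n_variants=30, causal_index=15,
                log_or_per_sd=0.0, confounder_on_x=0.0, confounder_on_y=0.0,
                seed=1000 + s)
            co = simdata.simulate_cohort(cfg)
            x = co.phenotypes.components["x_std"]
            y = co.phenotypes.df["hypertension"].to_numpy(float)
            fit = sm.Logit(y, sm.add_constant(x / x.std())).fit(disp=0)
            lo, hi = fit.conf_int()[1]
            covered += lo <= 0.0 <= hi
        assert covered >= 26

    def test_iv_r2_recovered_by_regression(self):
        cfg = simdata.SimConfig(n_samples=3000, n_variants=50, causal_index=25,
                                target_iv_r2=0.12, seed=5)
        co = simdata.simulate_cohort(cfg)
        z = co.genotypes.dosage[:, 25]
        x = co.phenotypes.components["x_std"]
        r2 = sm.OLS(x, sm.add_constant(z)).fit().rsquared
        assert 0.09 <= r2 <= 0.15

    def test_prevalence_recount(self):
        cfg = simdata.SimConfig(n_samples=3000, n_variants=50, causal_index=25,
                                outcome_prevalence=0.26, seed=6)
        co = simdata.simulate_cohort(cfg)
        prev = co.phenotypes.df["hypertension"].mean()
        assert 0.23 <= prev <= 0.29
        assert co.truth["realized_prevalence"] == prev  # definitional identity

    def test_null_effects_give_zero_realized_r2(self):
        cfg = simdata.SimConfig(n_samples=500, n_variants=50, causal_index=25,
                                target_iv_r2=0.0, polygenic_h2=0.0, seed=7)
        co = simdata.simulate_cohort(cfg)
        assert co.truth["realized_iv_r2"] == pytest.approx(0.0, abs=1e-12)
        assert co.truth["realized_h2"] == pytest.approx(0.0, abs=1e-12)

    def test_realized_h2_near_total_target(self):
        cfg = simdata.SimConfig(n_samples=2000, n_variants=2000, causal_index=1000,
                                seed=8)
        co = simdata.simulate_cohort(cfg)
        assert abs(co.truth["realized_h2"] - 0.385) < 0.05

    def test_confounding_biases_naive_regression(self):
        # positive U loadings on X and Y push the naive estimate upward
        biases = []
        for s in range(25):
            cfg = simdata.SimConfig(n_samples=800, n_variants=30, causal_index=15,
                                    seed=3000 + s)
            co = simdata.simulate_cohort(cfg)
            x = co.phenotypes.components["x_std"]
            y = co.phenotypes.df["hypertension"].to_numpy(float)
            fit = sm.Logit(y, sm.add_constant(x / x.std())).fit(disp=0)
            biases.append(fit.params[1] - cfg.log_or_per_sd)
        t = np.mean(biases) / (np.std(biases, ddof=1) / math.sqrt(len(biases)))
        assert np.mean(biases) > 0 and t > 3  # clearly biased toward the null

    def test_intercept_solver_hits_target_in_expectation(self):
        cfg = simdata.SimConfig(n_samples=4000, n_variants=30, causal_index=15, seed=9)
        co = simdata.simulate_cohort(cfg)
        assert co.truth["expected_prevalence"] == pytest.approx(0.26, abs=1e-3)


def test_null_association_pvalues_uniform():
    """With all effects zero the marginal association p-values are uniform."""
    cfg = simdata.SimConfig(
        n_samples=500, n_variants=5000, causal_index=2500,
        target_iv_r2=0.0, polygenic_h2=0.0, confounder_on_x=0.0,
        sex_effect_x=0.0, age_effect_x=0.0, bmi_effect_x=0.0,
        fst=0.0, n_subpops=1, n_sib_pairs=0, within_block_rho=0.0, seed=99)
    co = simdata.simulate_cohort(cfg)
    x = co.phenotypes.components["x_std"]
    dos = co.genotypes.dosage
    z = (dos - dos.mean(0)) / np.maximum(dos.std(0), 1e-12)
    n = len(x)
    xc = (x - x.mean()) / x.std()
    r = z.T @ xc / n
    tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-12))
    pvals = 2 * stats.t.sf(np.abs(tstat), n - 2)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
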