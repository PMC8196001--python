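import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from bilicausal import assoc, simdata


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        y = rng.standard_normal(50)
        r = assoc.residualize(y, np.ones((50, 1)))
        assert np.allclose(r, y - y.mean())

    def test_exact_linear_gives_zero(self, rng):
        c = np.column_stack([np.ones(40), rng.standard_normal(40)])
        y = c @ np.array([2.0, -1.5])
        assert np.allclose(assoc.residualize(y, c), 0.0, atol=1e-10)

    def test_orthogonality(self, rng):
        n = 200
        c = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = rng.standard_normal(n)
        r = assoc.residualize(y, c)
        assert np.max(np.abs(r @ c)) < 1e-8 * n

    def test_rank_deficient_rejected(self, rng):
        x = rng.standard_normal(30)
        c = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            assoc.residualize(rng.standard_normal(30), c)


class TestRankInverseNormal:
    def test_n3_blom_values(self):
        out = assoc.rank_inverse_normal(np.array([10.0, -3.0, 5.0]))
        expected = stats.norm.ppf(np.array([21, 5, 13]) / 26.0)
        assert np.allclose(np.sort(out), np.sort(expected), atol=1e-12)

    def test_middle_of_odd_sample_is_zero(self):
        out = assoc.rank_inverse_normal(np.arange(7.0))
        assert out[3] == pytest.approx(0.0, abs=1e-12)

    def test_moments_near_standard_normal(self, rng):
        out = assoc.rank_inverse_normal(rng.exponential(size=2000))
        assert abs(out.mean()) < 1e-3
        assert abs(out.var() - 1.0) < 0.02

    def test_ties_get_average_rank(self):
        out = assoc.rank_inverse_normal(np.array([1.0, 1.0, 5.0, 9.0]))
        assert out[0] == out[1]

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            assoc.rank_inverse_normal(np.ones(10))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_strictly_monotone_on_distinct_values(self, values):
        arr = np.array(values)
        out = assoc.rank_inverse_normal(arr)
        order = np.argsort(arr)
        assert np.all(np.diff(out[order]) > 0)


class TestKinship:
    def test_duplicate_samples_match_diagonal(self, plain_genotypes):
        from bilicausal.genio import GenotypeMatrix
        g = plain_genotypes
        dos = g.dosage.copy()
        dos[1] = dos[0]
        g2 = GenotypeMatrix(g.samples, g.variants, dos)
        k = assoc.kinship(g2).matrix
        assert k[0, 1] == pytest.approx(k[0, 0], rel=1e-9)

    def test_offdiagonal_scale_and_diag_mean(self, plain_genotypes):
        k = assoc.kinship(plain_genotypes)
        k.validate()
        m = plain_genotypes.n_variants
        off = k.matrix[np.triu_indices_from(k.matrix, k=1)]
        assert abs(np.std(off) - 1 / math.sqrt(m)) < 0.3 / math.sqrt(m)
        assert abs(np.mean(np.diag(k.matrix)) - 1.0) < 0.05

    def test_monomorphic_only_rejected(self):
        from bilicausal.genio import GenotypeMatrix
        import pandas as pd
        dos = np.zeros((20, 3))
        variants = pd.DataFrame({"chrom": "1", "pos": [1, 2, 3], "id": list("abc"),
                                 "ref": "A", "alt": "G", "eaf": 0.0, "info": np.nan})
        g = GenotypeMatrix([f"S{i}" for i in range(20)], variants, dos)
        with pytest.raises(ValueError):
            assoc.kinship(g)


class TestTracyWidom:
    def test_null_rarely_significant(self):
        hits = 0
        for s in range(100):
            cfg = simdata.SimConfig(n_samples=150, n_variants=600, causal_index=300,
                                    fst=0.0, n_subpops=1, n_sib_pairs=0,
                                    within_block_rho=0.0, seed=4000 + s)
            g = simdata.simulate_genotypes(cfg)
            _, k = assoc.significant_pcs(g, alpha=0.05)
            hits += k > 0
        assert hits <= 10  # k = 0 in at least 90/100 homogeneous cohorts

    def test_structure_always_detected(self):
        for s in range(5):
            cfg = simdata.SimConfig(n_samples=500, n_variants=2000, causal_index=1000,
                                    n_subpops=2, fst=0.1, n_sib_pairs=0,
                                    within_block_rho=0.0, seed=4200 + s)
            g = simdata.simulate_genotypes(cfg)
            pcs, k = assoc.significant_pcs(g, alpha=0.05)
            assert k >= 1
            # returned PCs are mutually orthogonal
            gram = pcs.T @ pcs
            assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)


class TestLmmAssoc:
    def test_identity_kinship_equals_ols(self, plain_genotypes, rng):
        g = plain_genotypes.subset_variants(np.arange(40))
        n = g.n_samples
        y = rng.standard_normal(n)
        c = np.column_stack([np.ones(n), rng.standard_normal(n)])
        k = assoc.KinshipMatrix(np.eye(n), list(g.samples))
        res = assoc.lmm_assoc(g, y, c, k)
        for j in range(g.n_variants):
            fit = sm.OLS(y, np.column_stack([c, g.dosage[:, j]])).fit()
            assert res.df["beta"].iloc[j] == pytest.approx(fit.params[-1], rel=1e-6)
            assert res.df["se"].iloc[j] == pytest.approx(fit.bse[-1], rel=1e-6)
            assert res.df["p"].iloc[j] == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_missing_intercept_rejected(self, plain_genotypes, rng):
        n = plain_genotypes.n_samples
        k = assoc.KinshipMatrix(np.eye(n), list(plain_genotypes.samples))
        with pytest.raises(ValueError, match="intercept"):
            assoc.lmm_assoc(plain_genotypes, rng.standard_normal(n),
                            rng.standard_normal((n, 2)), k)

    def test_recovers_injected_effect(self):
        cfg = simdata.SimConfig(
            n_samples=2000, n_variants=300, causal_index=150,
            target_iv_r2=None, exposure_effect=0.59, polygenic_h2=0.0, seed=55)
        co = simdata.simulate_cohort(cfg)
        g = co.genotypes
        x = co.phenotypes.components["x_std"]
        k = assoc.kinship(g)
        c = np.ones((2000, 1))
        res = assoc.lmm_assoc(g, x, c, k)
        row = res.df[res.df["id"] == "rs_causal"].iloc[0]
        assert abs(row["beta"] - 0.59) < 3 * row["se"]


class TestGenomicControl:
    def test_uniform_quantiles_give_unity(self):
        p = (np.arange(1, 10001) - 0.5) / 10000
        assert assoc.genomic_control(p) == pytest.approx(1.0, abs=1e-3)

    def test_halved_pvalues_inflate(self):
        p = (np.arange(1, 10001) - 0.5) / 10000
        assert assoc.genomic_control(p / 2) > 1.0

    def test_minimum_count_enforced(self):
        with pytest.raises(ValueError):
            assoc.genomic_control(np.full(50, 0.5))


class TestConditionalScan:
    def _cohort(self, seed):
        cfg = simdata.SimConfig(n_samples=800, n_variants=300, causal_index=150,
                                polygenic_h2=0.0, seed=seed)
        return simdata.simulate_cohort(cfg)

    def test_conditioning_removes_signal(self):
        cleared = 0
        for s in range(10):
            co = self._cohort(6000 + s)
            g = co.genotypes
            y = assoc.prepare_trait(co.phenotypes.df)
            k = assoc.kinship(g)
            c = np.ones((g.n_samples, 1))
            res = assoc.conditional_scan(g, y, c, k, condition_on="rs_causal")
            assert "rs_causal" not in set(res.df["id"])
            cleared += (res.df["p"].dropna() >= assoc.GENOME_WIDE_P).all()
        assert cleared >= 9

    def test_orthogonal_conditioner_leaves_beta_unchanged(self, plain_genotypes, rng):
        g = plain_genotypes.subset_variants(np.arange(20))
        n = g.n_samples
        y = rng.standard_normal(n)
        k = assoc.KinshipMatrix(np.eye(n), list(g.samples))
        c = np.ones((n, 1))
        base = assoc.lmm_assoc(g, y, c, k)
        # conditioner exactly orthogonal to the tested variant and intercept
        target = g.dosage[:, 3] - g.dosage[:, 3].mean()
        w = rng.standard_normal(n)
        w -= w.mean()
        w -= (w @ target) / (target @ target) * target
        # make it orthogonal to y's residual direction too? not needed for beta_j
        g.dosage[:, 10] = w - w.min()  # keep dosage-like positivity
        g.variants.loc[10, "id"] = "ortho"
        g.variants.loc[10, "eaf"] = g.dosage[:, 10].mean() / 2
        res = assoc.conditional_scan(g, y, c, k, condition_on="ortho")
        b0 = base.df.loc[base.df["id"] == g.variants["id"].iloc[3], "beta"].iloc[0]
        b1 = res.df.loc[res.df["id"] == g.variants["id"].iloc[3], "beta"].iloc[0]
        assert b1 == pytest.approx(b0, abs=1e-6)

    def test_perfect_proxy_flagged(self, plain_genotypes, rng):
        g = plain_genotypes.subset_variants(np.arange(10))
        g.dosage[:, 5] = g.dosage[:, 2]
        g.variants.loc[5, "id"] = "proxy"
        g.variants.loc[5, "eaf"] = g.variants["eaf"].iloc[2]
        n = g.n_samples
        k = assoc.KinshipMatrix(np.eye(n), list(g.samples))
        res = assoc.conditional_scan(g, rng.standard_normal(n), np.ones((n, 1)), k,
                                     condition_on=g.variants["id"].iloc[2])
        row = res.df[res.df["id"] == "proxy"].iloc[0]
        assert row["collinear"]
        assert np.isnan(row["beta"])

    def test_monomorphic_conditioner_rejected(self, plain_genotypes, rng):
        g = plain_genotypes.subset_variants(np.arange(10))
        g.dosage[:, 4] = 1.0
        g.variants.loc[4, "id"] = "mono"
        n = g.n_samples
        k = assoc.KinshipMatrix(np.eye(n), list(g.samples))
        with pytest.raises(ValueError, match="monomorphic"):
            assoc.conditional_scan(g, rng.standard_normal(n), np.ones((n, 1)), k,
                                   condition_on="mono")
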