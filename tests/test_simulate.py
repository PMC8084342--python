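"""Synthetic genotypes, paired studies, and coefficient-level generators."""

import warnings

import numpy as np
import pytest
from scipy import stats

from mrslope import (marginal_sumstats, simulate_correlated_instruments,
                     simulate_from_slope_model, simulate_genotypes,
                     simulate_study, true_alpha)


class TestSimulateGenotypes:
    def test_independent_when_rho_zero(self):
        panel = simulate_genotypes(400, 30, ld_spec={"rho": 0.0}, seed=1)
        r = panel.ld_matrix().r
        off = r[np.triu_indices(30, 1)]
        assert np.mean(np.abs(off)) < 3 / np.sqrt(400)

    def test_same_seed_identical(self):
        p1 = simulate_genotypes(100, 20, seed=7)
        p2 = simulate_genotypes(100, 20, seed=7)
        assert np.array_equal(p1.Z, p2.Z)
        assert p1.meta.equals(p2.meta)

    def test_columns_standardized(self):
        panel = simulate_genotypes(300, 25, seed=3)
        assert np.abs(panel.Z.mean(axis=0)).max() < 1e-8
        assert np.abs(panel.Z.var(axis=0) - 1).max() < 1e-8

    def test_adjacent_correlation_matches_monte_carlo_oracle(self):
        """The thresholded-haplotype construction's adjacent-SNP dosage
        correlation agrees with a large direct Monte-Carlo of the same
        two-SNP thresholding."""
        rho, maf = 0.9, 0.3
        panel = simulate_genotypes(5000, 2, ld_spec={"rho": rho,
                                                     "maf_range": (maf, maf)},
                                   seed=5)
        r_panel = panel.ld_matrix().r[0, 1]
        rng = np.random.default_rng(99)
        n = 1_000_000
        q = stats.norm.ppf(maf)
        dos = np.zeros((2, n))
        for _ in range(2):
            x1 = rng.standard_normal(n)
            x2 = rho * x1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            dos[0] += x1 < q
            dos[1] += x2 < q
        r_mc = np.corrcoef(dos)[0, 1]
        assert r_panel == pytest.approx(r_mc, abs=0.02)


class TestMarginalSumstats:
    def test_phenotype_equal_to_column_gives_unit_beta(self):
        panel = simulate_genotypes(200, 10, seed=2)
        y = panel.Z[:, 4] / panel.Z[:, 4].std()
        ss = marginal_sumstats(panel, y)
        assert ss.table["beta"].iloc[4] == pytest.approx(1.0, abs=1e-6)
        assert ss.table["pvalue"].iloc[4] > 0  # representable, not underflowed

    def test_null_pvalues_uniform(self):
        panel = simulate_genotypes(300, 500, ld_spec={"rho": 0.0}, seed=8)
        rng = np.random.default_rng(9)
        y = rng.standard_normal(300)
        y = (y - y.mean()) / y.std()
        ss = marginal_sumstats(panel, y)
        ks = stats.kstest(ss.table["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_beta_equals_correlation_identity(self):
        panel = simulate_genotypes(150, 5, seed=4)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(150)
        y = (y - y.mean()) / y.std(ddof=0)
        ss = marginal_sumstats(panel, y)
        for k in range(5):
            z = panel.Z[:, k]
            expected = np.corrcoef(z, y)[0, 1] * y.std(ddof=0) / z.std(ddof=0)
            assert ss.table["beta"].iloc[k] == pytest.approx(expected, abs=1e-10)


class TestSimulateStudy:
    def _panels(self, seed, n_ind=400, n_snp=120):
        pe = simulate_genotypes(n_ind, n_snp, seed=seed)
        pg = simulate_genotypes(n_ind, n_snp, seed=seed + 1)
        return pe, pg

    def test_realized_heritability_matches_target(self):
        """Mean realized V(Z beta)/V(y) across replicates hits the target h2g."""
        vals = []
        for k in range(50):
            pe, pg = self._panels(3 * k + 10, n_ind=500, n_snp=100)
            _, _, truth = simulate_study(pe, pg, h2g=0.1, h2med=0.01,
                                         causal_frac=0.05, seed=k)
            vals.append(truth.s2_gene / truth.sd_gene ** 2)
        assert np.mean(vals) == pytest.approx(0.1, abs=0.01)

    def test_null_mode_effects_uncorrelated(self):
        rs = []
        for k in range(100):
            pe, pg = self._panels(5000 + 2 * k, n_ind=50, n_snp=60)
            _, _, truth = simulate_study(pe, pg, mode="null",
                                         causal_frac=0.1, seed=k)
            rs.append(np.corrcoef(truth.beta_eqtl, truth.beta_gwas)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_hp_mode_adds_three_trait_only_signals(self):
        pe, pg = self._panels(77)
        _, _, truth = simulate_study(pe, pg, mode="hp", seed=6)
        assert np.count_nonzero(truth.beta_gwas) == \
            np.count_nonzero(truth.beta_eqtl) + 3

    def test_mediated_zero_h2med_falls_back_to_null(self):
        pe, pg = self._panels(42)
        with pytest.warns(UserWarning, match="null semantics"):
            _, _, truth = simulate_study(pe, pg, h2med=0.0, mode="mediated",
                                         seed=1)
        assert truth.mode == "null"
        assert not truth.alpha_defined


class TestTrueAlpha:
    def test_alpha_matches_heritability_relation(self):
        """|alpha| ~= sqrt(h2med/h2g) on average over replicates."""
        vals = []
        for k in range(20):
            pe = simulate_genotypes(500, 100, seed=900 + 2 * k)
            pg = simulate_genotypes(2000, 100, seed=901 + 2 * k)
            _, _, truth = simulate_study(pe, pg, h2g=0.1, h2med=0.01,
                                         causal_frac=0.05, seed=k)
            vals.append(abs(true_alpha(truth)))
        assert np.mean(vals) == pytest.approx(np.sqrt(0.1), abs=0.05)

    def test_null_flagged_zero(self):
        pe = simulate_genotypes(200, 50, seed=1)
        pg = simulate_genotypes(200, 50, seed=2)
        _, _, truth = simulate_study(pe, pg, mode="null", seed=3)
        assert true_alpha(truth) == 0.0

    def test_constant_ratio_in_mediated_mode(self):
        pe = simulate_genotypes(200, 50, seed=4)
        pg = simulate_genotypes(200, 50, seed=5)
        _, _, truth = simulate_study(pe, pg, seed=6)
        # would raise inside true_alpha if the ratio were not constant
        assert truth.alpha == pytest.approx(true_alpha(truth), rel=1e-12)


class TestCorrelatedInstruments:
    def test_zero_correlation(self):
        sets = simulate_correlated_instruments(4, 0.0, 1000, seed=1)
        ba = np.array([s.beta_a for s in sets])
        adj = [np.corrcoef(ba[:, j], ba[:, j + 1])[0, 1] for j in range(3)]
        assert np.abs(adj).max() < 0.08

    def test_adjacent_correlation_matches_parameter(self):
        sets = simulate_correlated_instruments(4, 0.05, 1000, seed=2)
        ba = np.array([s.beta_a for s in sets])
        adj = np.mean([np.corrcoef(ba[:, j], ba[:, j + 1])[0, 1]
                       for j in range(3)])
        assert adj == pytest.approx(0.05, abs=0.03)

    def test_true_slope_is_zero_by_construction(self):
        sets = simulate_correlated_instruments(6, 0.2, 500, seed=3)
        bb = np.array([s.beta_b for s in sets])
        assert np.abs(bb.mean(axis=0)).max() < 0.15
        ba = np.array([s.beta_a for s in sets])
        assert ba.mean() == pytest.approx(10.0, abs=0.1)

    def test_common_random_numbers_across_r2(self):
        s1 = simulate_correlated_instruments(4, 0.0, 5, seed=9)
        s2 = simulate_correlated_instruments(4, 0.05, 5, seed=9)
        # same underlying normals: strongly matched draws
        d = np.concatenate([a.beta_a - b.beta_a for a, b in zip(s1, s2)])
        assert np.abs(d).max() < 0.5


class TestSimulateFromSlopeModel:
    def test_zero_dispersion_collinear(self):
        ins = simulate_from_slope_model(10, 0.7, 0.0, 1.0, 1e-6, 1e-6, seed=1)
        resid = ins.beta_b - 0.7 * ins.beta_a
        assert np.abs(resid).max() < 1e-4

    def test_large_sample_wls_slope(self):
        ins = simulate_from_slope_model(200, 0.3, 0.05, 1.0, 0.05, 0.05, seed=2)
        w = 1 / ins.se_b ** 2
        slope = np.sum(w * ins.beta_a * ins.beta_b) / np.sum(w * ins.beta_a ** 2)
        assert slope == pytest.approx(0.3, abs=0.05)

    def test_same_seed_identical(self):
        a = simulate_from_slope_model(5, 0.3, 0.1, 1.0, 0.05, 0.05, seed=3)
        b = simulate_from_slope_model(5, 0.3, 0.1, 1.0, 0.05, 0.05, seed=3)
        assert np.array_equal(a.beta_a, b.beta_a)
        assert np.array_equal(a.beta_b, b.beta_b)
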