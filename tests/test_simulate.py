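"""Tests of the synthetic-data generator: LD structure, standardization,
phenotype model, summary statistics and covariate projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import heels as H
from heels.types import GenotypePanel


def _adjacent_corr(G):
    X = (G - G.mean(0)) / G.std(0)
    return np.mean([np.mean(X[:, j] * X[:, j + 1]) for j in range(G.shape[1] - 1)])


class TestSimulateGenotypes:
    def test_independent_markers_uncorrelated(self):
        cfg = H.SimulationConfig(n=500, p=50, seed=1, ld_model="ar1", rho=0.0)
        panel = H.simulate_genotypes(cfg)
        assert abs(_adjacent_corr(panel.G.astype(float))) < 0.05

    def test_deterministic_given_seed(self):
        cfg = H.SimulationConfig(n=200, p=40, seed=5, ld_model="ar1", rho=0.5)
        g1 = H.simulate_genotypes(cfg).G
        g2 = H.simulate_genotypes(cfg).G
        assert np.array_equal(g1, g2)

    def test_no_monomorphic_columns(self):
        cfg = H.SimulationConfig(n=30, p=80, seed=2, maf_range=(0.05, 0.2))
        panel = H.simulate_genotypes(cfg)
        counts = panel.G.sum(axis=0)
        assert np.all((counts > 0) & (counts < 2 * cfg.n))

    def test_ar1_ld_matches_latent_threshold_oracle(self):
        # brute-force Monte-Carlo of the latent model at the same rho and mafs
        cfg = H.SimulationConfig(n=2000, p=100, seed=3, ld_model="ar1", rho=0.9)
        panel = H.simulate_genotypes(cfg)
        observed = _adjacent_corr(panel.G.astype(float))

        from scipy import stats as sps

        rng = np.random.default_rng(12345)
        m = 200_000
        rho = 0.9
        sims = []
        for f1, f2 in zip(panel.maf[:-1:7], panel.maf[1::7]):  # subsample pairs
            z1 = rng.standard_normal((m, 2))
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal((m, 2))
            g1 = (z1 < sps.norm.ppf(f1)).sum(axis=1)
            g2 = (z2 < sps.norm.ppf(f2)).sum(axis=1)
            sims.append(np.corrcoef(g1, g2)[0, 1])
        assert observed == pytest.approx(np.mean(sims), abs=0.1)

    def test_block_model_has_within_block_ld(self):
        cfg = H.SimulationConfig(
            n=1000, p=40, seed=4, ld_model="block", rho=0.8, block_size=10
        )
        G = H.simulate_genotypes(cfg).G.astype(float)
        X = (G - G.mean(0)) / G.std(0)
        C = X.T @ X / cfg.n
        within = np.mean([C[i, j] for i in range(10) for j in range(10) if i != j])
        between = np.mean([C[i, j] for i in range(10) for j in range(10, 20)])
        assert within > 0.2 and abs(between) < 0.1


class TestStandardize:
    def test_unit_variance_moments(self, small_panel):
        X = small_panel["Xu"].X
        assert np.allclose(X.mean(0), 0, atol=1e-12)
        assert np.allclose((X**2).mean(0), 1, atol=1e-10)

    def test_model_scale_diagonal(self, small_panel):
        Xm = small_panel["Xm"]
        diag = np.diag(Xm.X.T @ Xm.X) / Xm.n
        assert np.allclose(diag, 1.0 / Xm.p, atol=1e-10)

    def test_raw_formula_at_half_frequency(self):
        # G=2 at f=0.5 maps to (2-1)/sqrt(0.5) = sqrt(2) before re-centering
        assert (2 - 2 * 0.5) / np.sqrt(2 * 0.5 * 0.5) == pytest.approx(np.sqrt(2))

    def test_monomorphic_column_rejected(self):
        G = np.array([[0, 1], [0, 2], [0, 1]])
        with pytest.raises(ValueError, match="monomorphic"):
            GenotypePanel(G=G, maf=G.mean(0) / 2)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_moments_hold_for_any_panel(self, seed):
        cfg = H.SimulationConfig(n=50, p=8, seed=seed, ld_model="ar1", rho=0.4)
        Xu = H.standardize(H.simulate_genotypes(cfg), "unit_variance")
        assert np.allclose(Xu.X.mean(0), 0, atol=1e-10)
        assert np.allclose((Xu.X**2).mean(0), 1, atol=1e-8)


class TestSimulatePhenotype:
    def test_null_heritability_gives_pure_noise(self, small_panel):
        cfg = H.SimulationConfig(n=300, p=30, h2=0.0, seed=7)
        y, beta, causal = H.simulate_phenotype(small_panel["Xu"], cfg)
        assert np.all(beta == 0) and causal.size == 0
        assert abs(y.var() - 1.0) < 0.3

    def test_deterministic_given_seed(self, small_panel):
        cfg = small_panel["cfg"]
        y1, _, _ = H.simulate_phenotype(small_panel["Xu"], cfg)
        y2, _, _ = H.simulate_phenotype(small_panel["Xu"], cfg)
        assert np.array_equal(y1, y2)

    def test_causal_set_size(self, small_panel):
        cfg = H.SimulationConfig(n=300, p=30, h2=0.2, polygenicity=0.5, seed=9)
        _, beta, causal = H.simulate_phenotype(small_panel["Xu"], cfg)
        assert causal.size == 15 == np.count_nonzero(beta)

    def test_heritability_recovery_infinitesimal(self):
        # mean of var(X beta)/var(y) over replicates approaches h2
        cfg0 = H.SimulationConfig(n=2000, p=200, h2=0.25, seed=42, ld_model="ar1", rho=0.8)
        Xu = H.standardize(H.simulate_genotypes(cfg0), "unit_variance")
        ratios = []
        for rep in range(200):
            cfg = H.SimulationConfig(n=2000, p=200, h2=0.25, seed=5000 + rep,
                                     ld_model="ar1", rho=0.8)
            y, beta, _ = H.simulate_phenotype(Xu, cfg)
            g = Xu.X @ beta
            ratios.append(g.var() / y.var())
        assert np.mean(ratios) == pytest.approx(0.25, abs=0.03)


class TestSummaryStats:
    def test_zero_phenotype(self, small_panel):
        stats, R = H.compute_sumstats(small_panel["Xm"], np.zeros(300))
        assert np.all(stats.S == 0) and stats.yty == 0

    def test_ld_symmetric_psd(self, small_panel):
        R = small_panel["R"]
        assert np.max(np.abs(R - R.T)) == 0
        assert np.linalg.eigvalsh(R).min() >= -1e-8

    def test_single_marker_ld_equals_n(self):
        cfg = H.SimulationConfig(n=150, p=1, seed=0)
        panel = H.simulate_genotypes(cfg)
        Xm = H.standardize(panel, "model_scale")
        _, R = H.compute_sumstats(Xm, np.ones(150))
        assert R[0, 0] == pytest.approx(150, abs=1e-6)

    def test_scale_duality(self, small_panel):
        Xu, Xm, y = small_panel["Xu"], small_panel["Xm"], small_panel["y"]
        p = Xu.p
        stats, R = H.compute_sumstats(Xm, y)
        S_unit = Xu.X.T @ y
        assert np.allclose(stats.S, S_unit / np.sqrt(p), rtol=0, atol=1e-12)
        assert np.allclose(R, (Xu.X.T @ Xu.X) / p, rtol=0, atol=1e-12)

    def test_expected_sumstats_recover_truth_exactly(self, small_panel):
        stats = H.simulate.expected_sumstats(small_panel["R"], 0.31, 0.72, 300)
        fit = H.heels_fit(stats, H.DenseLD(small_panel["R"]), tol=1e-12)
        assert fit.vc.sigma_g2 == pytest.approx(0.31, abs=1e-7)
        assert fit.vc.sigma_e2 == pytest.approx(0.72, abs=1e-7)


class TestMarginalOLS:
    def test_self_column_slope_is_one(self, small_panel):
        Xu = small_panel["Xu"]
        slopes = H.marginal_ols(Xu, Xu.X[:, 3])
        assert slopes[3] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_phenotype(self, small_panel):
        Xu = small_panel["Xu"]
        y = small_panel["y"]
        y_orth = y - Xu.X @ np.linalg.lstsq(Xu.X, y, rcond=None)[0]
        assert np.allclose(H.marginal_ols(Xu, y_orth), 0, atol=1e-10)

    def test_matches_scalar_regressions(self, small_panel):
        Xu, y = small_panel["Xu"], small_panel["y"]
        slopes = H.marginal_ols(Xu, y)
        for j in [0, 7, 29]:
            x = Xu.X[:, j]
            assert slopes[j] == pytest.approx(float(x @ y) / float(x @ x), rel=1e-10)


class TestProjectCovariates:
    def test_intercept_equals_centering(self, small_panel):
        X, y = small_panel["Xu"].X, small_panel["y"]
        Xr, yr = H.project_covariates(X, y, np.ones((300, 1)))
        assert np.allclose(Xr, X - X.mean(0), atol=1e-10)
        assert np.allclose(yr, y - y.mean(), atol=1e-10)

    def test_phenotype_in_covariate_span_vanishes(self, small_panel):
        y = small_panel["y"]
        C = np.column_stack([np.ones(300), y])
        _, yr = H.project_covariates(small_panel["Xu"].X, y, C)
        assert np.allclose(yr, 0, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, small_panel):
        rng = np.random.default_rng(0)
        C = rng.standard_normal((300, 4))
        Xr, yr = H.project_covariates(small_panel["Xu"].X, small_panel["y"], C)
        assert np.max(np.abs(Xr.T @ C)) < 1e-8
        assert np.max(np.abs(yr @ C)) < 1e-8

    def test_rank_deficient_rejected(self, small_panel):
        C = np.ones((300, 2))
        with pytest.raises(ValueError, match="rank"):
            H.project_covariates(small_panel["Xu"].X, small_panel["y"], C)
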