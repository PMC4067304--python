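"""Lognormal distance likelihood and Gibbs updates of nuisance parameters."""

import numpy as np
import pytest
from scipy import stats

from ramaweight.restraints import (
    DistanceRestraint,
    NuisanceParams,
    RestraintSet,
    data_energy,
    gibbs_update_aux_distances,
    gibbs_update_gamma,
    gibbs_update_sigma,
    neg_log_lognormal,
    read_restraint_table,
    write_restraint_table,
)


class TestLognormal:
    def test_zero_residual_value(self):
        # d_obs = gamma * d_calc: only the normalization term remains
        v = neg_log_lognormal(3.0, 1.5, gamma=2.0, sigma=0.2)
        assert v == pytest.approx(np.log(3.0 * 0.2 * np.sqrt(2 * np.pi)))

    def test_minimum_over_dcalc_at_zero_residual(self):
        d_obs, gamma, sigma = 4.0, 1.1, 0.3
        grid = np.linspace(1.0, 10.0, 2001)
        vals = neg_log_lognormal(d_obs, grid, gamma, sigma)
        assert grid[np.argmin(vals)] == pytest.approx(d_obs / gamma, abs=0.01)

    def test_large_sigma_kills_quadratic_term(self):
        big = neg_log_lognormal(2.0, 5.0, 1.0, 1e6)
        assert big == pytest.approx(np.log(2.0 * 1e6 * np.sqrt(2 * np.pi)), abs=1e-9)

    def test_sum_matches_per_term_oracle(self, rng):
        d_obs = rng.uniform(2, 8, 20)
        d_calc = rng.uniform(2, 8, 20)
        total = neg_log_lognormal(d_obs, d_calc, 1.2, 0.25).sum()
        oracle = sum(
            float(neg_log_lognormal(o, c, 1.2, 0.25)) for o, c in zip(d_obs, d_calc)
        )
        assert total == pytest.approx(oracle, abs=1e-12)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            neg_log_lognormal(-1.0, 2.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            neg_log_lognormal(1.0, 2.0, 1.0, -0.1)


class TestDataEnergy:
    def test_empty_restraint_set(self, rng):
        coords = rng.uniform(0, 5, (6, 3))
        assert data_energy(coords, RestraintSet([]), NuisanceParams()) == 0.0

    def test_degenerate_bounds_equal_exact(self, rng):
        coords = rng.uniform(0, 5, (6, 3)) * 3
        d = float(np.linalg.norm(coords[0] - coords[4]))
        exact = RestraintSet([DistanceRestraint(0, 4, "exact", d_obs=5.0)])
        bounds = RestraintSet([DistanceRestraint(0, 4, "bounds", lower=5.0, upper=5.0)])
        nz = NuisanceParams(gamma=1.0, sigma=0.2, aux_distances=np.array([5.0]))
        assert data_energy(coords, bounds, nz) == data_energy(
            coords, exact, NuisanceParams(gamma=1.0, sigma=0.2)
        )

    def test_permutation_invariance(self, rng):
        coords = rng.uniform(0, 8, (8, 3))
        rs = [
            DistanceRestraint(i, j, "exact", d_obs=float(rng.uniform(2, 6)))
            for i, j in [(0, 3), (1, 5), (2, 7), (0, 6)]
        ]
        nz = NuisanceParams(1.1, 0.3)
        a = data_energy(coords, RestraintSet(rs), nz)
        b = data_energy(coords, RestraintSet(rs[::-1]), nz)
        assert a == pytest.approx(b, abs=1e-12)

    def test_perturbation_locality(self, rng):
        # moving one bead changes only terms whose d_calc changed
        coords = rng.uniform(0, 8, (8, 3))
        rs = RestraintSet(
            [
                DistanceRestraint(0, 3, "exact", d_obs=4.0),
                DistanceRestraint(5, 7, "exact", d_obs=3.0),
            ]
        )
        nz = NuisanceParams(1.0, 0.2)
        coords2 = coords.copy()
        coords2[7] += 0.5
        terms_before = [
            data_energy(coords, RestraintSet([r]), nz) for r in rs
        ]
        terms_after = [
            data_energy(coords2, RestraintSet([r]), nz) for r in rs
        ]
        assert terms_before[0] == terms_after[0]
        assert terms_before[1] != terms_after[1]

    def test_missing_aux_distances_raise(self, rng):
        coords = rng.uniform(0, 5, (4, 3))
        rs = RestraintSet([DistanceRestraint(0, 3, "bounds", lower=2.0, upper=4.0)])
        with pytest.raises(RuntimeError):
            data_energy(coords, rs, NuisanceParams())

    def test_invalid_restraints_rejected(self):
        with pytest.raises(ValueError):
            DistanceRestraint(1, 1, "exact", d_obs=2.0)
        with pytest.raises(ValueError):
            DistanceRestraint(0, 1, "bounds", lower=4.0, upper=2.0)
        with pytest.raises(ValueError):
            DistanceRestraint(0, 1, "exact", d_obs=-2.0)


class TestGibbsSigma:
    def test_posterior_moment_matches_conjugate_oracle(self):
        residuals = np.array([0.1, -0.2, 0.15, 0.05, -0.1])
        n, ss = residuals.size, float(residuals @ residuals)
        rng = np.random.default_rng(5)
        draws = np.array([gibbs_update_sigma(residuals, rng) for _ in range(100_000)])
        inv_var = 1.0 / draws**2
        # E[1/sigma^2] = shape/scale = (n/2)/(ss/2) = n/ss
        mc_se = inv_var.std() / np.sqrt(inv_var.size)
        assert abs(inv_var.mean() - n / ss) < 2 * mc_se

    def test_scale_equivariance(self):
        residuals = np.array([0.3, -0.1, 0.2, 0.25])
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        a = np.median([gibbs_update_sigma(residuals, rng1) for _ in range(20_000)])
        b = np.median([gibbs_update_sigma(2 * residuals, rng2) for _ in range(20_000)])
        assert b / a == pytest.approx(2.0, rel=0.03)

    def test_seed_determinism(self):
        r = np.array([0.1, 0.2])
        assert gibbs_update_sigma(r, 3) == gibbs_update_sigma(r, 3)

    def test_all_zero_residuals_regularized(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = gibbs_update_sigma(np.zeros(4), 0)
        assert np.isfinite(s) and s > 0


class TestGibbsGamma:
    def test_exact_scale_small_sigma(self):
        d_calc = np.array([2.0, 3.0, 4.0])
        d_obs = 2.0 * d_calc
        g = gibbs_update_gamma(d_obs, d_calc, sigma=1e-6, seed=1)
        assert g == pytest.approx(2.0, rel=1e-4)

    def test_posterior_mean_matches_gaussian_oracle(self):
        rng0 = np.random.default_rng(2)
        d_calc = rng0.uniform(2, 6, 10)
        d_obs = 1.5 * d_calc * np.exp(0.1 * rng0.standard_normal(10))
        sigma = 0.2
        rng = np.random.default_rng(3)
        draws = np.log(
            [gibbs_update_gamma(d_obs, d_calc, sigma, rng) for _ in range(100_000)]
        )
        mean_expected = np.mean(np.log(d_obs) - np.log(d_calc))
        se = sigma / np.sqrt(10) / np.sqrt(100_000) * 3
        assert abs(draws.mean() - mean_expected) < 5 * se

    def test_common_rescaling_invariance(self):
        d_calc = np.array([2.0, 5.0])
        d_obs = np.array([2.2, 4.9])
        a = gibbs_update_gamma(d_obs, d_calc, 0.1, 7)
        b = gibbs_update_gamma(3 * d_obs, 3 * d_calc, 0.1, 7)
        assert a == pytest.approx(b, rel=1e-12)

    def test_weight_zero_flat_prior_rejected(self):
        with pytest.raises(ValueError):
            gibbs_update_gamma(np.array([2.0]), np.array([2.0]), 0.1, 0, weight=0.0)


class TestGibbsAux:
    def test_draws_respect_bounds(self):
        lower = np.full(50, 3.0)
        upper = np.full(50, 5.0)
        d_calc = np.full(50, 4.0)
        rng = np.random.default_rng(8)
        for _ in range(200):
            aux = gibbs_update_aux_distances(lower, upper, d_calc, 1.0, 0.3, rng)
            assert np.all(aux >= lower) and np.all(aux <= upper)

    def test_wide_bounds_match_untruncated_lognormal(self):
        n = 100_000
        lower = np.full(n, 1e-3)
        upper = np.full(n, 1e3)
        d_calc = np.full(n, 3.0)
        aux = gibbs_update_aux_distances(lower, upper, d_calc, 1.0, 0.25, 4)
        oracle = 3.0 * np.exp(0.25 * np.random.default_rng(5).standard_normal(n))
        assert stats.ks_2samp(aux, oracle).statistic < 0.02

    def test_piles_up_near_lower_when_dcalc_below(self):
        # gamma*d_calc far below the interval: density is monotone
        # decreasing on [L, U], so draws concentrate near L
        n = 20_000
        lower, upper = np.full(n, 6.0), np.full(n, 8.0)
        d_calc = np.full(n, 2.0)
        aux = gibbs_update_aux_distances(lower, upper, d_calc, 1.0, 0.2, 6)
        x = np.log(aux)
        mu, sd = np.log(2.0), 0.2
        a, b = (np.log(6.0) - mu) / sd, (np.log(8.0) - mu) / sd
        # quadrature oracle for the median of the truncated conditional
        med_oracle = np.exp(stats.truncnorm.ppf(0.5, a, b, loc=mu, scale=sd))
        assert np.median(aux) == pytest.approx(med_oracle, rel=1e-3)
        # quadrature oracle: bin masses of the truncated conditional are
        # monotone decreasing on [L, U] and match the empirical histogram
        edges = np.linspace(6.0, 8.0, 11)
        quad = np.diff(stats.truncnorm.cdf((np.log(edges) - mu) / sd, a, b))
        emp, _ = np.histogram(aux, bins=edges)
        emp = emp / emp.sum()
        assert np.all(np.diff(quad) < 0)
        assert np.abs(emp - quad).max() < 0.01

    def test_zero_width_interval_returns_bound(self):
        aux = gibbs_update_aux_distances(
            np.array([4.0]), np.array([4.0]), np.array([3.0]), 1.0, 0.2, 0
        )
        assert aux[0] == 4.0

    def test_weight_zero_uniform(self):
        n = 50_000
        aux = gibbs_update_aux_distances(
            np.full(n, 2.0), np.full(n, 4.0), np.full(n, 3.0), 1.0, 0.2, 1, weight=0.0
        )
        assert stats.kstest(aux, stats.uniform(2.0, 2.0).cdf).statistic < 0.01


class TestJointGibbs:
    def test_joint_matches_quadrature_on_frozen_conformation(self):
        """Alternating sigma/gamma updates target the exact conditional
        posterior: on a 3-restraint toy the empirical joint over a
        (sigma, gamma) grid matches brute-force quadrature (TV < 0.05).
        """
        d_calc = np.array([3.0, 4.0, 5.0])
        d_obs = np.array([3.3, 3.7, 5.4])
        diffs = np.log(d_obs) - np.log(d_calc)

        rng = np.random.default_rng(10)
        sig, gam = 0.3, 1.0
        sigmas, gammas = [], []
        for it in range(60_000):
            gam = gibbs_update_gamma(d_obs, d_calc, sig, rng)
            resid = diffs - np.log(gam)
            sig = gibbs_update_sigma(resid, rng)
            if it >= 1000:
                sigmas.append(sig)
                gammas.append(gam)
        sigmas, gammas = np.array(sigmas), np.array(gammas)

        # brute-force joint posterior on a grid, compared inside the
        # central 98% window (the n=3 posterior has very heavy tails)
        s_edges = np.quantile(sigmas, np.linspace(0.01, 0.99, 9))
        g_edges = np.quantile(gammas, np.linspace(0.01, 0.99, 9))
        s_grid = np.linspace(s_edges[0], s_edges[-1], 800)
        g_grid = np.linspace(g_edges[0], g_edges[-1], 800)
        S, G = np.meshgrid(s_grid, g_grid, indexing="ij")
        # Jeffreys on sigma^2 is 1/sigma as a density in sigma
        logp = -np.log(S)
        for d in diffs:
            logp += -np.log(S) - 0.5 * (d - np.log(G)) ** 2 / S**2
        logp += -np.log(G)  # flat prior on log gamma -> 1/gamma in gamma
        p = np.exp(logp - logp.max())
        p /= p.sum()

        emp, _, _ = np.histogram2d(sigmas, gammas, bins=[s_edges, g_edges])
        emp = emp / emp.sum()
        quad, _, _ = np.histogram2d(
            S.ravel(), G.ravel(), bins=[s_edges, g_edges], weights=p.ravel()
        )
        quad /= quad.sum()
        tv = 0.5 * np.abs(emp - quad).sum()
        assert tv < 0.05


class TestTableIO:
    def test_round_trip(self, tmp_path):
        rs = RestraintSet(
            [
                DistanceRestraint(0, 5, "exact", d_obs=4.2),
                DistanceRestraint(1, 7, "bounds", lower=3.0, upper=6.5),
            ]
        )
        path = tmp_path / "restraints.tsv"
        write_restraint_table(rs, path)
        back = read_restraint_table(path)
        assert len(back) == 2
        assert back.restraints[0].d_obs == pytest.approx(4.2)
        assert back.restraints[1].lower == pytest.approx(3.0)
        assert back.restraints[1].upper == pytest.approx(6.5)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError):
            read_restraint_table(p)
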