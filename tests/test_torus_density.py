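"""Maximum-entropy torus density: basis, quadrature, fitting, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0
from scipy.stats import chi2, ks_2samp

from ramaweight.torus_density import (
    MaxEntDensity,
    enumerate_basis,
    eval_basis,
    fit_maxent,
    log_partition,
    rama_potential,
    sample_density,
    update_precision,
    wrap_angle,
)

TWO_PI = 2 * np.pi


def _brute_force_basis_count(order):
    """Independent enumeration over all 4*order^2 candidate products."""
    count = 0
    for t1 in ("cos", "sin"):
        for t2 in ("cos", "sin"):
            for k in range(order):
                for l in range(order):
                    if t1 == "sin" and k == 0:
                        continue  # identically zero
                    if t2 == "sin" and l == 0:
                        continue
                    if t1 == t2 == "cos" and k == l == 0:
                        continue  # constant
                    count += 1
    return count


class TestBasis:
    @pytest.mark.parametrize("order", [1, 2, 3, 5, 7])
    def test_count_matches_brute_force_enumeration(self, order):
        assert len(enumerate_basis(order)) == _brute_force_basis_count(order)

    def test_order5_has_80_functions(self):
        # five frequencies per dimension -> 80 cosine/sine products
        assert len(enumerate_basis(5)) == 80

    def test_order1_is_empty(self):
        assert enumerate_basis(1) == []

    @pytest.mark.parametrize("bad", [0, -1])
    def test_nonpositive_order_rejected(self, bad):
        with pytest.raises(ValueError):
            enumerate_basis(bad)

    def test_origin_values(self):
        # at (0, 0) sine factors vanish and pure-cosine products are 1
        vals = eval_basis(0.0, 0.0, 5)
        for v, b in zip(vals, enumerate_basis(5)):
            expected = 1.0 if b.phi_kind == b.psi_kind == "cos" else 0.0
            assert v == pytest.approx(expected, abs=1e-14)

    def test_values_bounded(self, rng):
        phi = rng.uniform(-10, 10, 50)
        psi = rng.uniform(-10, 10, 50)
        vals = eval_basis(phi, psi, 4)
        assert np.all(np.abs(vals) <= 1 + 1e-12)

    def test_zero_mean_over_torus(self):
        g = np.linspace(-np.pi, np.pi, 256, endpoint=False)
        vals = eval_basis(g[:, None], g[None, :], 3)
        means = vals.mean(axis=(0, 1))
        assert np.abs(means).max() < 1e-8

    def test_orthogonality_pattern(self):
        # trapezoidal inner products on a 256^2 grid: the product trig
        # basis is orthogonal with norm (pi or 2pi)^2 / (2pi)^2 factors
        g = np.linspace(-np.pi, np.pi, 256, endpoint=False)
        vals = eval_basis(g[:, None], g[None, :], 3).reshape(-1, len(enumerate_basis(3)))
        gram = vals.T @ vals / vals.shape[0]
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10
        diag = np.diag(gram)
        assert np.all((np.abs(diag - 0.25) < 1e-10) | (np.abs(diag - 0.5) < 1e-10))


class TestPotentialAndPartition:
    def test_zero_coeffs_give_zero_potential(self, rng):
        d = MaxEntDensity(order=3, coeffs=np.zeros(len(enumerate_basis(3))))
        pts = rng.uniform(-np.pi, np.pi, (20, 2))
        assert np.all(rama_potential(d, pts[:, 0], pts[:, 1]) == 0)

    def test_single_cos_phi_coefficient(self, rng):
        basis = enumerate_basis(5)
        idx = basis.index(("cos", "cos", 1, 0))
        c = np.zeros(80)
        c[idx] = 1.0
        d = MaxEntDensity(order=5, coeffs=c)
        phi = rng.uniform(-np.pi, np.pi, 30)
        assert rama_potential(d, phi, np.zeros_like(phi)) == pytest.approx(np.cos(phi))

    def test_matches_term_by_term_summation(self, rng):
        order = 4
        basis = enumerate_basis(order)
        coeffs = rng.normal(size=len(basis))
        d = MaxEntDensity(order=order, coeffs=coeffs)
        trig = {"cos": np.cos, "sin": np.sin}
        for _ in range(64):
            phi, psi = rng.uniform(-np.pi, np.pi, 2)
            oracle = sum(
                c * trig[b.phi_kind](b.k * phi) * trig[b.psi_kind](b.l * psi)
                for c, b in zip(coeffs, basis)
            )
            assert rama_potential(d, phi, psi) == pytest.approx(oracle, abs=1e-12)

    def test_uniform_partition(self):
        assert log_partition(np.zeros(80), 5) == pytest.approx(np.log(4 * np.pi**2))

    def test_bessel_oracle(self):
        # E = -cos(phi)  =>  Z = 4 pi^2 I0(1)
        idx = enumerate_basis(5).index(("cos", "cos", 1, 0))
        c = np.zeros(80)
        c[idx] = -1.0
        assert log_partition(c, 5) == pytest.approx(np.log(4 * np.pi**2 * i0(1.0)))

    def test_grid_doubling_self_convergence(self, toy_density):
        a = log_partition(toy_density.coeffs, toy_density.order, 128)
        b = log_partition(toy_density.coeffs, toy_density.order, 512)
        assert abs(a - b) < 1e-6

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            log_partition(np.zeros(80), 5, grid_n=8)


class TestFit:
    def test_uniform_samples_give_near_zero_coefficients(self, rng):
        samples = rng.uniform(-np.pi, np.pi, (5000, 2))
        fit = fit_maxent(samples, order=3, precision=10.0)
        assert np.abs(fit.density.coeffs).max() < 0.1
        # with the evidence-driven precision the fit shrinks to uniform
        fit_auto = fit_maxent(samples, order=3, precision="auto")
        g = np.linspace(-np.pi, np.pi, 64, endpoint=False)
        p = np.exp(fit_auto.density.log_pdf(g[:, None], g[None, :]))
        uniform = 1 / (4 * np.pi**2)
        assert np.abs(p / uniform - 1).max() < 0.02

    def test_recovers_known_density(self, order2_density, rng):
        samples = sample_density(order2_density, 10_000, rng)
        fit = fit_maxent(samples, order=2, precision="auto")
        g = np.linspace(-np.pi, np.pi, 128, endpoint=False)
        lp_true = order2_density.log_pdf(g[:, None], g[None, :])
        lp_fit = fit.density.log_pdf(g[:, None], g[None, :])
        kl = float(np.mean(np.exp(lp_true) * (lp_true - lp_fit)) * 4 * np.pi**2)
        assert 0 <= kl < 0.05

    def test_gradient_vanishes_at_optimum(self, rng):
        samples = rng.uniform(-np.pi, np.pi, (2000, 2))
        samples[:, 1] = wrap_angle(0.7 + 0.5 * rng.standard_normal(2000))
        tau = 5.0
        fit = fit_maxent(samples, order=2, precision=tau, tol=1e-8)
        g = fit.density.coeffs
        n = samples.shape[0]

        def objective(c):
            return (
                log_partition(c, 2)
                + eval_basis(samples[:, 0], samples[:, 1], 2).mean(axis=0) @ c
                + 0.5 * tau / n * c @ c
            )

        h = 1e-6
        fd = np.array(
            [
                (objective(g + h * e) - objective(g - h * e)) / (2 * h)
                for e in np.eye(g.size)
            ]
        )
        assert np.abs(fd).max() < 1e-4

    def test_regularization_monotonicity(self, order2_density, rng):
        samples = sample_density(order2_density, 3000, rng)
        norms = [
            np.linalg.norm(fit_maxent(samples, 2, precision=t).density.coeffs)
            for t in [0.1, 10.0, 1000.0, 1e5]
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_midpoint_convexity_of_objective(self, rng):
        samples = rng.uniform(-np.pi, np.pi, (500, 2))
        b_mean = eval_basis(samples[:, 0], samples[:, 1], 2).mean(axis=0)
        tau, n = 3.0, 500

        def objective(c):
            return log_partition(c, 2, 64) + b_mean @ c + 0.5 * tau / n * c @ c

        for _ in range(20):
            a = rng.normal(scale=1.5, size=8)
            b = rng.normal(scale=1.5, size=8)
            mid = objective(0.5 * (a + b))
            assert mid <= 0.5 * (objective(a) + objective(b)) + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent(np.zeros((1, 2)), 2)

    def test_normalization_invariant(self, toy_density):
        g = np.linspace(-np.pi, np.pi, toy_density.grid_n, endpoint=False)
        p = np.exp(toy_density.log_pdf(g[:, None], g[None, :]))
        integral = p.mean() * 4 * np.pi**2
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_periodicity(self, toy_density, rng):
        phi = rng.uniform(-np.pi, np.pi, 10)
        psi = rng.uniform(-np.pi, np.pi, 10)
        a = rama_potential(toy_density, phi, psi)
        b = rama_potential(toy_density, phi + TWO_PI, psi - TWO_PI)
        assert a == pytest.approx(b, abs=1e-9)


class TestPrecision:
    def test_formula(self):
        coeffs = np.full(80, np.sqrt(0.5))  # ||g||^2 = 40, K = 80
        assert update_precision(coeffs).tau == pytest.approx(2.0)

    def test_zero_coeffs_degenerate(self):
        state = update_precision(np.zeros(10))
        assert state.degenerate and state.tau == state.tau_max

    def test_fit_update_fixed_point(self, order2_density, rng):
        samples = sample_density(order2_density, 4000, rng)
        fit = fit_maxent(samples, 2, precision="auto")
        tau = fit.precision.tau
        refit = fit_maxent(samples, 2, precision=tau)
        tau2 = update_precision(refit.density.coeffs).tau
        assert abs(tau2 - tau) < 2e-3 * tau

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_tau_positive_and_capped(self, scale):
        coeffs = np.full(12, scale)
        tau = update_precision(coeffs).tau
        assert 0 < tau <= 1e6


class TestAngleTable:
    def test_per_residue_fit_with_generic_fallback(self, rng, tmp_path):
        import pandas as pd

        from ramaweight.torus_density import (
            fit_angle_table,
            read_angle_table,
            write_angle_table,
        )

        frames = []
        for rtype, (p0, s0) in {"ALA": (-63, -43), "GLY": (90, 0)}.items():
            frames.append(
                pd.DataFrame(
                    {
                        "residue_type": rtype,
                        "phi_deg": rng.normal(p0, 20, 800),
                        "psi_deg": rng.normal(s0, 20, 800),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        path = tmp_path / "angles.tsv"
        write_angle_table(df, path)
        densities = fit_angle_table(read_angle_table(path), order=3)
        assert set(densities) == {"GENERIC", "ALA", "GLY"}
        ala = densities["ALA"]
        # the ALA density must put its mode near the ALA basin
        assert ala.pdf(np.deg2rad(-63), np.deg2rad(-43)) > ala.pdf(
            np.deg2rad(90), np.deg2rad(0)
        )


class TestSampler:
    def test_seed_reproducibility(self, toy_density):
        a = sample_density(toy_density, 100, 42)
        b = sample_density(toy_density, 100, 42)
        assert np.array_equal(a, b)

    def test_uniform_density_gof(self):
        d = MaxEntDensity(order=2, coeffs=np.zeros(8))
        s = sample_density(d, 20_000, 7)
        h, _, _ = np.histogram2d(s[:, 0], s[:, 1], bins=8,
                                 range=[[-np.pi, np.pi], [-np.pi, np.pi]])
        expected = 20_000 / 64
        stat = ((h - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.999, df=63)

    def test_peaked_marginal_matches_quadrature(self, toy_density):
        s = sample_density(toy_density, 50_000, 11)
        g = np.linspace(-np.pi, np.pi, 512, endpoint=False)
        p = np.exp(toy_density.log_pdf(g[:, None], g[None, :]))
        marg = p.sum(axis=1)
        marg /= marg.sum()
        # inverse-CDF draw from the quadrature marginal as the oracle
        rng = np.random.default_rng(12)
        cdf = np.cumsum(marg)
        oracle = g[np.searchsorted(cdf, rng.random(50_000))]
        assert ks_2samp(s[:, 0], oracle).statistic < 0.02
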