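"""Eigenvalue solver for the Fokker-Planck operator and its adjoint."""

import numpy as np
import pytest

from fpreduce import (build_spectral_grid, backward_flux,
                      init_spectrum_real_scan, track_eigenvalue,
                      find_spectrum, solve_eigenvalue, solve_adjoint,
                      eigenfunction, biorthonormalize, select_dominant,
                      stationary_mode, build_voltage_grid, solve_stationary,
                      spectral_quantities)
from fpreduce.spectral import coefficient_matrix, inner


@pytest.fixture(scope="module")
def sgrid(eif):
    return build_spectral_grid(eif, dV=0.02)


class TestCoefficientMatrix:
    def test_lambda_zero_first_row(self, eif):
        A = coefficient_matrix(-60.0, 0.0, 1.0, 4.0, eif)
        assert np.all(A[0] == 0.0)

    def test_real_for_real_lambda(self, eif):
        A = coefficient_matrix(-55.0, -0.3, 1.0, 4.0, eif)
        assert np.all(A.imag == 0.0)

    def test_threshold_exponential_contribution(self, eif):
        A = coefficient_matrix(eif.V_T, 0.0, 0.0, 4.0, eif)
        leak = -eif.g_L * (eif.V_T - eif.E_L) / eif.C
        g_at_VT = -A[1, 1] * 4.0 / 2.0
        assert g_at_VT - leak == pytest.approx(eif.g_L * eif.Delta_T / eif.C)


class TestBackwardFlux:
    def test_lambda_zero_is_always_a_root(self, eif, sgrid):
        for mu, sig in ((-1.0, 1.0), (1.5, 2.0), (3.5, 1.5)):
            assert abs(backward_flux(0.0, mu, sig, sgrid, eif)) < 1e-10

    def test_conjugate_symmetry(self, eif, sgrid):
        lam = -0.2 + 0.3j
        qa = backward_flux(lam, 1.0, 2.0, sgrid, eif)
        qb = backward_flux(lam.conjugate(), 1.0, 2.0, sgrid, eif)
        assert qa == pytest.approx(qb.conjugate(), rel=1e-12)

    def test_real_scan_sign_changes(self, eif, sgrid):
        """At hyperpolarized mean input the scan of q(V_lb) over real
        lambda changes sign between consecutive eigenvalues."""
        roots = init_spectrum_real_scan(-1.5, 2.0, sgrid, eif, n_eigs=4)
        assert len(roots) == 4
        assert np.all(roots < 0)
        assert np.all(np.diff(roots) < 0)          # sorted toward -inf
        assert len(np.unique(np.round(roots, 8))) == 4
        mids = 0.5 * (roots[:-1] + roots[1:])
        vals = [backward_flux(m, -1.5, 2.0, sgrid, eif).real for m in mids]
        signs = np.sign(vals)
        assert np.all(signs[:-1] != signs[1:])


class TestTracking:
    def test_lambda0_invariant_along_path(self, eif, sgrid):
        path = np.linspace(-1.0, 2.0, 7)
        lams = track_eigenvalue(0.0, path, 1.5, sgrid, eif)
        assert np.all(np.abs(lams) < 1e-8)

    def test_imaginary_part_grows_after_merge(self, eif, sgrid):
        """Past the real-to-complex transition the imaginary part of the
        dominant pair grows roughly linearly with the mean input."""
        path = np.arange(1.0, 3.51, 0.5)
        lams = np.array([select_dominant(find_spectrum(m, 1.5, sgrid,
                                                       eif))[0]
                         for m in path])
        im = np.abs(lams.imag)
        assert np.all(np.diff(im) > 0)
        slopes = np.diff(im) / 0.5
        assert slopes.max() / slopes.min() < 1.6   # roughly linear

    def test_diffusive_branch_stays_real_at_large_sigma(self, eif, sgrid):
        for mu in (-1.0, 0.5, 2.0):
            lams = find_spectrum(mu, 3.0, sgrid, eif, n_eigs=4)
            assert any(abs(l.imag) < 1e-9 for l in lams)

    def test_all_real_parts_negative(self, eif, sgrid):
        for mu, sig in ((-1.0, 1.0), (1.0, 2.0), (3.0, 1.0)):
            lams = find_spectrum(mu, sig, sgrid, eif)
            assert np.all(lams.real < 0)


class TestAdjoint:
    def test_stationary_adjoint_is_constant(self, eif, sgrid):
        psi, dps, res = solve_adjoint(0.0, 1.5, 2.0, sgrid, eif)
        assert np.max(np.abs(psi - 1.0)) < 1e-12
        assert res < 1e-12

    def test_conjugate_symmetry(self, eif, sgrid):
        lam = solve_eigenvalue(-0.1 + 0.3j, 1.5, 1.5, sgrid, eif)
        pa, _, _ = solve_adjoint(lam, 1.5, 1.5, sgrid, eif)
        pb, _, _ = solve_adjoint(lam.conjugate(), 1.5, 1.5, sgrid, eif)
        assert np.allclose(pa, pb.conjugate())

    def test_derivative_continuous_at_reset(self, eif, sgrid):
        """psi_1 has no kink at V_r (in contrast to phi_1): the one-sided
        finite-difference slopes agree there."""
        lams = find_spectrum(1.5, 1.5, sgrid, eif)
        lam1, _ = select_dominant(lams)
        psi, _, _ = solve_adjoint(lam1, 1.5, 1.5, sgrid, eif)
        k = sgrid.k_r
        h = sgrid.dV
        left = (psi[k] - psi[k - 1]) / h
        right = (psi[k + 1] - psi[k]) / h
        scale = np.abs(psi).max() / h
        assert abs(right - left) / scale < 1e-3
        # while the forward eigenfunction does kink at the reset
        sol = eigenfunction(lam1, 1.5, 1.5, sgrid, eif)
        phi = sol.phi
        dl = (phi[k] - phi[k - 1]) / h
        dr = (phi[k + 1] - phi[k]) / h
        assert abs(dr - dl) > 100 * abs(right - left)

    def test_rejects_non_eigenvalue(self, eif, sgrid):
        _, _, res = solve_adjoint(-0.123 + 0.05j, 1.5, 2.0, sgrid, eif)
        assert res > 1e-6


class TestBiorthonormality:
    def test_pair_normalization(self, eif, sgrid):
        lams = find_spectrum(2.0, 1.5, sgrid, eif)
        lam1, _ = select_dominant(lams)
        sol = biorthonormalize([eigenfunction(lam1, 2.0, 1.5, sgrid,
                                              eif)])[0]
        assert inner(sol.psi, sol.phi, sgrid.dV) == pytest.approx(1.0,
                                                                  abs=1e-8)

    def test_cross_orthogonality(self, eif):
        """<psi_n, phi_m> vanishes for n != m; the trapezoid quadrature
        converges to it at second order, so a fine grid is used."""
        fine = build_spectral_grid(eif, dV=0.005)
        lams = find_spectrum(2.0, 1.5, fine, eif, n_eigs=4)
        lam1, _ = select_dominant(lams)
        lam2 = [l for l in lams
                if abs(l - lam1) > 1e-6 and abs(l - lam1.conjugate()) > 1e-6
                ][0]
        s1 = biorthonormalize([eigenfunction(lam1, 2.0, 1.5, fine, eif)])[0]
        s2 = biorthonormalize([eigenfunction(lam2, 2.0, 1.5, fine, eif)])[0]
        assert abs(inner(s1.psi, s2.phi, fine.dV)) < 1e-4
        assert abs(inner(s1.psi,
                         stationary_mode(2.0, 1.5, fine, eif).phi,
                         fine.dV)) < 1e-4

    def test_joint_rescale_invariance(self, eif, sgrid):
        """f_n c_n is invariant under phi -> c phi, psi -> psi / c."""
        lams = find_spectrum(1.5, 2.0, sgrid, eif)
        lam1, _ = select_dominant(lams)
        sol = biorthonormalize([eigenfunction(lam1, 1.5, 2.0, sgrid,
                                              eif)])[0]
        c = 2.7 - 0.4j
        f_a = sol.q_phi[-1]
        psi_a = sol.psi
        f_b = (sol.q_phi * c)[-1]
        psi_b = sol.psi / c
        probe = stationary_mode(1.5, 2.0, sgrid, eif).phi
        prod_a = f_a * inner(psi_a, probe, sgrid.dV)
        prod_b = f_b * inner(psi_b, probe, sgrid.dV)
        assert prod_a == pytest.approx(prod_b, rel=1e-12)


class TestStationaryMode:
    def test_phi0_matches_finite_volume_density(self, eif, sgrid):
        """The lambda_0 eigenfunction reproduces the stationary density of
        the finite-volume solve after normalization."""
        mode = stationary_mode(1.5, 2.0, sgrid, eif)
        grid = build_voltage_grid(eif, dV=0.02)
        st = solve_stationary(1.5, 2.0, grid, eif)
        phi_interp = np.interp(grid.centers, sgrid.nodes, mode.phi.real)
        err = np.abs(phi_interp - st.p_inf) / st.p_inf.max()
        assert err.max() < 5e-3
        # the residual is the O(dV) smearing of the reinjection source
        # over the reset cell; away from that layer agreement is tight
        mask = np.abs(grid.centers - eif.V_r + 1.0) > 2.5
        assert err[mask].max() < 1e-3
        # and its flux at V_s is the stationary rate
        assert mode.q_phi[-1].real == pytest.approx(st.r_inf, rel=2e-3)


class TestSpectralQuantities:
    def test_conjugate_pair_products_real(self, eif):
        g = build_spectral_grid(eif, dV=0.05)
        q = spectral_quantities(2.0, 1.5, g, eif)
        assert q.lam2 == pytest.approx(q.lam1.conjugate())
        for fc in (q.f_cmu, q.f_csigma2, q.F_mu, q.F_sigma2):
            assert np.isfinite(fc)
        raw = q.f[0] * q.c_mu[0] + q.f[1] * q.c_mu[1]
        assert abs(raw.imag) < 1e-8

    def test_coupling_coefficient_dual_identity(self, eif):
        """c_1 = <d_mu psi_1, phi_0> equals -<psi_1, d_mu phi_0>
        (differentiating the orthogonality <psi_1, phi_0> = 0)."""
        g = build_spectral_grid(eif, dV=0.02)
        lams = find_spectrum(1.5, 2.0, g, eif)
        lam1, _ = select_dominant(lams)
        sol = biorthonormalize([eigenfunction(lam1, 1.5, 2.0, g, eif)])[0]
        d = 0.02
        psis = []
        for mq in (1.5 + d, 1.5 - d):
            lq = solve_eigenvalue(lam1, mq, 2.0, g, eif)
            psis.append(eigenfunction(lq, mq, 2.0, g, eif).psi)
        phi0 = stationary_mode(1.5, 2.0, g, eif)
        c_a = inner((psis[0] - psis[1]) / (2 * d), phi0.phi, g.dV)
        p_p = stationary_mode(1.5 + d, 2.0, g, eif).phi
        p_m = stationary_mode(1.5 - d, 2.0, g, eif).phi
        c_b = -inner(sol.psi, (p_p - p_m) / (2 * d), g.dV)
        assert abs(c_a - c_b) / abs(c_a) < 0.02

    def test_slow_pair_at_small_sigma_large_mu(self, eif):
        """Mean-driven, low-noise inputs have a slowly decaying regular
        pair: 1/|Re lambda_1| grows toward that corner."""
        g = build_spectral_grid(eif, dV=0.05)
        t_small = 1.0 / abs(select_dominant(
            find_spectrum(3.5, 1.0, g, eif))[0].real)
        t_big = 1.0 / abs(select_dominant(
            find_spectrum(3.5, 2.5, g, eif))[0].real)
        assert t_small > t_big
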