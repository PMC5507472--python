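"""Linear rate-response functions and semi-analytic filter fits.

The linear-nonlinear cascade models pass the synaptic input moments through
a linear temporal filter followed by the static nonlinearity r_inf.  The
true filters are proportional to the linear rate-response functions
R_mu(t), R_sigma(t) of the EIF population, computed here in the Fourier
domain: for each modulation frequency f one complex linear system — the
linearized Scharfetter-Gummel finite-volume operator about the stationary
solution — yields the complex rate response R^(f) per unit modulation of
the mean (or the standard deviation) of the input.

The normalized filter transforms D^(f) = R^(f) / (dr_inf/dx) are then
approximated: by a single exponential (time constant tau_mu, either from
the exact high-frequency asymptotics or by least squares over
f in [0, 1] kHz), by a damped oscillator (tau, omega; matched at the
frequencies where |Re D^| and |Im D^| peak), and, for the noise-intensity
channel, by an exponential with time constant tau_sigma, which collapses to
a delta filter when dr_inf/dsigma <= 0 (drift-dominated regime).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import least_squares, minimize_scalar

from .params import NeuronParams
from .fv import VoltageGrid, assemble_fv_operator
from .stationary import solve_stationary

log = logging.getLogger(__name__)

__all__ = [
    "ResponseSpectrum", "FilterParams", "default_frequency_grid",
    "linear_rate_response", "fit_exp_filter", "fit_dos_filter",
    "fit_sigma_filter", "lorentzian", "damped_oscillator_ft",
]


@dataclass
class ResponseSpectrum:
    """Complex rate responses on a frequency grid (f > 0, kHz)."""

    f: np.ndarray
    R_mu: np.ndarray        # kHz per unit mean modulation (mV/ms)
    R_sigma: np.ndarray     # kHz per unit sigma modulation (mV ms^-1/2)
    mu0: float
    sigma0: float
    #: DC limits of the two responses (computed at a vanishing frequency);
    #: equal to dr_inf/dmu and dr_inf/dsigma and better conditioned than
    #: finite differences of r_inf where the rate is exponentially small.
    R_mu_dc: float = np.nan
    R_sigma_dc: float = np.nan


@dataclass
class FilterParams:
    """Fitted filter parameters at one (mu, sigma) node."""

    tau_mu: float           # ms, exponential mean filter
    tau: float              # ms, damped-oscillator decay
    omega: float            # rad/ms, damped-oscillator frequency
    tau_sigma: float        # ms, sigma filter (0 => delta filter)

    @property
    def A_mu(self) -> float:
        return 1.0 / self.tau_mu

    @property
    def B_mu(self) -> float:
        return (1.0 + self.tau ** 2 * self.omega ** 2) / self.tau


def default_frequency_grid(n: int = 64, f_min: float = 1e-3,
                           f_max: float = 1.0) -> np.ndarray:
    """Log-spaced modulation frequencies in kHz; f = 0 is handled by the
    stationary derivative."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


def _generator_parts(grid: VoltageGrid, mu: float, sigma_sq: float,
                     neuron: NeuronParams):
    """(tridiagonal generator without reinjection, a_out) as sparse + float."""
    op = assemble_fv_operator(grid, mu, sigma_sq, neuron)
    N = grid.N_V
    A = sp.diags([op.lower[1:], op.diag, op.upper[:-1]], [-1, 0, 1],
                 format="csc")
    return A, op.a_out


def linear_rate_response(mu0: float, sigma0: float, f_grid: np.ndarray,
                         grid: VoltageGrid, neuron: NeuronParams,
                         d_mu: float = 1e-3,
                         d_sigma_sq: float = 1e-3) -> ResponseSpectrum:
    """Rate response to weak sinusoidal modulations of mu and of sigma.

    Solves, for each frequency, (i 2 pi f I - A0 - e^{-i 2 pi f T_ref} B0)
    p^ = (A1 + B1) p_inf where A is the finite-volume generator, B the
    reinjection coupling, and the subscript-1 parts are the parameter
    derivatives (by central differences of the assembly).  The response is
    the perturbed absorbing flux per unit modulation amplitude.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(np.diff(f_grid) <= 0) or np.any(f_grid <= 0):
        raise ValueError("f_grid must be strictly increasing and positive")
    f_solve = np.concatenate([[1e-6], f_grid])
    st = solve_stationary(mu0, sigma0, grid, neuron)
    p_inf = st.p_inf
    N = grid.N_V
    s0 = sigma0 ** 2
    A0, aout0 = _generator_parts(grid, mu0, s0, neuron)
    e_mr = np.zeros(N)
    e_mr[grid.m_r] = 1.0 / grid.dV

    responses = []
    for dpar, kind in ((d_mu, "mu"), (d_sigma_sq, "s2")):
        if kind == "mu":
            Ap, aoutp = _generator_parts(grid, mu0 + dpar, s0, neuron)
            Am, aoutm = _generator_parts(grid, mu0 - dpar, s0, neuron)
        else:
            Ap, aoutp = _generator_parts(grid, mu0, s0 + dpar, neuron)
            Am, aoutm = _generator_parts(grid, mu0, s0 - dpar, neuron)
        A1 = (Ap - Am) / (2.0 * dpar)
        da_out = (aoutp - aoutm) / (2.0 * dpar)
        src_base = A1 @ p_inf
        R = np.empty(len(f_solve), dtype=complex)
        for i, f in enumerate(f_solve):
            w = 2j * np.pi * f
            delay = np.exp(-w * neuron.T_ref)
            # reinjection couples the outflow back into the reset cell
            M = (sp.identity(N, format="csc") * w - A0
                 - delay * sp.csc_matrix(
                     (np.array([aout0 / grid.dV]),
                      (np.array([grid.m_r]), np.array([N - 1]))),
                     shape=(N, N)))
            rhs = src_base + delay * e_mr * (da_out * p_inf[-1])
            p_hat = spla.spsolve(M, rhs.astype(complex))
            R[i] = aout0 * p_hat[-1] + da_out * p_inf[-1]
        responses.append(R)
    R_mu = responses[0]
    # chain rule: response per unit sigma modulation = 2 sigma * per sigma^2
    R_sigma = responses[1] * (2.0 * sigma0)
    return ResponseSpectrum(f=f_grid, R_mu=R_mu[1:], R_sigma=R_sigma[1:],
                            mu0=mu0, sigma0=sigma0,
                            R_mu_dc=float(R_mu[0].real),
                            R_sigma_dc=float(R_sigma[0].real))


def lorentzian(f: np.ndarray, tau: float) -> np.ndarray:
    """Fourier transform of the normalized exponential filter e^{-t/tau}/tau."""
    return 1.0 / (1.0 + 2j * np.pi * f * tau)


def damped_oscillator_ft(f: np.ndarray, tau: float,
                         omega: float) -> np.ndarray:
    """Fourier transform of B e^{-t/tau} cos(omega t), B = (1+tau^2 w^2)/tau."""
    B = (1.0 + tau ** 2 * omega ** 2) / tau
    w = 2.0 * np.pi * f
    a = 1.0 / tau
    return 0.5 * B * (1.0 / (a + 1j * (w - omega))
                      + 1.0 / (a + 1j * (w + omega)))


def _lsq_tau(D_hat: np.ndarray, f: np.ndarray,
             tau_max: float = 100.0) -> float:
    """Least-squares Lorentzian fit on complex residuals over f in [0,1] kHz.

    Residuals are weighted by the local frequency spacing so the discrete
    sum approximates the continuous L2 misfit over the range regardless of
    how the (log-spaced) grid samples it.
    """
    sel = f <= 1.0
    wts = np.gradient(f[sel])

    def cost(log_tau: float) -> float:
        res = lorentzian(f[sel], np.exp(log_tau)) - D_hat[sel]
        return float(np.sum(wts * (res.real ** 2 + res.imag ** 2)))

    opt = minimize_scalar(cost, bounds=(np.log(1e-3), np.log(tau_max)),
                          method="bounded",
                          options={"xatol": 1e-12})
    return float(np.exp(opt.x))


def fit_exp_filter(spec: ResponseSpectrum, dmu_rinf: float | None = None,
                   neuron: NeuronParams | None = None,
                   mode: str = "least_squares",
                   r_inf: float | None = None) -> float:
    """Exponential mean-input filter time constant tau_mu.

    The DC normalization A_mu = 1/tau_mu holds in both modes.  The
    asymptotic mode matches the exact high-frequency limit
    R^(f) -> r_inf/(i 2 pi f Delta_T), giving
    tau_mu = Delta_T dr_inf/dmu / r_inf; the least-squares mode fits the
    Lorentzian to D^_mu = R^_mu / (dr_inf/dmu) over f in [0, 1] kHz.
    """
    if dmu_rinf is None:
        dmu_rinf = spec.R_mu_dc
    if dmu_rinf <= 0:
        raise ValueError("dr_inf/dmu must be positive for the mean filter")
    if mode == "asymptotic":
        if neuron is None or r_inf is None:
            raise ValueError("asymptotic mode needs neuron and r_inf")
        return float(neuron.Delta_T * dmu_rinf / r_inf)
    if mode != "least_squares":
        raise ValueError(f"unknown mode {mode!r}")
    return _lsq_tau(spec.R_mu / dmu_rinf, spec.f)


def fit_dos_filter(spec: ResponseSpectrum, dmu_rinf: float | None = None):
    """Damped-oscillator mean filter (tau, omega, B_mu).

    B_mu is fixed by the DC normalization; tau and omega minimize the
    mismatch of the damped-oscillator transform at the two frequencies
    where |Re D^_mu| and |Im D^_mu| peak (refined by local quadratic
    interpolation of the peak position).  A degenerate peak at the grid
    edge falls back to the exponential-equivalent fit with omega = 0.
    """
    if dmu_rinf is None:
        dmu_rinf = spec.R_mu_dc
    if dmu_rinf <= 0:
        raise ValueError("dr_inf/dmu must be positive")
    D_hat = spec.R_mu / dmu_rinf
    f = spec.f
    sel = f <= 1.0
    fs, Ds = f[sel], D_hat[sel]

    def refined_argmax(y: np.ndarray) -> tuple[int, float]:
        i = int(np.argmax(y))
        if 0 < i < len(y) - 1:
            # quadratic interpolation on log-f around the discrete peak
            x = np.log(fs[i - 1:i + 2])
            c = np.polyfit(x, y[i - 1:i + 2], 2)
            if c[0] < 0:
                return i, float(np.exp(-c[1] / (2 * c[0])))
        return i, float(fs[i])

    iR, fR = refined_argmax(np.abs(Ds.real))
    iI, fI = refined_argmax(np.abs(Ds.imag))
    edge = iR in (0, len(fs) - 1) or iI in (0, len(fs) - 1)
    tau0 = _lsq_tau(D_hat, f)
    if edge:
        log.debug("dos fit: peak at grid edge, falling back to omega=0")
        return tau0, 0.0, 1.0 / tau0

    targets = np.interp([fR, fI], fs, Ds)

    def resid(x):
        tau, omega = np.exp(x[0]), x[1]
        model = damped_oscillator_ft(np.array([fR, fI]), tau, omega)
        d = model - targets
        return [d[0].real, d[0].imag, d[1].real, d[1].imag]

    best = None
    for om0 in (2 * np.pi * fI, np.pi * fI, 4 * np.pi * fI):
        sol = least_squares(resid, [np.log(tau0), om0],
                            bounds=([np.log(1e-3), 0.0],
                                    [np.log(100.0), 50.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    tau = float(np.exp(best.x[0]))
    omega = float(best.x[1])
    if omega < 1e-6:
        omega = 0.0
    B_mu = (1.0 + tau ** 2 * omega ** 2) / tau
    return tau, omega, B_mu


def fit_sigma_filter(spec: ResponseSpectrum,
                     dsigma_rinf: float | None = None) -> float:
    """Noise-channel filter time constant tau_sigma.

    When dr_inf/dsigma <= 0 (large mean, small noise) the true filter has a
    negative high-frequency tail that an exponential cannot represent; the
    filter then degenerates to a delta, tau_sigma = 0.
    """
    if dsigma_rinf is None:
        dsigma_rinf = spec.R_sigma_dc
    if dsigma_rinf <= 0:
        return 0.0
    return _lsq_tau(spec.R_sigma / dsigma_rinf, spec.f)
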