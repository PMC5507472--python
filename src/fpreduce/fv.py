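"""Scharfetter-Gummel finite-volume solver for the Fokker-Planck model.

The membrane-voltage density p(V, t) of the mean-field limit obeys a
drift-diffusion (Fokker-Planck) equation on [V_lb, V_s] with a reflecting
boundary at V_lb, an absorbing boundary at V_s (spikes leave the domain
there) and reinjection of the exited flux at the reset voltage V_r after the
refractory period.  The domain is split into N_V equidistant cells; the flux
at each cell border uses the exponentially fitted Scharfetter-Gummel form,
which recovers centered differences for vanishing drift and the upwind flux
for drift-dominated borders.  Time stepping is implicit (backward Euler in
p) with operator coefficients frozen at the beginning of each step, so every
step solves one tridiagonal system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.linalg import solve_banded

from .params import NeuronParams, CouplingParams, SIGMA_FLOOR
from .signals import Signal
from .network import PopulationTrace

log = logging.getLogger(__name__)

__all__ = [
    "VoltageGrid", "FVOperator", "FPState", "build_voltage_grid",
    "sg_weights", "assemble_fv_operator", "fv_step", "flux_rate",
    "fv_operator_matrix", "run_fp", "gaussian_initial_density",
]


@dataclass(frozen=True)
class VoltageGrid:
    """Equidistant cell-centered grid on [V_lb, V_s] with reset cell m_r."""

    V_lb: float
    V_s: float
    N_V: int
    dV: float
    centers: np.ndarray
    borders: np.ndarray
    m_r: int


def build_voltage_grid(neuron: NeuronParams, N_V: int | None = None,
                       dV: float | None = None) -> VoltageGrid:
    """Build the finite-volume grid; specify either N_V or the spacing dV."""
    span = neuron.V_s - neuron.V_lb
    if N_V is None:
        if dV is None:
            dV = 0.028
        N_V = int(round(span / dV))
    if N_V < 10:
        raise ValueError("need at least 10 grid cells")
    if not (neuron.V_lb < neuron.V_r < neuron.V_s):
        raise ValueError("V_r must lie strictly inside (V_lb, V_s)")
    dV = span / N_V
    borders = neuron.V_lb + dV * np.arange(N_V + 1)
    centers = borders[:-1] + dV / 2.0
    m_r = min(int((neuron.V_r - neuron.V_lb) / dV), N_V - 1)
    return VoltageGrid(neuron.V_lb, neuron.V_s, N_V, dV, centers, borders, m_r)


def sg_weights(z):
    """Scharfetter-Gummel border weights (w_plus, w_minus).

    The border flux is q = (D/dV) [w_plus(z) p_left - w_minus(z) p_right]
    with Peclet number z = v dV / D; w_plus = z/(1-e^-z), w_minus = z/(e^z-1).
    Both reduce to 1 at z=0 (centered difference) and to the upwind weights
    (z, 0) or (0, -z) for large |z|.
    """
    z = np.asarray(z, dtype=float)
    wp = np.empty_like(z)
    wm = np.empty_like(z)
    small = np.abs(z) < 1e-8
    big_pos = z > 500.0
    big_neg = z < -500.0
    mid = ~(small | big_pos | big_neg)
    zs = z[small]
    wp[small] = 1.0 + zs / 2.0 + zs * zs / 12.0
    wm[small] = 1.0 - zs / 2.0 + zs * zs / 12.0
    zm = z[mid]
    wm[mid] = zm / np.expm1(zm)
    wp[mid] = wm[mid] + zm          # identity w_plus - w_minus = z
    wp[big_pos] = z[big_pos]
    wm[big_pos] = 0.0
    wp[big_neg] = 0.0
    wm[big_neg] = -z[big_neg]
    return wp, wm


@dataclass
class FVOperator:
    """Tridiagonal generator A (1/ms) with A p = dp/dt (without reinjection).

    ``lower``, ``diag``, ``upper`` are the bands of A; ``a_out`` is the
    outflow coefficient at V_s so that the emitted rate is a_out * p[-1].
    """

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    a_out: float
    v_borders: np.ndarray
    D: float
    grid: VoltageGrid


def assemble_fv_operator(grid: VoltageGrid, mu_tot: float,
                         sigma_tot_sq: float,
                         neuron: NeuronParams) -> FVOperator:
    """Assemble the Scharfetter-Gummel generator for frozen (mu, sigma^2)."""
    if sigma_tot_sq <= 0:
        raise ValueError("sigma_tot_sq must be positive")
    D = sigma_tot_sq / 2.0
    v = neuron.g(grid.borders) + mu_tot
    z = v * grid.dV / D
    wp, wm = sg_weights(z)
    aL = (D / grid.dV) * wp     # coefficient on the left cell of each border
    aR = (D / grid.dV) * wm     # coefficient on the right cell
    N = grid.N_V
    lower = np.zeros(N)
    diag = np.zeros(N)
    upper = np.zeros(N)
    # interior borders j = 1..N-1 between cells j-1 and j
    lower[1:] = aL[1:N] / grid.dV
    upper[:-1] = aR[1:N] / grid.dV
    diag[0] = -aL[1] / grid.dV
    diag[1:N - 1] = -(aR[1:N - 1] + aL[2:N]) / grid.dV
    a_out = aL[N] + aR[N]       # ghost-cell absorbing outflow, z*coth(z/2)*D/dV
    if v[N] <= 0:
        raise AssertionError("drift at the spike voltage must be positive "
                             "for the EIF (exponential current dominates)")
    diag[N - 1] = -(aR[N - 1] + a_out) / grid.dV
    return FVOperator(lower, diag, upper, a_out, v, D, grid)


@dataclass
class FPState:
    """Density per cell (1/mV), refractory rate queue, adaptation, delay."""

    p: np.ndarray
    r_queue: np.ndarray            # most recent rates, oldest first (kHz)
    mean_w: float = 0.0
    r_d: float = 0.0
    t: float = 0.0

    def refractory_mass(self, dt: float) -> float:
        """Probability mass currently in the refractory pipeline."""
        return float(self.r_queue.sum() * dt)

    def total_mass(self, dV: float, dt: float) -> float:
        return float(self.p.sum() * dV) + self.refractory_mass(dt)


def fv_step(state: FPState, op: FVOperator, dt: float,
            reinjected_rate: float) -> FPState:
    """One implicit Euler step (I - dt A) p^{n+1} = p^n + g.

    ``reinjected_rate`` is the spike rate of the step whose refractory period
    has just elapsed; its mass dt*r enters the reset cell.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    N = op.grid.N_V
    ab = np.zeros((3, N))
    ab[0, 1:] = -dt * op.upper[:-1]
    ab[1, :] = 1.0 - dt * op.diag
    ab[2, :-1] = -dt * op.lower[1:]
    rhs = state.p.copy()
    rhs[op.grid.m_r] += dt / op.grid.dV * reinjected_rate
    p_new = solve_banded((1, 1), ab, rhs)
    r_new = op.a_out * p_new[-1]
    queue = np.roll(state.r_queue, -1)
    queue[-1] = r_new
    return FPState(p=p_new, r_queue=queue, mean_w=state.mean_w,
                   r_d=state.r_d, t=state.t + dt)


def flux_rate(state: FPState, op: FVOperator) -> float:
    """Emitted rate r = a_out p_{N_V} with the operator's (frozen) drift."""
    return op.a_out * state.p[-1]


def fv_operator_matrix(grid: VoltageGrid, mu: float, sigma: float,
                       neuron: NeuronParams) -> sp.csc_matrix:
    """Sparse generator including instantaneous reinjection (T_ref = 0).

    The spectrum of this matrix approximates the Fokker-Planck operator's
    eigenvalues; used as an independent cross-check of the shooting solver.
    """
    op = assemble_fv_operator(grid, mu, sigma ** 2, neuron)
    N = grid.N_V
    A = sp.diags([op.lower[1:], op.diag, op.upper[:-1]], [-1, 0, 1],
                 format="lil")
    A[grid.m_r, N - 1] += op.a_out / grid.dV
    return A.tocsc()


def gaussian_initial_density(grid: VoltageGrid,
                             neuron: NeuronParams) -> np.ndarray:
    """Initial density Normal(V_r - dV0, (dV0/2)^2), truncated, normalized."""
    dV0 = neuron.V_T - neuron.V_r
    p0 = np.exp(-0.5 * ((grid.centers - (neuron.V_r - dV0)) / (dV0 / 2.0)) ** 2)
    p0 /= p0.sum() * grid.dV
    return p0


@njit(cache=False)
def _fp_kernel(n_steps, dt, dV, N, m_r, gv_b, Vc,
               mu_ext_arr, s2_ext_arr, JK, J2K,
               delay_code, tau_d, d_steps,
               a, b, E_w, tau_w, C, n_ref,
               p, w0, rd0, floor_sq):
    r_out = np.zeros(n_steps)
    V_out = np.zeros(n_steps)
    w_out = np.zeros(n_steps)
    rd_out = np.zeros(n_steps)
    mass_out = np.zeros(n_steps)
    r_hist = np.zeros(n_steps + n_ref + 1)
    rd_buf = np.zeros(max(d_steps, 1))
    w_mean = w0
    r_d = rd0
    aL = np.zeros(N + 1)
    aR = np.zeros(N + 1)
    low = np.zeros(N)
    dia = np.zeros(N)
    up = np.zeros(N)
    cp = np.zeros(N)
    rhs = np.zeros(N)
    err = 0
    for n in range(n_steps):
        mu_syn = mu_ext_arr[n] + JK * r_d
        s2 = s2_ext_arr[n] + J2K * r_d
        if s2 < floor_sq:
            err = 1
            break
        mu_tot = mu_syn - w_mean / C
        D = 0.5 * s2
        inv_dV = 1.0 / dV
        for j in range(N + 1):
            v = gv_b[j] + mu_tot
            z = v * dV / D
            if z > 500.0:
                wp = z
                wm = 0.0
            elif z < -500.0:
                wp = 0.0
                wm = -z
            elif -1e-8 < z < 1e-8:
                wp = 1.0 + 0.5 * z + z * z / 12.0
                wm = 1.0 - 0.5 * z + z * z / 12.0
            else:
                wm = z / np.expm1(z)
                wp = wm + z
            aL[j] = D * inv_dV * wp
            aR[j] = D * inv_dV * wm
        a_out = aL[N] + aR[N]
        # bands of (I - dt A)
        for m in range(N):
            if m == 0:
                dia[m] = 1.0 + dt * aL[1] * inv_dV
            elif m == N - 1:
                dia[m] = 1.0 + dt * (aR[N - 1] + a_out) * inv_dV
            else:
                dia[m] = 1.0 + dt * (aR[m] + aL[m + 1]) * inv_dV
            if m >= 1:
                low[m] = -dt * aL[m] * inv_dV
            if m < N - 1:
                up[m] = -dt * aR[m + 1] * inv_dV
        for m in range(N):
            rhs[m] = p[m]
        rein_idx = n + 1 - n_ref
        r_rein = r_hist[rein_idx + n_ref] if rein_idx >= 0 else 0.0
        rhs[m_r] += dt * inv_dV * r_rein
        # Thomas algorithm
        cp[0] = up[0] / dia[0]
        rhs[0] = rhs[0] / dia[0]
        for m in range(1, N):
            denom = dia[m] - low[m] * cp[m - 1]
            if m < N - 1:
                cp[m] = up[m] / denom
            rhs[m] = (rhs[m] - low[m] * rhs[m - 1]) / denom
        p[N - 1] = rhs[N - 1]
        for m in range(N - 2, -1, -1):
            p[m] = rhs[m] - cp[m] * p[m + 1]
        r_new = a_out * p[N - 1]
        r_hist[n + 1 + n_ref] = r_new
        psum = 0.0
        vsum = 0.0
        for m in range(N):
            psum += p[m]
            vsum += Vc[m] * p[m]
        V_mean = vsum / psum
        w_mean += dt * ((a * (V_mean - E_w) - w_mean) / tau_w + b * r_new)
        if delay_code == 0:
            r_d = r_new
        elif delay_code == 1:
            r_d += dt * (r_new - r_d) / tau_d
        else:
            r_d = rd_buf[n % d_steps]
            rd_buf[n % d_steps] = r_new
        r_out[n] = r_new
        V_out[n] = V_mean
        w_out[n] = w_mean
        rd_out[n] = r_d
        refmass = 0.0
        for k in range(n_ref):
            refmass += r_hist[n + 2 + k] * dt
        mass_out[n] = psum * dV + refmass
    return r_out, V_out, w_out, rd_out, mass_out, err


def run_fp(neuron: NeuronParams, coupling: CouplingParams,
           mu_ext: Signal, sigma_ext_sq: Signal,
           grid: VoltageGrid | None = None, dt: float = 0.05,
           p0: np.ndarray | None = None, w0: float = 0.0, rd0: float = 0.0):
    """Integrate the Fokker-Planck mean-field model.

    Per step: form mu_tot = mu_syn - <w>/C and sigma_tot^2 = sigma_syn^2,
    rebuild the Scharfetter-Gummel operator, take one implicit step with
    delayed reinjection (minimal refractory period of one step), read the
    rate off the absorbing flux and advance <w> and the delayed rate r_d
    with explicit Euler.  Returns (PopulationTrace at dt resolution, mass
    diagnostic array).
    """
    if grid is None:
        grid = build_voltage_grid(neuron)
    T = min(mu_ext.duration, sigma_ext_sq.duration)
    n_steps = int(round(T / dt))
    mu_arr = mu_ext.resample(dt, n_steps + 1).values[:n_steps]
    s2_arr = sigma_ext_sq.resample(dt, n_steps + 1).values[:n_steps]
    if p0 is None:
        p0 = gaussian_initial_density(grid, neuron)
    p = p0.astype(float).copy()
    delay_code = {"none": 0, "exponential": 1, "identical": 2}[
        coupling.delay_kind]
    d_steps = max(1, int(round(coupling.d / dt))) \
        if coupling.delay_kind == "identical" else 1
    n_ref = max(1, int(np.ceil(neuron.T_ref / dt)))
    gv_b = np.asarray(neuron.g(grid.borders), dtype=float)
    r, V, w, rd, mass, err = _fp_kernel(
        n_steps, dt, grid.dV, grid.N_V, grid.m_r, gv_b, grid.centers,
        mu_arr, s2_arr,
        coupling.J * coupling.K, coupling.J ** 2 * coupling.K,
        delay_code, coupling.tau_d, d_steps,
        neuron.a, neuron.b, neuron.E_w, neuron.tau_w, neuron.C, n_ref,
        p, w0, rd0, SIGMA_FLOOR ** 2)
    if err:
        raise ValueError("sigma_tot fell below the admissible floor "
                         f"({SIGMA_FLOOR} mV ms^-1/2)")
    trace = PopulationTrace(
        r=Signal(dt, dt, r), mean_V=Signal(dt, dt, V),
        mean_w=Signal(dt, dt, w))
    return trace, mass
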