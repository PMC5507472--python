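"""Time integration of the four reduced spike-rate models.

All four models share the population-averaged adaptation current
d<w>/dt = [a(<V>_inf - E_w) - <w>]/tau_w + b r and the delayed rate
dr_d/dt = (r - r_d)/tau_d (exponential delays; identical delays use a ring
buffer, no delays set r_d = r), and all evaluate their coefficients by
bilinear lookup in a precomputed QuantityTable:

* spec_1 — complex scalar ODE dr~/dt = lambda_1 (r~ - r_inf), r = Re r~,
  driven by the dominant Fokker-Planck eigenvalue at the total moments.
* spec_2 — real second-order ODE beta_2 r'' + beta_1 r' + beta_0 r =
  r_inf - r - beta_c with coefficients assembled from the two dominant
  eigenvalues and the spectral coupling scalars; requires twice
  differentiable inputs and T_ref = 0.  Negative excursions clamp r and r'
  to zero.
* LN_exp — exponential filters for mean and noise amplitude with time
  constants looked up at the effective moments, followed by r_inf.
* LN_dos — damped-oscillator mean filter (parameters at the total moments)
  with the same sigma filter and nonlinearity.

The default stepper is Heun (explicit trapezoid) at dt = 0.01 ms; explicit
Euler is available but needs smaller steps for the second-order models to
avoid oscillatory artifacts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import NeuronParams, CouplingParams
from .signals import Signal
from .network import PopulationTrace
from .tables import QuantityTable, SPECTRAL_NAMES

__all__ = [
    "run_spec1", "run_spec2", "run_lnexp", "run_lndos", "run_model",
    "step_mean_adaptation", "step_delayed_rate", "bin_average",
]


# ---------------------------------------------------------------------------
# small explicit steppers exposed for direct use and testing

def step_mean_adaptation(w: float, mean_V_inf: float, r: float,
                         neuron: NeuronParams, dt: float,
                         heun: bool = False) -> float:
    """One step of d<w>/dt = [a(<V>_inf - E_w) - <w>]/tau_w + b r."""
    if dt <= 0:
        raise ValueError("dt must be positive")

    def f(w_):
        return (neuron.a * (mean_V_inf - neuron.E_w) - w_) / neuron.tau_w \
            + neuron.b * r

    k1 = f(w)
    if not heun:
        return w + dt * k1
    return w + dt / 2.0 * (k1 + f(w + dt * k1))


def step_delayed_rate(r_d: float, r: float, tau_d: float, dt: float) -> float:
    """One Euler step of dr_d/dt = (r - r_d)/tau_d."""
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    return r_d + dt * (r - r_d) / tau_d


def bin_average(sig: Signal, bin_width: float) -> Signal:
    """Average a dt-resolution signal over consecutive bins of bin_width."""
    k = int(round(bin_width / sig.dt))
    n = (sig.values.size // k) * k
    vals = sig.values[:n].reshape(-1, k).mean(axis=1)
    return Signal(sig.t0 + (k - 1) * sig.dt / 2.0, bin_width, vals)


# ---------------------------------------------------------------------------
# numba helpers

@njit(cache=False, inline="always")
def _blerp(arr, mu, sig, mu0, dmu, sig0, dsig):
    n_mu, n_sig = arr.shape
    x = (mu - mu0) / dmu
    y = (sig - sig0) / dsig
    if x < 0.0:
        x = 0.0
    elif x > n_mu - 1.0:
        x = n_mu - 1.0
    if y < 0.0:
        y = 0.0
    elif y > n_sig - 1.0:
        y = n_sig - 1.0
    i = int(x)
    j = int(y)
    if i > n_mu - 2:
        i = n_mu - 2
    if j > n_sig - 2:
        j = n_sig - 2
    fx = x - i
    fy = y - j
    return ((1 - fx) * (1 - fy) * arr[i, j] + fx * (1 - fy) * arr[i + 1, j]
            + (1 - fx) * fy * arr[i, j + 1] + fx * fy * arr[i + 1, j + 1])


@njit(cache=False)
def _spec1_kernel(n_steps, dt, mu_ext, s2_ext, JK, J2K, delay_code, tau_d,
                  d_steps, a, b, E_w, tau_w, C,
                  mu0, dmu, sig0, dsig, A_l1re, A_l1im, A_rinf, A_vinf,
                  heun, rr0, ri0):
    r_out = np.zeros(n_steps)
    w_out = np.zeros(n_steps)
    v_out = np.zeros(n_steps)
    rd_buf = np.zeros(max(d_steps, 1))
    rr, ri, wm, rd = rr0, ri0, 0.0, rr0
    d_rr = d_ri = d_wm = d_rd = 0.0
    v_now = 0.0
    for n in range(n_steps):
        # stage derivatives at (t_n, state)
        for stage in range(2 if heun else 1):
            if stage == 0:
                s_rr, s_ri, s_wm, s_rd = rr, ri, wm, rd
                idx = n
            else:
                s_rr, s_ri = rr + dt * d_rr, ri + dt * d_ri
                s_wm, s_rd = wm + dt * d_wm, rd + dt * d_rd
                idx = n + 1
            mu_syn = mu_ext[idx] + JK * s_rd
            s2 = s2_ext[idx] + J2K * s_rd
            mu_tot = mu_syn - s_wm / C
            sig_tot = np.sqrt(s2)
            l1re = _blerp(A_l1re, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            l1im = _blerp(A_l1im, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            rinf = _blerp(A_rinf, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            vinf = _blerp(A_vinf, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            ro = s_rr if s_rr > 0.0 else 0.0
            e_rr = s_rr - rinf
            k_rr = l1re * e_rr - l1im * s_ri
            k_ri = l1re * s_ri + l1im * e_rr
            k_wm = (a * (vinf - E_w) - s_wm) / tau_w + b * ro
            if delay_code == 1:
                k_rd = (ro - s_rd) / tau_d
            else:
                k_rd = 0.0
            if stage == 0:
                d_rr, d_ri, d_wm, d_rd = k_rr, k_ri, k_wm, k_rd
                v_now = vinf
            else:
                d_rr = 0.5 * (d_rr + k_rr)
                d_ri = 0.5 * (d_ri + k_ri)
                d_wm = 0.5 * (d_wm + k_wm)
                d_rd = 0.5 * (d_rd + k_rd)
        r_out[n] = rr if rr > 0.0 else 0.0
        w_out[n] = wm
        v_out[n] = v_now
        rr += dt * d_rr
        ri += dt * d_ri
        wm += dt * d_wm
        if delay_code == 0:
            rd = rr if rr > 0.0 else 0.0
        elif delay_code == 1:
            rd += dt * d_rd
        else:
            rd = rd_buf[n % d_steps]
            rd_buf[n % d_steps] = rr if rr > 0.0 else 0.0
    return r_out, w_out, v_out


@njit(cache=False)
def _spec2_kernel(n_steps, dt, mu_ext, s2_ext, dmu_ext, d2mu_ext, ds2_ext,
                  d2s2_ext, KJ, KJ2, delay_code, tau_d, d_steps,
                  a, b, E_w, tau_w, C,
                  mu0, dmu, sig0, dsig,
                  A_l1re, A_l1im, A_l2re, A_l2im, A_fcmu, A_fcs2, A_Fmu,
                  A_Fs2, A_rinf, A_vinf, A_dmur, A_ds2r, A_dmuv, A_ds2v,
                  heun, r_init):
    r_out = np.zeros(n_steps)
    w_out = np.zeros(n_steps)
    rd_buf = np.zeros(max(d_steps, 1))
    v_out = np.zeros(n_steps)
    r, dr, wm, rd = r_init, 0.0, 0.0, r_init
    coupled = KJ != 0.0 or KJ2 != 0.0
    d_r = d_dr = d_wm = d_rd = 0.0
    v_now = 0.0
    for n in range(n_steps):
        for stage in range(2 if heun else 1):
            if stage == 0:
                s_r, s_dr, s_wm, s_rd = r, dr, wm, rd
                idx = n
            else:
                s_r, s_dr = r + dt * d_r, dr + dt * d_dr
                s_wm, s_rd = wm + dt * d_wm, rd + dt * d_rd
                idx = n + 1
            mu_syn = mu_ext[idx] + KJ * s_rd
            s2 = s2_ext[idx] + KJ2 * s_rd
            mu_tot = mu_syn - s_wm / C
            sig_tot = np.sqrt(s2)
            l1 = complex(_blerp(A_l1re, mu_tot, sig_tot, mu0, dmu, sig0, dsig),
                         _blerp(A_l1im, mu_tot, sig_tot, mu0, dmu, sig0, dsig))
            l2 = complex(_blerp(A_l2re, mu_tot, sig_tot, mu0, dmu, sig0, dsig),
                         _blerp(A_l2im, mu_tot, sig_tot, mu0, dmu, sig0, dsig))
            D = (1.0 / (l1 * l2)).real
            T = (1.0 / l1 + 1.0 / l2).real
            M = _blerp(A_dmur, mu_tot, sig_tot, mu0, dmu, sig0, dsig) \
                + _blerp(A_fcmu, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            S = _blerp(A_ds2r, mu_tot, sig_tot, mu0, dmu, sig0, dsig) \
                + _blerp(A_fcs2, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            Fmu = _blerp(A_Fmu, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            Fs2 = _blerp(A_Fs2, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            rinf = _blerp(A_rinf, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            vinf = _blerp(A_vinf, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            dmuv = _blerp(A_dmuv, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            ds2v = _blerp(A_ds2v, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            R = D * M * KJ + D * S * KJ2
            Hmu = T * M + D * M * a * dmuv / (tau_w * C) - D * Fmu
            Hs2 = T * S + D * M * a * ds2v / (tau_w * C) - D * Fs2
            beta2 = D
            beta1 = -T + D * M * b / C
            beta0 = -D * M * b / (tau_w * C) - (b / C) * Hmu
            beta_c = 0.0
            if coupled and delay_code == 1:
                beta1 -= R / tau_d
                cterm = (KJ * Hmu + KJ2 * Hs2) / tau_d + R / (tau_d * tau_d)
                beta0 += cterm
                beta_c += -s_rd * cterm
            adapt = (a * (vinf - E_w) - s_wm)
            beta_c += -(d2mu_ext[idx] + adapt / (tau_w * tau_w * C)) * D * M \
                - d2s2_ext[idx] * D * S \
                + (dmu_ext[idx] - adapt / (tau_w * C)) * Hmu \
                + ds2_ext[idx] * Hs2
            ro = s_r if s_r > 0.0 else 0.0
            k_r = s_dr
            k_dr = (rinf - beta_c - beta1 * s_dr - (beta0 + 1.0) * s_r) / beta2
            k_wm = adapt / tau_w + b * ro
            k_rd = (ro - s_rd) / tau_d if delay_code == 1 else 0.0
            if stage == 0:
                d_r, d_dr, d_wm, d_rd = k_r, k_dr, k_wm, k_rd
                v_now = vinf
            else:
                d_r = 0.5 * (d_r + k_r)
                d_dr = 0.5 * (d_dr + k_dr)
                d_wm = 0.5 * (d_wm + k_wm)
                d_rd = 0.5 * (d_rd + k_rd)
        r_out[n] = r if r > 0.0 else 0.0
        w_out[n] = wm
        v_out[n] = v_now
        r += dt * d_r
        dr += dt * d_dr
        wm += dt * d_wm
        if delay_code == 0:
            rd = r if r > 0.0 else 0.0
        elif delay_code == 1:
            rd += dt * d_rd
        else:
            rd = rd_buf[n % d_steps]
            rd_buf[n % d_steps] = r if r > 0.0 else 0.0
        if r < 0.0:
            r = 0.0
            dr = 0.0
    return r_out, w_out, v_out


@njit(cache=False)
def _lnexp_kernel(n_steps, dt, mu_ext, s2_ext, JK, J2K, delay_code, tau_d,
                  d_steps, a, b, E_w, tau_w, C,
                  mu0, dmu, sig0, dsig, A_tmu, A_tsig, A_rinf, A_vinf,
                  heun):
    r_out = np.zeros(n_steps)
    w_out = np.zeros(n_steps)
    rd_buf = np.zeros(max(d_steps, 1))
    mu_f = mu_ext[0]
    sig_f = np.sqrt(s2_ext[0])
    wm = 0.0
    rd = _blerp(A_rinf, mu_f, sig_f, mu0, dmu, sig0, dsig)
    v_out = np.zeros(n_steps)
    d_muf = d_sigf = d_wm = d_rd = 0.0
    r_now = rd
    v_now = 0.0
    for n in range(n_steps):
        for stage in range(2 if heun else 1):
            if stage == 0:
                s_muf, s_sigf, s_wm, s_rd = mu_f, sig_f, wm, rd
                idx = n
            else:
                s_muf, s_sigf = mu_f + dt * d_muf, sig_f + dt * d_sigf
                s_wm, s_rd = wm + dt * d_wm, rd + dt * d_rd
                idx = n + 1
            mu_syn = mu_ext[idx] + JK * s_rd
            sig_syn = np.sqrt(s2_ext[idx] + J2K * s_rd)
            mu_eff = s_muf - s_wm / C
            sig_eff = s_sigf
            tmu = _blerp(A_tmu, mu_eff, sig_eff, mu0, dmu, sig0, dsig)
            tsig = _blerp(A_tsig, mu_eff, sig_eff, mu0, dmu, sig0, dsig)
            rinf = _blerp(A_rinf, mu_eff, sig_eff, mu0, dmu, sig0, dsig)
            vinf = _blerp(A_vinf, mu_eff, sig_eff, mu0, dmu, sig0, dsig)
            if tmu < dt:
                tmu = dt
            if tsig < dt:
                tsig = dt
            k_muf = (mu_syn - s_muf) / tmu
            k_sigf = (sig_syn - s_sigf) / tsig
            k_wm = (a * (vinf - E_w) - s_wm) / tau_w + b * rinf
            k_rd = (rinf - s_rd) / tau_d if delay_code == 1 else 0.0
            if stage == 0:
                d_muf, d_sigf, d_wm, d_rd = k_muf, k_sigf, k_wm, k_rd
                r_now = rinf
                v_now = vinf
            else:
                d_muf = 0.5 * (d_muf + k_muf)
                d_sigf = 0.5 * (d_sigf + k_sigf)
                d_wm = 0.5 * (d_wm + k_wm)
                d_rd = 0.5 * (d_rd + k_rd)
        r_out[n] = r_now
        w_out[n] = wm
        v_out[n] = v_now
        mu_f += dt * d_muf
        sig_f += dt * d_sigf
        wm += dt * d_wm
        if delay_code == 0:
            rd = r_now
        elif delay_code == 1:
            rd += dt * d_rd
        else:
            rd = rd_buf[n % d_steps]
            rd_buf[n % d_steps] = r_now
    return r_out, w_out, v_out


@njit(cache=False)
def _lndos_kernel(n_steps, dt, mu_ext, s2_ext, dmu_ext, JK, J2K, delay_code,
                  tau_d, d_steps, a, b, E_w, tau_w, C,
                  mu0, dmu, sig0, dsig, A_tau, A_om, A_tsig, A_rinf, A_vinf,
                  heun):
    r_out = np.zeros(n_steps)
    w_out = np.zeros(n_steps)
    rd_buf = np.zeros(max(d_steps, 1))
    mu_f = mu_ext[0]
    dmu_f = 0.0
    sig_f = np.sqrt(s2_ext[0])
    wm = 0.0
    rd = _blerp(A_rinf, mu_f, sig_f, mu0, dmu, sig0, dsig)
    r_prev = rd
    rd_prev = rd
    v_out = np.zeros(n_steps)
    d_muf = d_dmuf = d_sigf = d_wm = d_rd = 0.0
    r_now = rd
    v_now = 0.0
    for n in range(n_steps):
        for stage in range(2 if heun else 1):
            if stage == 0:
                s_muf, s_dmuf, s_sigf = mu_f, dmu_f, sig_f
                s_wm, s_rd = wm, rd
                idx = n
            else:
                s_muf, s_dmuf = mu_f + dt * d_muf, dmu_f + dt * d_dmuf
                s_sigf = sig_f + dt * d_sigf
                s_wm, s_rd = wm + dt * d_wm, rd + dt * d_rd
                idx = n + 1
            mu_syn = mu_ext[idx] + JK * s_rd
            s2_syn = s2_ext[idx] + J2K * s_rd
            sig_syn = np.sqrt(s2_syn)
            mu_tot = mu_syn - s_wm / C
            sig_tot = sig_syn
            mu_eff = s_muf - s_wm / C
            sig_eff = s_sigf
            tau = _blerp(A_tau, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            om = _blerp(A_om, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            tsig = _blerp(A_tsig, mu_tot, sig_tot, mu0, dmu, sig0, dsig)
            rinf = _blerp(A_rinf, mu_eff, sig_eff, mu0, dmu, sig0, dsig)
            vinf = _blerp(A_vinf, mu_eff, sig_eff, mu0, dmu, sig0, dsig)
            if tau < dt:
                tau = dt
            if tsig < dt:
                tsig = dt
            if delay_code == 1 and (JK != 0.0 or J2K != 0.0):
                mu_syn_dot = dmu_ext[idx] + JK * (rinf - s_rd) / tau_d
            elif delay_code == 2 and JK != 0.0:
                # identical delays: d mu_syn/dt needs the delayed rate's
                # derivative r'(t - d), estimated from the ring buffer
                mu_syn_dot = dmu_ext[idx] + JK * (rd - rd_prev) / dt
            elif JK != 0.0:
                mu_syn_dot = dmu_ext[idx] + JK * (rinf - r_prev) / dt
            else:
                mu_syn_dot = dmu_ext[idx]
            B = (1.0 + tau * tau * om * om) / tau
            k_muf = s_dmuf
            k_dmuf = B * (mu_syn / tau + mu_syn_dot) \
                - 2.0 / tau * s_dmuf - (1.0 / (tau * tau) + om * om) * s_muf
            k_sigf = (sig_syn - s_sigf) / tsig
            k_wm = (a * (vinf - E_w) - s_wm) / tau_w + b * rinf
            k_rd = (rinf - s_rd) / tau_d if delay_code == 1 else 0.0
            if stage == 0:
                d_muf, d_dmuf, d_sigf = k_muf, k_dmuf, k_sigf
                d_wm, d_rd = k_wm, k_rd
                r_now = rinf
                v_now = vinf
            else:
                d_muf = 0.5 * (d_muf + k_muf)
                d_dmuf = 0.5 * (d_dmuf + k_dmuf)
                d_sigf = 0.5 * (d_sigf + k_sigf)
                d_wm = 0.5 * (d_wm + k_wm)
                d_rd = 0.5 * (d_rd + k_rd)
        r_out[n] = r_now
        w_out[n] = wm
        v_out[n] = v_now
        r_prev = r_now
        mu_f += dt * d_muf
        dmu_f += dt * d_dmuf
        sig_f += dt * d_sigf
        wm += dt * d_wm
        rd_prev = rd
        if delay_code == 0:
            rd = r_now
        elif delay_code == 1:
            rd += dt * d_rd
        else:
            rd = rd_buf[n % d_steps]
            rd_buf[n % d_steps] = r_now
    return r_out, w_out, v_out


# ---------------------------------------------------------------------------
# wrappers

def _prepare(table: QuantityTable, mu_ext: Signal, sigma_ext_sq: Signal,
             coupling: CouplingParams, dt: float, need_derivs: bool):
    T = min(mu_ext.duration, sigma_ext_sq.duration)
    n_steps = int(round(T / dt))
    mu = mu_ext.resample(dt, n_steps + 1).values
    s2 = sigma_ext_sq.resample(dt, n_steps + 1).values
    delay_code = {"none": 0, "exponential": 1, "identical": 2}[
        coupling.delay_kind]
    d_steps = max(1, int(round(coupling.d / dt))) \
        if coupling.delay_kind == "identical" else 1
    g = table.grid
    base = (n_steps, dt, mu, s2)
    cpl = (coupling.J * coupling.K, coupling.J ** 2 * coupling.K,
           delay_code, coupling.tau_d, d_steps)
    gridp = (g.mu_grid[0], g.d_mu, g.sigma_grid[0], g.d_sigma)
    if need_derivs:
        dmu = np.gradient(mu, dt, edge_order=2)
        d2mu = np.gradient(dmu, dt, edge_order=2)
        ds2 = np.gradient(s2, dt, edge_order=2)
        d2s2 = np.gradient(ds2, dt, edge_order=2)
        return base, cpl, gridp, (dmu, d2mu, ds2, d2s2)
    return base, cpl, gridp, None


def _adapt(neuron: NeuronParams):
    return (neuron.a, neuron.b, neuron.E_w, neuron.tau_w, neuron.C)


def _trace(r, w, v, dt) -> PopulationTrace:
    return PopulationTrace(r=Signal(0.0, dt, r), mean_V=Signal(0.0, dt, v),
                           mean_w=Signal(0.0, dt, w))


def run_spec1(table: QuantityTable, mu_ext: Signal, sigma_ext_sq: Signal,
              coupling: CouplingParams, neuron: NeuronParams,
              dt: float = 0.01, stepper: str = "heun") -> PopulationTrace:
    table.require(("lam1_re", "lam1_im", "r_inf", "mean_V_inf"))
    base, cpl, gridp, _ = _prepare(table, mu_ext, sigma_ext_sq, coupling,
                                   dt, False)
    a = table.arrays
    from .tables import lookup
    r0 = lookup(table, base[2][0], np.sqrt(base[3][0]), ("r_inf",))["r_inf"]
    r, w, v = _spec1_kernel(*base, *cpl, *_adapt(neuron), *gridp,
                            a["lam1_re"], a["lam1_im"], a["r_inf"],
                            a["mean_V_inf"], stepper == "heun", r0, 0.0)
    return _trace(r, w, v, dt)


def run_spec2(table: QuantityTable, mu_ext: Signal, sigma_ext_sq: Signal,
              coupling: CouplingParams, neuron: NeuronParams,
              dt: float = 0.01, stepper: str = "heun") -> PopulationTrace:
    if neuron.T_ref > 0:
        raise ValueError("a nonzero refractory period is not supported by "
                         "the spec_2 model")
    if coupling.K > 0 and coupling.J != 0.0 \
            and coupling.delay_kind != "exponential":
        raise ValueError("coupled spec_2 integration implements the "
                         "exponential-delay coefficient set")
    table.require(SPECTRAL_NAMES + ("r_inf", "mean_V_inf", "d_mu_r_inf",
                                    "d_sigma2_r_inf", "d_mu_V_inf",
                                    "d_sigma2_V_inf"))
    base, cpl, gridp, derivs = _prepare(table, mu_ext, sigma_ext_sq,
                                        coupling, dt, True)
    a = table.arrays
    from .tables import lookup
    r0 = lookup(table, base[2][0], np.sqrt(base[3][0]), ("r_inf",))["r_inf"]
    r, w, v = _spec2_kernel(*base, *derivs, *cpl, *_adapt(neuron), *gridp,
                         a["lam1_re"], a["lam1_im"], a["lam2_re"],
                         a["lam2_im"], a["f_cmu"], a["f_csigma2"],
                         a["F_mu"], a["F_sigma2"], a["r_inf"],
                         a["mean_V_inf"], a["d_mu_r_inf"], a["d_sigma2_r_inf"],
                         a["d_mu_V_inf"], a["d_sigma2_V_inf"],
                         stepper == "heun", r0)
    return _trace(r, w, v, dt)


def run_lnexp(table: QuantityTable, mu_ext: Signal, sigma_ext_sq: Signal,
              coupling: CouplingParams, neuron: NeuronParams,
              dt: float = 0.01, stepper: str = "heun") -> PopulationTrace:
    table.require(("tau_mu", "tau_sigma", "r_inf", "mean_V_inf"))
    base, cpl, gridp, _ = _prepare(table, mu_ext, sigma_ext_sq, coupling,
                                   dt, False)
    a = table.arrays
    r, w, v = _lnexp_kernel(*base, *cpl, *_adapt(neuron), *gridp,
                            a["tau_mu"], a["tau_sigma"], a["r_inf"],
                            a["mean_V_inf"], stepper == "heun")
    return _trace(r, w, v, dt)


def run_lndos(table: QuantityTable, mu_ext: Signal, sigma_ext_sq: Signal,
              coupling: CouplingParams, neuron: NeuronParams,
              dt: float = 0.01, stepper: str = "heun") -> PopulationTrace:
    table.require(("tau", "omega", "tau_sigma", "r_inf", "mean_V_inf"))
    base, cpl, gridp, derivs = _prepare(table, mu_ext, sigma_ext_sq,
                                        coupling, dt, True)
    a = table.arrays
    r, w, v = _lndos_kernel(*base[:4], derivs[0], *cpl, *_adapt(neuron),
                            *gridp,
                            a["tau"], a["omega"], a["tau_sigma"], a["r_inf"],
                            a["mean_V_inf"], stepper == "heun")
    return _trace(r, w, v, dt)


_RUNNERS = {"spec1": run_spec1, "spec2": run_spec2, "lnexp": run_lnexp,
            "lndos": run_lndos}


def run_model(name: str, table: QuantityTable, mu_ext: Signal,
              sigma_ext_sq: Signal, coupling: CouplingParams,
              neuron: NeuronParams, dt: float = 0.01,
              stepper: str = "heun") -> PopulationTrace:
    """Run one reduced model by name ('spec1', 'spec2', 'lnexp', 'lndos')."""
    try:
        runner = _RUNNERS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from "
                         f"{sorted(_RUNNERS)}") from None
    return runner(table, mu_ext, sigma_ext_sq, coupling, neuron, dt=dt,
                  stepper=stepper)


def match_initial_moments(V_samples: np.ndarray, neuron: NeuronParams,
                          candidates: list[tuple[float, float]],
                          dV: float = 0.1) -> tuple[float, float]:
    """Initial (mu_f, sigma_f) whose stationary density best matches a
    voltage sample, by minimizing the Kolmogorov-Smirnov statistic.

    ``candidates`` is a list of (mu, sigma) pairs to search (e.g. grid
    nodes); returns the pair whose stationary membrane-voltage CDF is
    closest to the empirical CDF of ``V_samples``.
    """
    from .fv import build_voltage_grid
    from .stationary import solve_stationary

    grid = build_voltage_grid(neuron, dV=dV)
    V_sorted = np.sort(np.asarray(V_samples, dtype=float))
    emp = np.arange(1, V_sorted.size + 1) / V_sorted.size
    best = None
    for mu, sig in candidates:
        st = solve_stationary(mu, sig, grid, neuron)
        cdf = np.cumsum(st.p_inf) * grid.dV
        cdf /= cdf[-1]
        model_cdf = np.interp(V_sorted, grid.centers, cdf,
                              left=0.0, right=1.0)
        ks = float(np.max(np.abs(model_cdf - emp)))
        if best is None or ks < best[0]:
            best = (ks, (mu, sig))
    return best[1]
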