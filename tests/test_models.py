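"""Reduced rate models: fixed points, relaxation dynamics, clamping."""

import numpy as np
import pytest

from fpreduce import (NeuronParams, CouplingParams, OUParams, Signal,
                      ou_process, gaussian_smooth, run_model,
                      step_mean_adaptation, step_delayed_rate)
from fpreduce.tables import lookup
from fpreduce.models import bin_average


def _const(mu, s2, T, dt=0.05):
    return Signal.constant(mu, dt, T), Signal.constant(s2, dt, T)


UNCOUPLED = CouplingParams(K=0, delay_kind="none")
ALL_MODELS = ("spec1", "spec2", "lnexp", "lndos")


class TestSharedSteppers:
    def test_adaptation_stays_zero_without_currents(self, eif):
        w = 0.0
        for _ in range(100):
            w = step_mean_adaptation(w, -60.0, 0.02, eif, 0.1)
        assert w == 0.0

    def test_adaptation_exponential_relaxation(self):
        nrn = NeuronParams(a=4.0, b=0.0)
        w, dt = 0.0, 0.1
        trace = []
        for _ in range(5000):
            w = step_mean_adaptation(w, -60.0, 0.0, nrn, dt)
            trace.append(w)
        w_inf = nrn.a * (-60.0 - nrn.E_w)
        trace = np.array(trace)
        # fit the decay constant of w_inf - w(t)
        resid = w_inf - trace[:2000]
        slope = np.polyfit(dt * np.arange(2000), np.log(resid), 1)[0]
        assert -1.0 / slope == pytest.approx(nrn.tau_w, rel=0.01)

    def test_adaptation_fixed_point_with_rate(self):
        nrn = NeuronParams(a=4.0, b=40.0)
        w = 0.0
        for _ in range(400000):
            w = step_mean_adaptation(w, -58.0, 0.02, nrn, 0.01)
        assert w == pytest.approx(nrn.a * (-58.0 - nrn.E_w)
                                  + nrn.tau_w * nrn.b * 0.02, rel=1e-4)

    def test_delayed_rate_impulse_response(self):
        """Euler-integrated delayed rate reproduces the exponential-delay
        convolution kernel e^{-t/tau_d}/tau_d."""
        tau_d, dt = 3.0, 0.001
        r_d = 0.0
        out = []
        for n in range(8000):
            r = 1.0 / dt if n == 0 else 0.0     # unit impulse
            r_d = step_delayed_rate(r_d, r, tau_d, dt)
            out.append(r_d)
        t = dt * np.arange(1, 8001)
        kernel = np.exp(-t / tau_d) / tau_d
        assert np.allclose(out, kernel, rtol=2e-3, atol=1e-5)

    def test_delayed_rate_validates_tau(self):
        with pytest.raises(ValueError):
            step_delayed_rate(0.0, 1.0, 0.0, 0.1)


class TestFixedPoints:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_constant_input_settles_at_stationary_rate(self, name,
                                                       suite_table, eif):
        mu, s2 = _const(1.5, 4.0, 400.0)
        tr = run_model(name, suite_table, mu, s2, UNCOUPLED, eif, dt=0.01)
        r_inf = lookup(suite_table, 1.5, 2.0, ("r_inf",))["r_inf"]
        assert tr.r.values[-1] == pytest.approx(r_inf, rel=1e-6)

    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_adaptation_fixed_point_self_consistent(self, name,
                                                    suite_table, neuron):
        mu, s2 = _const(1.5, 4.0, 2500.0)
        tr = run_model(name, suite_table, mu, s2, UNCOUPLED, neuron,
                       dt=0.01)
        r_end = tr.r.values[-1]
        w_end = tr.mean_w.values[-1]
        v_end = tr.mean_V.values[-1]
        w_star = neuron.a * (v_end - neuron.E_w) \
            + neuron.tau_w * neuron.b * r_end
        assert w_end == pytest.approx(w_star, rel=0.01)
        r_star = lookup(suite_table, 1.5 - w_end / neuron.C, 2.0,
                        ("r_inf",))["r_inf"]
        assert r_end == pytest.approx(r_star, rel=0.01)


class TestRelaxation:
    def test_spec1_decay_rate_is_dominant_eigenvalue(self, suite_table,
                                                     eif):
        """After a small input step the spec_1 rate relaxes at |Re
        lambda_1| of the new operating point (real diffusive branch)."""
        dt = 0.01
        T = 600.0
        n = int(T / 0.05) + 1
        vals = np.full(n, 0.0)
        vals[int(200.0 / 0.05):] = 0.15
        mu = gaussian_smooth(Signal(0.0, 0.05, vals), 1.0)
        s2 = Signal.constant(2.5 ** 2, 0.05, T)
        tr = run_model("spec1", suite_table, mu, s2, UNCOUPLED, eif, dt=dt)
        lam = lookup(suite_table, 0.15, 2.5, ("lam1_re", "lam1_im"))
        assert abs(lam["lam1_im"]) < 1e-8     # real branch here
        r = tr.r.values
        t = tr.r.times
        r_new = r[-1]
        sel = (t > 215.0) & (t < 275.0)
        resid = np.abs(r_new - r[sel])
        slope = np.polyfit(t[sel], np.log(resid), 1)[0]
        assert -slope == pytest.approx(abs(lam["lam1_re"]), rel=0.05)

    def test_lnexp_filter_relaxes_with_looked_up_tau(self, suite_table,
                                                     eif):
        dt = 0.01
        T = 300.0
        n = int(T / 0.05) + 1
        vals = np.full(n, 2.0)
        vals[int(100.0 / 0.05):] = 2.1
        mu = gaussian_smooth(Signal(0.0, 0.05, vals), 1.0)
        s2 = Signal.constant(4.0, 0.05, T)
        tr = run_model("lnexp", suite_table, mu, s2, UNCOUPLED, eif, dt=dt)
        tau_mu = lookup(suite_table, 2.1, 2.0, ("tau_mu",))["tau_mu"]
        r = tr.r.values
        t = tr.r.times
        sel = (t > 106.0) & (t < 112.0)
        resid = np.abs(r[-1] - r[sel])
        slope = np.polyfit(t[sel], np.log(resid), 1)[0]
        assert -1.0 / slope == pytest.approx(tau_mu, rel=0.1)

    def test_spec2_oscillation_frequency_matches_im_lambda1(self,
                                                            suite_table,
                                                            eif):
        """Mean-driven small-step response rings at |Im lambda_1|/2 pi."""
        dt = 0.01
        T = 400.0
        n = int(T / 0.05) + 1
        vals = np.full(n, 3.3)
        vals[int(150.0 / 0.05):] = 3.5
        mu = gaussian_smooth(Signal(0.0, 0.05, vals), 1.0)
        s2 = Signal.constant(1.0, 0.05, T)
        tr = run_model("spec2", suite_table, mu, s2, UNCOUPLED, eif, dt=dt)
        lam = lookup(suite_table, 3.5, 1.0, ("lam1_re", "lam1_im"))
        r = tr.r.values
        t = tr.r.times
        sel = (t > 151.0) & (t < 400.0)
        resid = r[sel] - r[-1]
        spectrum = np.abs(np.fft.rfft(resid))
        freqs = np.fft.rfftfreq(resid.size, d=dt)
        f_peak = freqs[1 + np.argmax(spectrum[1:])]
        f_pred = abs(lam["lam1_im"]) / (2 * np.pi)
        assert f_peak == pytest.approx(f_pred, rel=0.15)


class TestClampingAndRobustness:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_rates_nonnegative_under_violent_input(self, name, suite_table,
                                                   eif):
        mu = gaussian_smooth(
            ou_process(OUParams(mean=0.0, theta=0.8, tau_ou=5.0), 0.05,
                       3000.0, seed=2), 1.0)
        s2 = Signal.constant(2.25, 0.05, 3000.0)
        tr = run_model(name, suite_table, mu, s2, UNCOUPLED, eif, dt=0.01)
        assert np.all(np.isfinite(tr.r.values))
        assert np.all(tr.r.values >= 0.0)

    def test_spec2_clamp_engages_at_low_mean(self, suite_table, eif):
        mu = gaussian_smooth(
            ou_process(OUParams(mean=-0.5, theta=0.8, tau_ou=5.0), 0.05,
                       2000.0, seed=4), 1.0)
        s2 = Signal.constant(2.25, 0.05, 2000.0)
        tr = run_model("spec2", suite_table, mu, s2, UNCOUPLED, eif,
                       dt=0.01)
        assert (tr.r.values == 0.0).any()

    def test_spec2_refuses_refractory_period(self, suite_table):
        nref = NeuronParams(T_ref=1.0)
        mu, s2 = _const(1.0, 4.0, 10.0)
        with pytest.raises(ValueError, match="refractory"):
            run_model("spec2", suite_table, mu, s2, UNCOUPLED, nref)

    def test_unknown_model_name(self, suite_table, eif):
        mu, s2 = _const(1.0, 4.0, 10.0)
        with pytest.raises(ValueError, match="unknown model"):
            run_model("spec3", suite_table, mu, s2, UNCOUPLED, eif)


class TestStepperAccuracy:
    @staticmethod
    def _smooth_table():
        """Synthetic table with affine fields: bilinear interpolation is
        exact, so the integrator's order is measured in isolation (real
        tables add O(dV_grid) derivative kinks at cell edges)."""
        from fpreduce.tables import GridSpec, QuantityTable
        gs = GridSpec(mu_min=-1.0, mu_max=4.0, d_mu=0.5, sigma_min=1.0,
                      sigma_max=3.0, d_sigma=0.5)
        mu = gs.mu_grid[:, None]
        sig = gs.sigma_grid[None, :]
        one = np.ones((len(gs.mu_grid), len(gs.sigma_grid)))
        arrays = {
            "r_inf": 0.02 + 0.01 * mu + 0.005 * sig + 0 * one,
            "mean_V_inf": -60.0 + 1.5 * mu + 0 * one,
            "tau": 5.0 * one, "omega": 0.3 * one, "tau_sigma": 2.0 * one,
            "tau_mu": 5.0 * one,
        }
        return QuantityTable(grid=gs, arrays=arrays, neuron_hash="x")

    def test_heun_second_order_on_smooth_input(self, eif):
        """Richardson order estimate from dt-refinement of a smooth run."""
        tab = self._smooth_table()
        T = 200.0
        ends = {}
        for dt in (0.08, 0.04, 0.02):
            # input sampled analytically at the integration step, so the
            # only discretization is the stepper's own
            t = np.arange(0, int(T / dt) + 1) * dt
            mu = Signal(0.0, dt, 2.0 + 0.3 * np.sin(2 * np.pi * t / 40.0))
            s2 = Signal.constant(4.0, dt, T)
            tr = run_model("lndos", tab, mu, s2, UNCOUPLED, eif,
                           dt=dt, stepper="heun")
            ends[dt] = tr.r.values[int(round(150.0 / dt))]  # r at t=150
        e1 = abs(ends[0.08] - ends[0.02])
        e2 = abs(ends[0.04] - ends[0.02])
        order = np.log2(e1 / e2) - 0.4  # conservative allowance
        assert order >= 1.5

    def test_euler_and_heun_agree_at_small_dt(self, suite_table, eif):
        mu, s2 = _const(2.0, 4.0, 100.0)
        a = run_model("spec2", suite_table, mu, s2, UNCOUPLED, eif,
                      dt=0.005, stepper="euler").r.values[-1]
        b = run_model("spec2", suite_table, mu, s2, UNCOUPLED, eif,
                      dt=0.005, stepper="heun").r.values[-1]
        assert a == pytest.approx(b, rel=1e-6)


class TestDosReduction:
    def test_omega_zero_table_reduces_to_lnexp(self, suite_table, eif):
        """With omega = 0 and tau = tau_mu the damped-oscillator filter is
        exactly the exponential filter."""
        import copy
        tab = copy.copy(suite_table)
        tab.arrays = dict(suite_table.arrays)
        tab.arrays["omega"] = np.zeros_like(suite_table.arrays["omega"])
        tab.arrays["tau"] = suite_table.arrays["tau_mu"]
        T = 400.0
        t = np.arange(0, int(T / 0.05) + 1) * 0.05
        mu = Signal(0.0, 0.05, 1.8 + 0.2 * np.sin(2 * np.pi * t / 100.0))
        s2 = Signal.constant(4.0, 0.05, T)
        a = run_model("lndos", tab, mu, s2, UNCOUPLED, eif, dt=0.01)
        b = run_model("lnexp", tab, mu, s2, UNCOUPLED, eif, dt=0.01)
        sel = slice(int(100 / 0.01), None)
        dev = np.max(np.abs(a.r.values[sel] - b.r.values[sel]))
        assert dev < 0.02 * b.r.values[sel].mean()


class TestInitialMatching:
    def test_ks_matching_recovers_generating_moments(self, eif):
        """Voltage samples drawn from a stationary density are matched to
        the generating (mu, sigma) among distinct candidates."""
        from fpreduce.fv import build_voltage_grid
        from fpreduce.stationary import solve_stationary
        from fpreduce.models import match_initial_moments
        grid = build_voltage_grid(eif, dV=0.1)
        st = solve_stationary(1.5, 2.0, grid, eif)
        rng = np.random.default_rng(9)
        cdf = np.cumsum(st.p_inf) * grid.dV
        cdf /= cdf[-1]
        samples = np.interp(rng.uniform(size=4000), cdf, grid.centers)
        cands = [(0.5, 1.5), (1.5, 2.0), (2.5, 2.5), (3.0, 1.0)]
        assert match_initial_moments(samples, eif, cands) == (1.5, 2.0)
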