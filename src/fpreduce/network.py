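"""Monte-Carlo simulation of a sparsely coupled aEIF population.

This is the ground truth against which the Fokker-Planck model and the
low-dimensional rate models are benchmarked: N adaptive exponential
integrate-and-fire neurons, each driven by an independent realization of the
common external noise statistics, coupled by delta-current pulses of
amplitude J from K random presynaptic partners with distributed propagation
delays.  The stochastic dynamics are integrated with the Euler-Maruyama
scheme; spike delivery uses a per-neuron ring buffer after rounding each
connection delay to the nearest step (error at most dt/2, far below the mean
delay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import NeuronParams, CouplingParams
from .signals import Signal

__all__ = ["SpikeRaster", "PopulationTrace", "simulate_network", "bin_rate"]


@dataclass
class SpikeRaster:
    """Spike events (neuron index, time in ms), sorted by time."""

    neuron: np.ndarray
    time: np.ndarray
    T: float
    complete: bool = True

    def __len__(self) -> int:
        return self.time.size

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.neuron, self.time]),
                   delimiter="\t", header="neuron_id\ttime_ms", comments="",
                   fmt=("%d", "%.6f"))


@dataclass
class PopulationTrace:
    """Population averages on one binning grid: rate (kHz), voltage, w."""

    r: Signal
    mean_V: Signal
    mean_w: Signal


@njit(cache=False, fastmath=True)
def _sim_kernel(n_steps, N, dt, mu_arr, sig_arr,
                gL_C, E_L, D_T, V_T, V_s, V_r, C, a, b, E_w, tau_w,
                tref_steps, V, w,
                use_coupling, J, out_ptr, out_tgt, out_slot, buf,
                bin_steps, bin_counts, v_sum, v_cnt, w_sum,
                spikes_i, spikes_t, cap, seed):
    np.random.seed(seed)
    n_slots = buf.shape[0]
    ref = np.zeros(N, dtype=np.int64)
    inv_C = 1.0 / C
    inv_tw = 1.0 / tau_w
    inv_DT = 1.0 / D_T
    cur = 0
    nsp = 0
    overflow = False
    for n in range(n_steps):
        mu = mu_arr[n]
        sq = sig_arr[n] * np.sqrt(dt)
        b_idx = n // bin_steps
        vs = 0.0
        ws = 0.0
        vc = 0
        xi = np.random.standard_normal(N)
        for i in range(N):
            if ref[i] > 0:
                ref[i] -= 1
                ws += w[i]
                continue
            Vi = V[i]
            arg = (Vi - V_T) * inv_DT
            if arg > 20.0:
                arg = 20.0
            drift = gL_C * (E_L - Vi) + gL_C * D_T * np.exp(arg) \
                - w[i] * inv_C + mu
            dV = dt * drift + sq * xi[i]
            if use_coupling:
                dV += buf[cur, i]
            w[i] += dt * (a * (Vi - E_w) - w[i]) * inv_tw
            Vi += dV
            if Vi >= V_s:
                if nsp < cap:
                    spikes_i[nsp] = i
                    # midpoint convention: the spike occurred during step n
                    spikes_t[nsp] = (n + 0.5) * dt
                else:
                    overflow = True
                nsp += 1
                bin_counts[b_idx] += 1
                Vi = V_r
                w[i] += b
                ref[i] = tref_steps
                if use_coupling:
                    for k in range(out_ptr[i], out_ptr[i + 1]):
                        buf[(cur + out_slot[k]) % n_slots, out_tgt[k]] += J
            V[i] = Vi
            vs += Vi
            vc += 1
            ws += w[i]
        w_sum[b_idx] += ws
        v_sum[b_idx] += vs
        v_cnt[b_idx] += vc
        if use_coupling:
            for i in range(N):
                buf[cur, i] = 0.0
            cur = (cur + 1) % n_slots
    return nsp, overflow


def _build_connectivity(N: int, coupling: CouplingParams, dt: float,
                        rng: np.random.Generator):
    """Fixed in-degree K, partners uniform without replacement, no self."""
    K = coupling.K
    in_src = np.empty((N, K), dtype=np.int64)
    for i in range(N):
        picks = rng.choice(N - 1, size=K, replace=False)
        picks[picks >= i] += 1
        in_src[i] = picks
    if coupling.delay_kind == "exponential":
        delays = rng.exponential(coupling.tau_d, size=(N, K))
        max_delay = 10.0 * coupling.tau_d
        delays = np.minimum(delays, max_delay)
    elif coupling.delay_kind == "identical":
        delays = np.full((N, K), coupling.d)
    else:
        delays = np.zeros((N, K))
    slots = np.maximum(1, np.rint(delays / dt).astype(np.int64))
    n_slots = int(slots.max()) + 2
    # invert: outgoing adjacency of each presynaptic neuron
    counts = np.zeros(N, dtype=np.int64)
    np.add.at(counts, in_src.ravel(), 1)
    out_ptr = np.zeros(N + 1, dtype=np.int64)
    np.cumsum(counts, out=out_ptr[1:])
    out_tgt = np.empty(N * K, dtype=np.int64)
    out_slot = np.empty(N * K, dtype=np.int64)
    fill = out_ptr[:-1].copy()
    for i in range(N):
        for k in range(K):
            j = in_src[i, k]
            out_tgt[fill[j]] = i
            out_slot[fill[j]] = slots[i, k]
            fill[j] += 1
    return out_ptr, out_tgt, out_slot, n_slots


def simulate_network(neuron: NeuronParams, coupling: CouplingParams,
                     mu_ext: Signal, sigma_ext_sq: Signal,
                     N: int, dt: float, seed: int,
                     bin_width: float = 1.0,
                     spike_cap_rate: float = 0.1):
    """Simulate the aEIF network and return (SpikeRaster, PopulationTrace).

    The two input signals must share a uniform grid covering the run; they
    are resampled to the simulation step internally.  V_i(0) is drawn from
    Normal(V_r - dV, (dV/2)^2) with dV = V_T - V_r, w_i(0) = 0.  The run is
    fully reproducible for a given seed.
    """
    if N < 1 or dt <= 0:
        raise ValueError("need N >= 1 and dt > 0")
    if coupling.K >= N and coupling.K > 0:
        raise ValueError("in-degree K must be smaller than N")
    T = min(mu_ext.duration, sigma_ext_sq.duration)
    n_steps = int(round(T / dt))
    bin_steps = int(round(bin_width / dt))
    n_steps = (n_steps // bin_steps) * bin_steps
    n_bins = n_steps // bin_steps

    mu_arr = mu_ext.resample(dt, n_steps + 1).values[:n_steps]
    s2 = sigma_ext_sq.resample(dt, n_steps + 1).values[:n_steps]
    if np.any(s2 < 0):
        raise ValueError("sigma_ext^2 must be nonnegative")
    sig_arr = np.sqrt(s2)

    rng = np.random.default_rng(seed)
    dV0 = neuron.V_T - neuron.V_r
    V = rng.normal(neuron.V_r - dV0, dV0 / 2.0, size=N)
    V = np.minimum(V, neuron.V_s - 1e-6)
    w = np.zeros(N)

    use_coupling = coupling.K > 0 and coupling.J != 0.0
    if use_coupling:
        out_ptr, out_tgt, out_slot, n_slots = _build_connectivity(
            N, coupling, dt, rng)
        buf = np.zeros((n_slots, N))
    else:
        out_ptr = np.zeros(N + 1, dtype=np.int64)
        out_tgt = np.zeros(0, dtype=np.int64)
        out_slot = np.zeros(0, dtype=np.int64)
        buf = np.zeros((1, N))

    cap = max(10000, int(spike_cap_rate * N * T))
    spikes_i = np.empty(cap, dtype=np.int64)
    spikes_t = np.empty(cap, dtype=np.float64)
    bin_counts = np.zeros(n_bins, dtype=np.int64)
    v_sum = np.zeros(n_bins)
    v_cnt = np.zeros(n_bins, dtype=np.int64)
    w_sum = np.zeros(n_bins)

    tref_steps = int(np.ceil(neuron.T_ref / dt)) if neuron.T_ref > 0 else 0
    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
    nsp, overflow = _sim_kernel(
        n_steps, N, dt, mu_arr, sig_arr,
        neuron.g_L / neuron.C, neuron.E_L, neuron.Delta_T, neuron.V_T,
        neuron.V_s, neuron.V_r, neuron.C, neuron.a, neuron.b, neuron.E_w,
        neuron.tau_w, tref_steps, V, w,
        use_coupling, coupling.J, out_ptr, out_tgt, out_slot, buf,
        bin_steps, bin_counts, v_sum, v_cnt, w_sum,
        spikes_i, spikes_t, cap, kernel_seed)
    if overflow:
        warnings.warn("spike raster truncated at capacity; binned statistics "
                      "remain exact", stacklevel=2)
    nrec = min(nsp, cap)
    raster = SpikeRaster(spikes_i[:nrec].copy(), spikes_t[:nrec].copy(),
                         T=n_steps * dt, complete=not overflow)

    r_vals = bin_counts / (N * bin_width)
    with np.errstate(invalid="ignore"):
        v_bins = np.where(v_cnt > 0, v_sum / np.maximum(v_cnt, 1), np.nan)
    # carry the previous value forward if all neurons were refractory
    for k in range(1, n_bins):
        if not np.isfinite(v_bins[k]):
            v_bins[k] = v_bins[k - 1]
    w_bins = w_sum / (N * bin_steps)
    t0 = bin_width / 2.0
    trace = PopulationTrace(
        r=Signal(t0, bin_width, r_vals),
        mean_V=Signal(t0, bin_width, v_bins),
        mean_w=Signal(t0, bin_width, w_bins),
    )
    return raster, trace


def bin_rate(raster: SpikeRaster, N: int, bin_width: float,
             T: float | None = None) -> Signal:
    """Population rate r_N(t_k) = count in [t_k, t_k + dT) / (N dT), in kHz."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if T is None:
        T = raster.T
    n_bins = max(1, int(round(T / bin_width)))
    counts, _ = np.histogram(raster.time, bins=n_bins,
                             range=(0.0, n_bins * bin_width))
    return Signal(bin_width / 2.0, bin_width, counts / (N * bin_width))
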