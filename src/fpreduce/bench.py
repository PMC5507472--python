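"""Benchmark harness: reduced models against the aEIF network ground truth.

One smoothed Ornstein-Uhlenbeck realization of the external input moments is
shared by the network simulation, the Fokker-Planck solver and every reduced
model; reproduction accuracy is quantified by the Pearson correlation rho
and the RMS distance between the 1-ms binned population rate of the network
and each model's rate, after discarding an initial transient (the models'
initial conditions are not matched).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .params import NeuronParams, CouplingParams, OUParams
from .signals import Signal, ou_process, gaussian_smooth, clamp_variance_floor
from .network import simulate_network
from .fv import run_fp, build_voltage_grid
from .models import run_model, bin_average
from .metrics import pearson_rho, rms_distance
from .tables import QuantityTable

log = logging.getLogger(__name__)

__all__ = ["BenchmarkInputs", "ModelMetrics", "MetricsReport",
           "make_inputs", "compare_models"]


@dataclass
class BenchmarkInputs:
    """The shared input realization, at simulation resolution."""

    mu_ext: Signal
    sigma_ext_sq: Signal


@dataclass
class ModelMetrics:
    rho: float | None
    d_rms: float
    rate_mean: float
    rate_std: float
    failed: str | None = None


@dataclass
class MetricsReport:
    per_model: dict[str, ModelMetrics]
    rho_input_output: float | None
    rate_mean_net: float
    rate_std_net: float
    n_samples: int
    runtime_s: dict[str, float] = field(default_factory=dict)


def make_inputs(mu_ou: OUParams, sigma_sq_ou: OUParams | None,
                sigma_ext_sq: float | None, T: float, dt: float,
                seed: int) -> BenchmarkInputs:
    """Smoothed OU mean input plus either constant or OU noise intensity."""
    mu = gaussian_smooth(ou_process(mu_ou, dt, T, seed), mu_ou.sigma_t)
    if sigma_sq_ou is not None:
        s2 = gaussian_smooth(ou_process(sigma_sq_ou, dt, T, seed + 1),
                             sigma_sq_ou.sigma_t)
        s2 = clamp_variance_floor(s2)
    else:
        if sigma_ext_sq is None:
            raise ValueError("need either an OU process or a constant "
                             "for sigma_ext^2")
        s2 = Signal.constant(sigma_ext_sq, dt, T)
    return BenchmarkInputs(mu_ext=mu, sigma_ext_sq=s2)


def compare_models(neuron: NeuronParams, coupling: CouplingParams,
                   inputs: BenchmarkInputs, table: QuantityTable | None,
                   models=("lnexp", "lndos", "spec1", "spec2"),
                   N: int = 10000, dt_net: float = 0.05,
                   dt_model: float = 0.01, bin_width: float = 1.0,
                   transient: float = 1000.0, seed: int = 0,
                   fp_dV: float = 0.1, fp_dt: float = 0.05) -> MetricsReport:
    """Run the network and the requested models on one shared realization.

    ``models`` may include "fp" for the Fokker-Planck reference.  Model
    failures are caught and flagged; the report then covers the rest.
    """
    times: dict[str, float] = {}
    t0 = time.time()
    _, net = simulate_network(neuron, coupling, inputs.mu_ext,
                              inputs.sigma_ext_sq, N=N, dt=dt_net,
                              seed=seed, bin_width=bin_width)
    times["network"] = time.time() - t0
    keep = net.r.times >= transient
    r_net = net.r.values[keep]
    n_bins = r_net.size

    def binned(trace) -> np.ndarray:
        rb = bin_average(trace.r, bin_width)
        vals = rb.values
        k = int(round(transient / bin_width))
        return vals[k:k + n_bins]

    per: dict[str, ModelMetrics] = {}
    for name in models:
        t0 = time.time()
        try:
            if name == "fp":
                grid = build_voltage_grid(neuron, dV=fp_dV)
                trace, _ = run_fp(neuron, coupling, inputs.mu_ext,
                                  inputs.sigma_ext_sq, grid=grid, dt=fp_dt)
            else:
                trace = run_model(name, table, inputs.mu_ext,
                                  inputs.sigma_ext_sq, coupling, neuron,
                                  dt=dt_model)
            r_mod = binned(trace)
            if r_mod.size != r_net.size:
                m = min(r_mod.size, r_net.size)
                r_mod, r_cmp = r_mod[:m], r_net[:m]
            else:
                r_cmp = r_net
            if r_mod.std() < 1e-5 * (abs(r_mod.mean()) + 1e-12):
                rho = None      # constant trace: correlation undefined
            else:
                try:
                    rho = pearson_rho(r_cmp, r_mod)
                except ValueError:
                    rho = None
            per[name] = ModelMetrics(
                rho=rho, d_rms=rms_distance(r_cmp, r_mod),
                rate_mean=float(r_mod.mean()), rate_std=float(r_mod.std()))
        except Exception as exc:     # pragma: no cover - defensive
            log.warning("model %s failed: %s", name, exc)
            per[name] = ModelMetrics(rho=None, d_rms=np.nan,
                                     rate_mean=np.nan, rate_std=np.nan,
                                     failed=str(exc))
        times[name] = time.time() - t0

    mu_binned = bin_average(
        inputs.mu_ext.resample(dt_model), bin_width).values
    k = int(round(transient / bin_width))
    mu_b = mu_binned[k:k + n_bins]
    try:
        rho_io = pearson_rho(r_net[:mu_b.size], mu_b)
    except ValueError:
        rho_io = None
    return MetricsReport(per_model=per, rho_input_output=rho_io,
                         rate_mean_net=float(r_net.mean()),
                         rate_std_net=float(r_net.std()),
                         n_samples=n_bins, runtime_s=times)
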