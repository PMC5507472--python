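"""Steady-state quantities of the detached EIF population.

For frozen input moments (mu, sigma) the stationary density p_inf, spike
rate r_inf and mean voltage <V>_inf of an uncoupled EIF population solve the
stationary finite-volume system with reinjection.  Rather than marching the
PDE to its fixed point, the bordered linear system (flux balance for each
cell, the reinjected rate as an explicit unknown, and the normalization
row sum(p) dV + r T_ref = 1) is solved directly.  These quantities form the
static nonlinearity of every reduced model and are precomputed on a
(mu, sigma) grid together with their derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import NeuronParams, SIGMA_FLOOR
from .fv import VoltageGrid, assemble_fv_operator

__all__ = [
    "StationaryResult", "solve_stationary", "stationary_derivatives",
    "spike_shape_mean_voltage",
]


@dataclass
class StationaryResult:
    p_inf: np.ndarray       # density per cell, 1/mV
    r_inf: float            # kHz
    mean_V_inf: float       # mV, non-refractory average
    refractory_mass: float  # r_inf * T_ref
    grid: VoltageGrid


def solve_stationary(mu: float, sigma: float, grid: VoltageGrid,
                     neuron: NeuronParams) -> StationaryResult:
    """Stationary finite-volume solution at frozen (mu, sigma).

    Solves A p + (r/dV) e_{m_r} = 0 with the ghost-cell outflow r implied by
    the flux balance and the normalization sum(p) dV + r T_ref = 1.
    """
    if sigma < SIGMA_FLOOR:
        raise ValueError(f"sigma below admissible floor {SIGMA_FLOOR}")
    op = assemble_fv_operator(grid, mu, sigma ** 2, neuron)
    N = grid.N_V
    A = sp.lil_matrix((N + 1, N + 1))
    A[np.arange(N), np.arange(N)] = op.diag
    A[np.arange(1, N), np.arange(N - 1)] = op.lower[1:]
    A[np.arange(N - 1), np.arange(1, N)] = op.upper[:-1]
    A[grid.m_r, N] = 1.0 / grid.dV
    A[N, :N] = grid.dV
    A[N, N] = neuron.T_ref
    rhs = np.zeros(N + 1)
    rhs[N] = 1.0
    x = spla.spsolve(A.tocsc(), rhs)
    p = x[:N]
    r = float(x[N])
    if not np.isfinite(r) or r < -1e-12:
        raise RuntimeError("stationary solve failed to converge")
    p = np.where(p < 0, 0.0, p)
    r = max(r, 0.0)
    mass = p.sum() * grid.dV
    mean_V = float(np.dot(grid.centers, p) / p.sum())
    return StationaryResult(p_inf=p, r_inf=r, mean_V_inf=mean_V,
                            refractory_mass=r * neuron.T_ref, grid=grid)


def stationary_derivatives(mu_grid: np.ndarray, sigma_grid: np.ndarray,
                           fields: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Finite-difference derivatives of gridded quantities.

    ``fields`` maps names ("r_inf", "mean_V_inf") to arrays of shape
    (n_mu, n_sigma).  Central differences interiorly, one-sided at the
    edges; sigma^2-derivatives follow from the chain rule
    d/d(sigma^2) = d/d(sigma) / (2 sigma).
    """
    if len(mu_grid) < 3 or len(sigma_grid) < 3:
        raise ValueError("need at least 3 grid points per axis")
    out = {}
    for name, arr in fields.items():
        d_mu = np.gradient(arr, mu_grid, axis=0, edge_order=2)
        d_sig = np.gradient(arr, sigma_grid, axis=1, edge_order=2)
        out[f"d_mu_{name}"] = d_mu
        out[f"d_sigma_{name}"] = d_sig
        out[f"d_sigma2_{name}"] = d_sig / (2.0 * sigma_grid[None, :])
    return out


def spike_shape_mean_voltage(res: StationaryResult, neuron: NeuronParams,
                             enabled: bool = True) -> float:
    """Mean voltage including the linear spike-downswing trajectory.

    With the spike-shape extension the refractory mass traverses V linearly
    from V_s to V_r, so it contributes its time average (V_r + V_s)/2:
    <V>_inf = integral(v p_inf) + (1 - integral(p_inf)) (V_r + V_s)/2.
    Without it the non-refractory mean is returned.
    """
    if not enabled:
        return res.mean_V_inf
    mass = res.p_inf.sum() * res.grid.dV
    vint = float(np.dot(res.grid.centers, res.p_inf) * res.grid.dV)
    return vint + (1.0 - mass) * (neuron.V_r + neuron.V_s) / 2.0
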