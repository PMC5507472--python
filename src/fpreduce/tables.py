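"""Precomputation of all (mu, sigma)-dependent quantities and lookup.

Every reduced model evaluates its coefficients at time-varying total or
effective input moments.  All of those coefficients depend on the
parameters of the detached EIF membrane only, so they are computed once on
a rectangular (mu, sigma) grid and bilinearly interpolated during time
integration.  Changing input, coupling or adaptation parameters never
requires a recompute.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import h5py
import numpy as np

from .params import NeuronParams, SIGMA_FLOOR
from .fv import build_voltage_grid
from .stationary import solve_stationary, stationary_derivatives
from .spectral import (build_spectral_grid, find_spectrum, select_dominant,
                       pair_quantities, solve_eigenvalue)
from .cascade import (default_frequency_grid, linear_rate_response,
                      fit_exp_filter, fit_dos_filter, fit_sigma_filter)

log = logging.getLogger(__name__)

__all__ = ["GridSpec", "QuantityTable", "precompute_quantities", "lookup",
           "save_table", "load_table"]

_VERSION = "fpreduce-table-1"

STATIONARY_NAMES = (
    "r_inf", "mean_V_inf", "d_mu_r_inf", "d_sigma_r_inf", "d_sigma2_r_inf",
    "d_mu_V_inf", "d_sigma2_V_inf",
)
SPECTRAL_NAMES = (
    "lam1_re", "lam1_im", "lam2_re", "lam2_im",
    "f_cmu", "f_csigma2", "F_mu", "F_sigma2",
)
CASCADE_NAMES = ("tau_mu", "tau_sigma", "tau", "omega")


@dataclass(frozen=True)
class GridSpec:
    """Rectangular precompute grid in mean input and noise intensity."""

    mu_min: float = -1.5
    mu_max: float = 5.0
    d_mu: float = 0.025
    sigma_min: float = 0.5
    sigma_max: float = 5.0
    d_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_min < SIGMA_FLOOR:
            raise ValueError(f"sigma_min must be >= {SIGMA_FLOOR}")
        if self.d_mu <= 0 or self.d_sigma <= 0:
            raise ValueError("grid spacings must be positive")
        if len(self.mu_grid) < 3 or len(self.sigma_grid) < 3:
            raise ValueError("need at least 3 grid points per axis")

    @property
    def mu_grid(self) -> np.ndarray:
        n = int(round((self.mu_max - self.mu_min) / self.d_mu)) + 1
        return self.mu_min + self.d_mu * np.arange(n)

    @property
    def sigma_grid(self) -> np.ndarray:
        n = int(round((self.sigma_max - self.sigma_min) / self.d_sigma)) + 1
        return self.sigma_min + self.d_sigma * np.arange(n)


@dataclass
class QuantityTable:
    """Named real arrays of shape (n_mu, n_sigma) plus metadata."""

    grid: GridSpec
    arrays: dict[str, np.ndarray]
    neuron_hash: str
    version: str = _VERSION
    flags: np.ndarray | None = None   # branch-discontinuity markers

    def __contains__(self, name: str) -> bool:
        return name in self.arrays

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.arrays]
        if missing:
            raise KeyError(f"table lacks quantities {missing}; "
                           "precompute the corresponding group")


def _column_spectrum(mu_grid: np.ndarray, sigma: float, sgrid,
                     neuron: NeuronParams, n_eigs: int = 4):
    """Dominant pairs along one sigma column, mu ascending.

    Refines the previous node's eigenvalues as seeds; reseeds from the
    coarse operator matrix whenever refinement loses roots (e.g. across a
    real-to-complex merge).
    """
    out = np.empty((len(mu_grid), 2), dtype=complex)
    seeds = None
    prev1 = None
    prev_mu = None
    for i, mu in enumerate(mu_grid):
        cands = None
        if seeds is not None:
            ref = []
            for lam in seeds:
                # one intermediate half-step keeps the branch identity
                l = solve_eigenvalue(lam, 0.5 * (prev_mu + mu), sigma,
                                     sgrid, neuron)
                l = solve_eigenvalue(lam if l is None else l, float(mu),
                                     sigma, sgrid, neuron)
                if l is None or abs(l) < 1e-9:
                    continue
                l = l if l.imag >= 0 else l.conjugate()
                if abs(l.imag) < 1e-8:
                    l = complex(l.real)
                if all(abs(l - r) > 1e-6 * max(1.0, abs(l)) for r in ref):
                    ref.append(l)
            expanded = []
            for l in ref:
                expanded.append(l)
                if abs(l.imag) > 1e-9:
                    expanded.append(l.conjugate())
            if len(expanded) >= n_eigs:
                cands = np.array(sorted(expanded,
                                        key=lambda z: (abs(z.real), -z.imag)))
        if cands is None:
            cands = find_spectrum(float(mu), sigma, sgrid, neuron,
                                  n_eigs=n_eigs)
        lam1, lam2 = select_dominant(cands, prefer_like=prev1)
        out[i] = (lam1, lam2)
        prev1 = lam1
        prev_mu = float(mu)
        seeds = [l for l in cands if l.imag >= 0]
    return out


def precompute_quantities(neuron: NeuronParams, gridspec: GridSpec,
                          which=("stationary", "spectral", "cascade"),
                          dV_stationary: float = 0.01,
                          dV_spectral: float = 0.01,
                          dV_cascade: float = 0.05,
                          n_freq: int = 48) -> QuantityTable:
    """Fill a QuantityTable by solving the stationary, spectral and
    linear-response problems at every grid node.

    Nodes where a solve fails are masked (NaN) and flagged; a later lookup
    touching a masked node raises.  The sigma columns are independent.
    """
    which = set(which)
    mu_g = gridspec.mu_grid
    sig_g = gridspec.sigma_grid
    n_mu, n_sig = len(mu_g), len(sig_g)
    arrays: dict[str, np.ndarray] = {}
    t_start = time.time()

    if "stationary" in which or "cascade" in which:
        fv_grid = build_voltage_grid(neuron, dV=dV_stationary)
        r = np.empty((n_mu, n_sig))
        V = np.empty((n_mu, n_sig))
        for j, sig in enumerate(sig_g):
            for i, mu in enumerate(mu_g):
                st = solve_stationary(float(mu), float(sig), fv_grid, neuron)
                r[i, j] = st.r_inf
                V[i, j] = st.mean_V_inf
        arrays["r_inf"] = r
        arrays["mean_V_inf"] = V
        arrays.update(stationary_derivatives(
            mu_g, sig_g, {"r_inf": r, "V_inf": V}))
        arrays.pop("d_sigma_V_inf", None)
        log.info("stationary pass done in %.1f s", time.time() - t_start)

    if "spectral" in which:
        sgrid = build_spectral_grid(neuron, dV=dV_spectral)
        names = SPECTRAL_NAMES
        for nm in names:
            arrays[nm] = np.full((n_mu, n_sig), np.nan)
        flags = np.zeros((n_mu, n_sig), dtype=bool)
        d_mu_fd = min(0.05, gridspec.d_mu)
        d_sig_fd = min(0.05, gridspec.d_sigma)
        for j, sig in enumerate(sig_g):
            pairs = _column_spectrum(mu_g, float(sig), sgrid, neuron)
            for i, mu in enumerate(mu_g):
                lam1, lam2 = pairs[i]
                try:
                    q = pair_quantities(lam1, lam2, float(mu), float(sig),
                                        sgrid, neuron,
                                        d_mu=d_mu_fd, d_sigma=d_sig_fd)
                except RuntimeError as exc:
                    log.warning("masked spectral node (%.3f, %.3f): %s",
                                mu, sig, exc)
                    flags[i, j] = True
                    continue
                arrays["lam1_re"][i, j] = q.lam1.real
                arrays["lam1_im"][i, j] = q.lam1.imag
                arrays["lam2_re"][i, j] = q.lam2.real
                arrays["lam2_im"][i, j] = q.lam2.imag
                arrays["f_cmu"][i, j] = q.f_cmu
                arrays["f_csigma2"][i, j] = q.f_csigma2
                arrays["F_mu"][i, j] = q.F_mu
                arrays["F_sigma2"][i, j] = q.F_sigma2
            # flag branch discontinuities along mu (jumps in Im lam1)
            im = arrays["lam1_im"][:, j]
            jump = np.abs(np.diff(im)) > 0.25
            flags[:-1, j] |= jump
        log.info("spectral pass done in %.1f s", time.time() - t_start)
    else:
        flags = None

    if "cascade" in which:
        cgrid = build_voltage_grid(neuron, dV=dV_cascade)
        f_grid = default_frequency_grid(n_freq)
        for nm in CASCADE_NAMES:
            arrays[nm] = np.full((n_mu, n_sig), np.nan)
        for j, sig in enumerate(sig_g):
            for i, mu in enumerate(mu_g):
                spec = linear_rate_response(float(mu), float(sig), f_grid,
                                            cgrid, neuron)
                # normalize with the solver's own DC limit (identical to
                # d r_inf/d mu but well conditioned at tiny rates)
                if spec.R_mu_dc <= 0:
                    log.warning("masked cascade node (%.3f, %.3f): "
                                "nonpositive d r_inf/d mu", mu, sig)
                    continue
                arrays["tau_mu"][i, j] = fit_exp_filter(spec)
                tau, omega, _ = fit_dos_filter(spec)
                arrays["tau"][i, j] = tau
                arrays["omega"][i, j] = omega
                arrays["tau_sigma"][i, j] = fit_sigma_filter(spec)
        log.info("cascade pass done in %.1f s", time.time() - t_start)

    return QuantityTable(grid=gridspec, arrays=arrays,
                         neuron_hash=neuron.eif_hash(), flags=flags)


_warned = {"count": 0}


def lookup(table: QuantityTable, mu: float, sigma: float, names,
           clamp: bool = True) -> dict[str, float]:
    """Bilinear interpolation of named quantities at one (mu, sigma).

    Out-of-range queries clamp to the grid boundary (with a rate-limited
    warning) unless ``clamp`` is False, in which case they raise.
    """
    mu_g = table.grid.mu_grid
    sig_g = table.grid.sigma_grid
    if not clamp and not (mu_g[0] <= mu <= mu_g[-1]
                          and sig_g[0] <= sigma <= sig_g[-1]):
        raise ValueError(f"query ({mu}, {sigma}) outside table bounds")
    if clamp and (mu < mu_g[0] or mu > mu_g[-1] or sigma < sig_g[0]
                  or sigma > sig_g[-1]):
        if _warned["count"] < 5:
            log.warning("query (%.3f, %.3f) clamped to table bounds",
                        mu, sigma)
            _warned["count"] += 1
    mu = min(max(mu, mu_g[0]), mu_g[-1])
    sigma = min(max(sigma, sig_g[0]), sig_g[-1])
    i = min(int((mu - mu_g[0]) / table.grid.d_mu), len(mu_g) - 2)
    j = min(int((sigma - sig_g[0]) / table.grid.d_sigma), len(sig_g) - 2)
    x = (mu - mu_g[i]) / table.grid.d_mu
    y = (sigma - sig_g[j]) / table.grid.d_sigma
    table.require(names)
    out = {}
    for nm in names:
        a = table.arrays[nm]
        val = ((1 - x) * (1 - y) * a[i, j] + x * (1 - y) * a[i + 1, j]
               + (1 - x) * y * a[i, j + 1] + x * y * a[i + 1, j + 1])
        if not np.isfinite(val):
            raise ValueError(f"lookup of {nm} at ({mu}, {sigma}) touches a "
                             "masked node")
        out[nm] = float(val)
    return out


def save_table(table: QuantityTable, path) -> None:
    """Persist as a single HDF5 file: /grid, /stationary, /spectral,
    /cascade, /meta."""
    groups = {"stationary": STATIONARY_NAMES, "spectral": SPECTRAL_NAMES,
              "cascade": CASCADE_NAMES}
    with h5py.File(path, "w") as h:
        g = h.create_group("grid")
        for k in ("mu_min", "mu_max", "d_mu", "sigma_min", "sigma_max",
                  "d_sigma"):
            g.attrs[k] = getattr(table.grid, k)
        for gname, names in groups.items():
            grp = h.create_group(gname)
            for nm in names:
                if nm in table.arrays:
                    grp.create_dataset(nm, data=table.arrays[nm])
        meta = h.create_group("meta")
        meta.attrs["neuron_hash"] = table.neuron_hash
        meta.attrs["version"] = table.version
        if table.flags is not None:
            meta.create_dataset("flags", data=table.flags)


def load_table(path, neuron: NeuronParams | None = None) -> QuantityTable:
    """Load a table; verifies the EIF-parameter hash when given a neuron."""
    with h5py.File(path, "r") as h:
        gs = GridSpec(**{k: float(h["grid"].attrs[k])
                         for k in ("mu_min", "mu_max", "d_mu", "sigma_min",
                                   "sigma_max", "d_sigma")})
        arrays = {}
        for gname in ("stationary", "spectral", "cascade"):
            if gname in h:
                for nm in h[gname]:
                    arrays[nm] = h[gname][nm][()]
        meta = h["meta"]
        nh = meta.attrs["version"]
        if nh != _VERSION:
            raise ValueError(f"unsupported table version {nh!r}")
        neuron_hash = meta.attrs["neuron_hash"]
        flags = meta["flags"][()] if "flags" in meta else None
    if neuron is not None and neuron.eif_hash() != neuron_hash:
        raise ValueError("table was precomputed for different EIF "
                         "parameters (hash mismatch)")
    return QuantityTable(grid=gs, arrays=arrays, neuron_hash=str(neuron_hash),
                         flags=flags)
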