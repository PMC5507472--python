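"""Eigendecomposition of the Fokker-Planck operator by exponential shooting.

For frozen input moments (mu, sigma) the operator L of the detached EIF
population has a discrete spectrum {lambda_n} with Re lambda_n <= 0 and
lambda_0 = 0 (the stationary mode).  The eigenproblem is reformulated as a
complex root-finding problem: integrating the first-order system for the
eigenflux q and eigenfunction phi backward from V_s (phi(V_s) = 0,
q(V_s) = 1) through the reinjection jump at V_r down to V_lb, an eigenvalue
is a lambda for which the reflecting condition q(V_lb) = 0 holds.  Each
voltage step applies the analytic exponential of the 2x2 coefficient matrix
evaluated at the interval midpoint (one-term Magnus scheme), which remains
accurate despite the steep exponential current near V_s.

Initial approximations come from a dense scan over real lambda at
sufficiently hyperpolarized mean input, where the whole spectrum is real;
eigenvalues at other inputs are obtained by continuation in mu with a
two-variable Powell hybrid solve, detecting the merging of two real roots
into a complex-conjugate (regular) pair.  The adjoint eigenfunctions psi_n
are integrated forward from V_lb (psi = 1, psi' = 0) and pairs are scaled
to the biorthonormality <psi_n, phi_n> = 1 under the non-conjugated inner
product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import root, brentq

from .params import NeuronParams

log = logging.getLogger(__name__)

__all__ = [
    "SpectralGrid", "SpectralSolution", "SpectralQuantities",
    "build_spectral_grid", "coefficient_matrix", "backward_flux",
    "init_spectrum_real_scan", "track_eigenvalue", "track_spectrum",
    "find_spectrum", "solve_eigenvalue",
    "solve_adjoint", "eigenfunction", "biorthonormalize", "inner",
    "select_dominant", "spectral_quantities", "pair_quantities",
    "stationary_mode",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Node-centered uniform voltage grid for the shooting integrations."""

    V_lb: float
    V_s: float
    V_r: float
    dV: float
    nodes: np.ndarray
    mids: np.ndarray
    k_r: int


def build_spectral_grid(neuron: NeuronParams,
                        dV: float = 0.01) -> SpectralGrid:
    n = int(round((neuron.V_s - neuron.V_lb) / dV))
    dV = (neuron.V_s - neuron.V_lb) / n
    nodes = neuron.V_lb + dV * np.arange(n + 1)
    mids = nodes[:-1] + dV / 2.0
    k_r = int(round((neuron.V_r - neuron.V_lb) / dV))
    return SpectralGrid(neuron.V_lb, neuron.V_s, neuron.V_r, dV, nodes,
                        mids, k_r)


def coefficient_matrix(V: float, lam: complex, mu: float, sigma_sq: float,
                       neuron: NeuronParams) -> np.ndarray:
    """2x2 matrix A(V) of -d/dV (q, phi)^T = A (q, phi)^T."""
    g = float(neuron.g(V))
    return np.array([[0.0, lam],
                     [2.0 / sigma_sq, -2.0 * (g + mu) / sigma_sq]],
                    dtype=complex)


@njit(cache=False, inline="always")
def _step2x2(a12, a21, a22, h, x0, x1):
    """x <- exp(h * [[0, a12], [a21, a22]]) x, analytic 2x2 exponential."""
    tau = 0.5 * a22
    delta2 = tau * tau + a12 * a21
    delta = np.sqrt(delta2 + 0j)
    dh = delta * h
    e = np.exp(tau * h)
    if abs(dh) < 1e-7:
        ch = e * (1.0 + 0.5 * dh * dh)
        sh = e * h * (1.0 + dh * dh / 6.0)
    else:
        ep = np.exp(dh)
        em = 1.0 / ep
        ch = e * 0.5 * (ep + em)
        sh = e * 0.5 * (ep - em) / delta
    y0 = (ch - tau * sh) * x0 + a12 * sh * x1
    y1 = a21 * sh * x0 + (ch + tau * sh) * x1
    return y0, y1


@njit(cache=False)
def _qlb_sweep(lam, mu, s2, g_mid, dV, k_r, tref_fac):
    """Backward sweep V_s -> V_lb; returns scaled q(V_lb) (roots preserved)."""
    n = g_mid.shape[0]
    q = 1.0 + 0.0j
    phi = 0.0 + 0.0j
    q_s = 1.0 + 0.0j
    a21 = 2.0 / s2
    for k in range(n - 1, -1, -1):
        a22 = -2.0 * (g_mid[k] + mu) / s2
        q, phi = _step2x2(lam, a21, a22, dV, q, phi)
        if k == k_r:
            q = q - q_s * tref_fac
        m = abs(q) + abs(phi)
        if m > 1e120:
            q /= m
            phi /= m
            if k > k_r:
                q_s /= m
    return q


@njit(cache=False)
def _qlb_sweep_batch(lams, mu, s2, g_mid, dV, k_r, T_ref):
    out = np.empty(lams.shape[0], dtype=np.complex128)
    for i in range(lams.shape[0]):
        fac = np.exp(-lams[i] * T_ref) if T_ref > 0.0 else 1.0 + 0.0j
        out[i] = _qlb_sweep(lams[i], mu, s2, g_mid, dV, k_r, fac)
    return out


@njit(cache=False)
def _phi_sweep_store(lam, mu, s2, g_mid, dV, k_r, tref_fac):
    """Backward sweep storing phi and q on all nodes (V_lb..V_s)."""
    n = g_mid.shape[0]
    q_arr = np.zeros(n + 1, dtype=np.complex128)
    p_arr = np.zeros(n + 1, dtype=np.complex128)
    q = 1.0 + 0.0j
    phi = 0.0 + 0.0j
    q_s = 1.0 + 0.0j
    q_arr[n] = q
    a21 = 2.0 / s2
    for k in range(n - 1, -1, -1):
        a22 = -2.0 * (g_mid[k] + mu) / s2
        q, phi = _step2x2(lam, a21, a22, dV, q, phi)
        if k == k_r:
            q = q - q_s * tref_fac
        q_arr[k] = q
        p_arr[k] = phi
        m = abs(q) + abs(phi)
        if m > 1e120:
            q /= m
            phi /= m
            q_s /= m
            for j in range(k, n + 1):
                q_arr[j] /= m
                p_arr[j] /= m
    return q_arr, p_arr


@njit(cache=False)
def _psi_sweep_store(lam, mu, s2, g_mid, dV):
    """Forward sweep for the adjoint: psi(V_lb)=1, psi'(V_lb)=0."""
    n = g_mid.shape[0]
    psi_arr = np.zeros(n + 1, dtype=np.complex128)
    dps_arr = np.zeros(n + 1, dtype=np.complex128)
    psi = 1.0 + 0.0j
    dps = 0.0 + 0.0j
    psi_arr[0] = psi
    a21 = 2.0 * lam / s2
    for k in range(n):
        a22 = -2.0 * (g_mid[k] + mu) / s2
        psi, dps = _step2x2(1.0 + 0.0j, a21, a22, dV, psi, dps)
        psi_arr[k + 1] = psi
        dps_arr[k + 1] = dps
    return psi_arr, dps_arr


@dataclass
class SpectralSolution:
    """One (lambda, phi, q_phi, psi) tuple on the spectral grid."""

    lam: complex
    phi: np.ndarray
    q_phi: np.ndarray
    psi: np.ndarray
    dpsi: np.ndarray
    grid: SpectralGrid
    biorthonormalized: bool = False
    adjoint_residual: float = np.nan


def _g_mid(grid: SpectralGrid, neuron: NeuronParams) -> np.ndarray:
    return np.asarray(neuron.g(grid.mids), dtype=float)


def backward_flux(lam: complex, mu: float, sigma: float, grid: SpectralGrid,
                  neuron: NeuronParams, T_ref_mode: bool = False) -> complex:
    """q(V_lb; lambda) of the shooting problem (scaled; zeros preserved)."""
    T_ref = neuron.T_ref if T_ref_mode else 0.0
    fac = np.exp(-lam * T_ref) if T_ref > 0 else 1.0 + 0.0j
    return complex(_qlb_sweep(complex(lam), mu, sigma ** 2,
                              _g_mid(grid, neuron), grid.dV, grid.k_r, fac))


def init_spectrum_real_scan(mu_min: float, sigma: float, grid: SpectralGrid,
                            neuron: NeuronParams, n_eigs: int = 4,
                            lam_max: float = 1.5, n_scan: int = 2000,
                            T_ref_mode: bool = False) -> np.ndarray:
    """Real eigenvalues at hyperpolarized mean input from a dense scan.

    Scans q(V_lb; lambda) over real lambda in [-lam_max, 0), brackets sign
    changes and refines them with Brent's method; the window widens
    adaptively until n_eigs roots are found.  lambda_0 = 0 is excluded.
    """
    g_mid = _g_mid(grid, neuron)
    s2 = sigma ** 2
    T_ref = neuron.T_ref if T_ref_mode else 0.0

    def f(x: float) -> float:
        fac = np.exp(-x * T_ref) if T_ref > 0 else 1.0
        return _qlb_sweep(complex(x), mu_min, s2, g_mid, grid.dV,
                          grid.k_r, complex(fac)).real

    for trial in range(5):
        lams = np.linspace(-lam_max, -1e-6, n_scan)
        vals = _qlb_sweep_batch(lams.astype(complex), mu_min, s2, g_mid,
                                grid.dV, grid.k_r, T_ref).real
        sgn = np.sign(vals)
        idx = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
        if len(idx) >= n_eigs:
            roots = []
            for i in idx[::-1]:  # closest to zero first
                roots.append(brentq(f, lams[i], lams[i + 1],
                                    xtol=1e-13, rtol=1e-12))
                if len(roots) == n_eigs:
                    break
            return np.array(roots)
        lam_max *= 2.0
        n_scan *= 2
    raise RuntimeError(
        f"found only {len(idx)} real eigenvalues below mu={mu_min}; "
        "scan window exhausted")


def solve_eigenvalue(lam0: complex, mu: float, sigma: float,
                     grid: SpectralGrid, neuron: NeuronParams,
                     T_ref_mode: bool = False,
                     tol: float = 1e-12) -> complex | None:
    """Refine one eigenvalue of the shooting problem.

    q(V_lb; lambda) is analytic in lambda, so a complex secant iteration
    converges in a handful of sweeps; Powell's hybrid method on
    (Re lambda, Im lambda) serves as the fallback when it stalls.
    """
    g_mid = _g_mid(grid, neuron)
    s2 = sigma ** 2
    T_ref = neuron.T_ref if T_ref_mode else 0.0

    def q_of(lam: complex) -> complex:
        fac = np.exp(-lam * T_ref) if T_ref > 0 else 1.0 + 0.0j
        return _qlb_sweep(lam, mu, s2, g_mid, grid.dV, grid.k_r, fac)

    # complex secant iteration
    la, lb = complex(lam0), complex(lam0) * (1 + 1e-4) + 1e-6
    fa, fb = q_of(la), q_of(lb)
    for _ in range(40):
        if fb == fa:
            break
        ln = lb - fb * (lb - la) / (fb - fa)
        if not np.isfinite(ln.real) or not np.isfinite(ln.imag):
            break
        la, fa, lb = lb, fb, ln
        fb = q_of(lb)
        if abs(lb - la) < tol * max(1.0, abs(lb)):
            if abs(lb - lam0) < 0.6 * max(0.05, abs(lam0)):
                return lb
            break

    def f(x):
        q = q_of(complex(x[0], x[1]))
        return [q.real, q.imag]

    sol = root(f, [lam0.real, lam0.imag], method="hybr",
               options={"xtol": tol})
    if not sol.success:
        return None
    return complex(sol.x[0], sol.x[1])


def _canon(lam: complex) -> complex:
    return lam if lam.imag >= 0 else lam.conjugate()


def track_eigenvalue(lam_start: complex, mu_path: np.ndarray, sigma: float,
                     grid: SpectralGrid, neuron: NeuronParams,
                     T_ref_mode: bool = False) -> np.ndarray:
    """Continuation of one eigenvalue along a path of mean inputs."""
    out = np.empty(len(mu_path), dtype=complex)
    lam = complex(lam_start)
    for i, mu in enumerate(mu_path):
        nxt = solve_eigenvalue(lam, mu, sigma, grid, neuron, T_ref_mode)
        if nxt is None:
            # adaptive sub-stepping from the previous mean input
            mu_prev = mu_path[i - 1] if i > 0 else mu
            sub = np.linspace(mu_prev, mu, 5)[1:]
            for m in sub:
                nxt = solve_eigenvalue(lam, m, sigma, grid, neuron,
                                       T_ref_mode)
                if nxt is None:
                    break
                lam = nxt
            if nxt is None:
                raise RuntimeError(
                    f"eigenvalue continuation failed at mu={mu}, "
                    f"sigma={sigma}")
        lam = nxt
        out[i] = lam
    return out


def find_spectrum(mu: float, sigma: float, grid: SpectralGrid,
                  neuron: NeuronParams, n_eigs: int = 4,
                  seed_dV: float = 0.1,
                  T_ref_mode: bool = False) -> np.ndarray:
    """The n_eigs dominant nonstationary eigenvalues at one (mu, sigma).

    Initial approximations come from a sparse shift-invert
    eigendecomposition of the Scharfetter-Gummel operator matrix on a
    moderate grid (spacing ``seed_dV``); each is then refined by the
    shooting solver on the fine grid.  This stays robust across the
    real-to-complex transitions where plain continuation of individual
    real roots breaks down.  Complex pairs are returned as both conjugate
    members; the result is sorted by |Re lambda|.
    """
    from .fv import build_voltage_grid, fv_operator_matrix
    import scipy.sparse.linalg as spla

    fg = build_voltage_grid(neuron, dV=seed_dV)
    A = fv_operator_matrix(fg, mu, sigma, neuron)
    k = max(2 * n_eigs, 8)
    vals = spla.eigs(A, k=k, sigma=0.02, return_eigenvectors=False)
    vals = vals[np.abs(vals) > 1e-7]
    # canonical representatives (Im >= 0), deduplicated
    reps: list[complex] = []
    for v in sorted(vals, key=lambda z: abs(z.real)):
        v = _canon(complex(v))
        if all(abs(v - r) > 1e-6 * max(1.0, abs(v)) for r in reps):
            reps.append(v)
    refined: list[complex] = []
    for v in reps:
        lam = solve_eigenvalue(v, mu, sigma, grid, neuron, T_ref_mode)
        if lam is None or abs(lam) < 1e-9:
            continue
        lam = _canon(lam)
        if lam.imag < 1e-8:
            lam = complex(lam.real)
        if all(abs(lam - r) > 1e-6 * max(1.0, abs(lam)) for r in refined):
            refined.append(lam)
    out: list[complex] = []
    for lam in refined:
        out.append(lam)
        if abs(lam.imag) > 1e-9:
            out.append(lam.conjugate())
    out.sort(key=lambda z: (abs(z.real), -z.imag))
    if len(out) < n_eigs:
        raise RuntimeError(
            f"only {len(out)} eigenvalues recovered at mu={mu}, "
            f"sigma={sigma}")
    return np.array(out[:n_eigs], dtype=complex)


def track_spectrum(mu_path: np.ndarray, sigma: float, grid: SpectralGrid,
                   neuron: NeuronParams, n_eigs: int = 4,
                   seed_dV: float = 0.05,
                   T_ref_mode: bool = False) -> np.ndarray:
    """Dominant nonstationary eigenvalues along a path of mean inputs.

    Each node is solved with ``find_spectrum`` (operator-matrix seeding plus
    shooting refinement); the merging of two real roots into a complex
    conjugate pair with increasing mean input appears naturally.
    Returns an array of shape (len(mu_path), n_eigs).
    """
    out = np.empty((len(mu_path), n_eigs), dtype=complex)
    for j, mu in enumerate(mu_path):
        out[j] = find_spectrum(float(mu), sigma, grid, neuron,
                               n_eigs=n_eigs, seed_dV=seed_dV,
                               T_ref_mode=T_ref_mode)
    return out


def solve_adjoint(lam: complex, mu: float, sigma: float, grid: SpectralGrid,
                  neuron: NeuronParams,
                  T_ref_mode: bool = False) -> tuple[np.ndarray, np.ndarray, float]:
    """Adjoint eigenfunction psi by forward integration from V_lb.

    Returns (psi, psi', residual) where the residual
    |psi(V_s) - psi(V_r) e^{-lambda T_ref}| / max|psi| measures consistency
    of lambda with the adjoint boundary condition.
    """
    psi, dps = _psi_sweep_store(complex(lam), mu, sigma ** 2,
                                _g_mid(grid, neuron), grid.dV)
    T_ref = neuron.T_ref if T_ref_mode else 0.0
    fac = np.exp(-lam * T_ref) if T_ref > 0 else 1.0
    res = abs(psi[-1] - psi[grid.k_r] * fac) / np.abs(psi).max()
    return psi, dps, float(res)


def eigenfunction(lam: complex, mu: float, sigma: float, grid: SpectralGrid,
                  neuron: NeuronParams,
                  T_ref_mode: bool = False) -> SpectralSolution:
    """Forward/adjoint eigenfunction pair for an accepted eigenvalue."""
    T_ref = neuron.T_ref if T_ref_mode else 0.0
    fac = np.exp(-complex(lam) * T_ref) if T_ref > 0 else 1.0 + 0.0j
    q_arr, phi = _phi_sweep_store(complex(lam), mu, sigma ** 2,
                                  _g_mid(grid, neuron), grid.dV,
                                  grid.k_r, fac)
    psi, dps, res = solve_adjoint(lam, mu, sigma, grid, neuron, T_ref_mode)
    return SpectralSolution(lam=complex(lam), phi=phi, q_phi=q_arr, psi=psi,
                            dpsi=dps, grid=grid, adjoint_residual=res)


def inner(psi: np.ndarray, phi: np.ndarray, dV: float) -> complex:
    """Non-conjugated inner product <psi, phi> by trapezoidal quadrature."""
    return complex(np.trapezoid(psi * phi, dx=dV))


def biorthonormalize(solutions: list[SpectralSolution]) -> list[SpectralSolution]:
    """Scale each phi_n so that <psi_n, phi_n> = 1 (psi kept fixed).

    Keeping psi at its deterministic normalization psi(V_lb) = 1 makes the
    psi-branch smooth in (mu, sigma), which the finite-difference coupling
    coefficients rely on; the bilinear products f_n c_n are invariant under
    the remaining joint rescale freedom.
    """
    out = []
    for s in solutions:
        ip = inner(s.psi, s.phi, s.grid.dV)
        if abs(ip) < 1e-300:
            raise RuntimeError("degenerate pairing: <psi, phi> ~ 0")
        out.append(SpectralSolution(
            lam=s.lam, phi=s.phi / ip, q_phi=s.q_phi / ip, psi=s.psi,
            dpsi=s.dpsi, grid=s.grid, biorthonormalized=True,
            adjoint_residual=s.adjoint_residual))
    return out


def stationary_mode(mu: float, sigma: float, grid: SpectralGrid,
                    neuron: NeuronParams) -> SpectralSolution:
    """lambda_0 = 0 mode: phi_0 = p_inf normalized to unit mass, psi_0 = 1."""
    q_arr, phi = _phi_sweep_store(0.0 + 0.0j, mu, sigma ** 2,
                                  _g_mid(grid, neuron), grid.dV,
                                  grid.k_r, 1.0 + 0.0j)
    mass = np.trapezoid(phi.real, dx=grid.dV)
    phi = phi / mass
    q_arr = q_arr / mass
    psi = np.ones_like(phi)
    return SpectralSolution(lam=0.0, phi=phi, q_phi=q_arr, psi=psi,
                            dpsi=np.zeros_like(phi), grid=grid,
                            biorthonormalized=True, adjoint_residual=0.0)


def select_dominant(cands: np.ndarray,
                    prefer_like: complex | None = None):
    """Dominant eigenvalue pair (lambda_1, lambda_2).

    lambda_1 minimizes |Re lambda| over nonzero eigenvalues; lambda_2
    minimizes |Re| over the remaining ones subject to lambda_1 + lambda_2
    being real, so the pair is either real or complex conjugate.  Near ties
    (within 1e-6) the branch matching ``prefer_like`` (the neighboring grid
    point's choice) wins.
    """
    cands = np.asarray(cands, dtype=complex)
    nz = cands[np.abs(cands) > 1e-9]
    if len(nz) < 2:
        raise ValueError("need at least two nonstationary eigenvalues")
    order = np.argsort(np.abs(nz.real), kind="stable")
    lam1 = nz[order[0]]
    if prefer_like is not None and len(order) > 1:
        alt = nz[order[1]]
        if abs(abs(lam1.real) - abs(alt.real)) < 1e-6:
            like1 = (abs(lam1.imag) > 1e-9) == (abs(prefer_like.imag) > 1e-9)
            like2 = (abs(alt.imag) > 1e-9) == (abs(prefer_like.imag) > 1e-9)
            if like2 and not like1:
                lam1 = alt
    lam1 = _canon(lam1)
    if abs(lam1.imag) > 1e-9:
        return lam1, lam1.conjugate()
    rest = [l for l in nz if abs(l - lam1) > 1e-9 * max(1.0, abs(lam1))
            and abs(l.imag) < 1e-7]
    if not rest:
        raise ValueError("no admissible real lambda_2 candidate")
    lam2 = min(rest, key=lambda l: abs(l.real))
    return complex(lam1.real), complex(lam2.real)


@dataclass
class SpectralQuantities:
    """Scalar spectral quantities at one (mu, sigma) node."""

    lam1: complex
    lam2: complex
    r_inf: float
    f: np.ndarray            # eigenfluxes at V_s (2,)
    c_mu: np.ndarray         # <d_mu psi_n, phi_0> (2,)
    c_sigma2: np.ndarray     # <d_sigma2 psi_n, phi_0> (2,)
    f_cmu: float
    f_csigma2: float
    F_mu: float
    F_sigma2: float


def _pair_values(lam1: complex, lam2: complex, f1: complex, f2: complex,
                 c1: complex, c2: complex):
    fc = f1 * c1 + f2 * c2
    Fx = f1 * lam1 * c1 + f2 * lam2 * c2
    return fc, Fx


def pair_quantities(lam1: complex, lam2: complex, mu: float, sigma: float,
                    grid: SpectralGrid, neuron: NeuronParams,
                    d_mu: float = 0.05,
                    d_sigma: float = 0.05) -> SpectralQuantities:
    """Spectral scalars for an accepted dominant pair (lambda_1, lambda_2).

    Solves the forward/adjoint pairs at (mu, sigma) and, for the coupling
    coefficients c_n^x = <d_x psi_n, phi_0>, re-solves each eigenvalue at
    the four neighboring points (mu +- d_mu, sigma^2 +- d(sigma^2)) by
    local continuation, keeping the branch identity consistent, and
    differentiates the adjoint eigenfunctions centrally.
    """
    phi0 = stationary_mode(mu, sigma, grid, neuron)
    r_inf = float(phi0.q_phi[-1].real)

    def pair_at(lam, mu_q, sig_q):
        for start in (lam, lam * 1.05 + 0.005j, lam * 0.95 - 0.005j):
            l = solve_eigenvalue(start, mu_q, sig_q, grid, neuron)
            if l is not None:
                break
        else:
            raise RuntimeError("neighbor eigenvalue solve failed")
        sol = eigenfunction(l, mu_q, sig_q, grid, neuron)
        return biorthonormalize([sol])[0]

    out_f = np.empty(2, dtype=complex)
    out_cmu = np.empty(2, dtype=complex)
    out_cs2 = np.empty(2, dtype=complex)
    sig2 = sigma ** 2
    d_s2 = 2.0 * sigma * d_sigma
    conj_pair = abs(lam1 - lam2.conjugate()) < 1e-9 * max(1.0, abs(lam1))
    for n, lam in enumerate((lam1, lam2)):
        if n == 1 and conj_pair and abs(lam1.imag) > 1e-9:
            out_f[1] = out_f[0].conjugate()
            out_cmu[1] = out_cmu[0].conjugate()
            out_cs2[1] = out_cs2[0].conjugate()
            break
        sol = biorthonormalize([eigenfunction(lam, mu, sigma, grid,
                                              neuron)])[0]
        out_f[n] = sol.q_phi[-1]
        psi_pm = []
        for mq in (mu + d_mu, mu - d_mu):
            psi_pm.append(pair_at(lam, mq, sigma).psi)
        dpsi_dmu = (psi_pm[0] - psi_pm[1]) / (2.0 * d_mu)
        psi_pm = []
        for s2q in (sig2 + d_s2, sig2 - d_s2):
            psi_pm.append(pair_at(lam, mu, np.sqrt(s2q)).psi)
        dpsi_ds2 = (psi_pm[0] - psi_pm[1]) / (2.0 * d_s2)
        out_cmu[n] = inner(dpsi_dmu, phi0.phi, grid.dV)
        out_cs2[n] = inner(dpsi_ds2, phi0.phi, grid.dV)
    fc_mu, F_mu = _pair_values(lam1, lam2, out_f[0], out_f[1],
                               out_cmu[0], out_cmu[1])
    fc_s2, F_s2 = _pair_values(lam1, lam2, out_f[0], out_f[1],
                               out_cs2[0], out_cs2[1])
    return SpectralQuantities(
        lam1=lam1, lam2=lam2, r_inf=r_inf, f=out_f, c_mu=out_cmu,
        c_sigma2=out_cs2, f_cmu=float(fc_mu.real),
        f_csigma2=float(fc_s2.real), F_mu=float(F_mu.real),
        F_sigma2=float(F_s2.real))


def spectral_quantities(mu: float, sigma: float, grid: SpectralGrid,
                        neuron: NeuronParams, d_mu: float = 0.05,
                        d_sigma: float = 0.05) -> SpectralQuantities:
    """Self-contained spectral quantities at one (mu, sigma) node."""
    lams = find_spectrum(mu, sigma, grid, neuron, n_eigs=4)
    lam1, lam2 = select_dominant(lams)
    return pair_quantities(lam1, lam2, mu, sigma, grid, neuron,
                           d_mu=d_mu, d_sigma=d_sigma)
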