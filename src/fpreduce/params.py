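"""Parameter containers and unit conventions.

Units are fixed package-wide: time in ms, voltage in mV, capacitance in pF,
conductance in nS, current in pA, rates in kHz.  Input moments are expressed
per membrane capacitance: the mean drive ``mu`` carries mV/ms and the noise
intensity ``sigma^2`` carries mV^2/ms, so ``sigma`` itself has units
mV.ms^(-1/2).  With C in pF and g_L in nS the ratio g_L/C is 1/ms and w/C is
mV/ms, so all equations close without conversion factors.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, fields, asdict

__all__ = [
    "NeuronParams",
    "CouplingParams",
    "OUParams",
    "InputMoments",
    "SIGMA_FLOOR",
    "synaptic_moments",
]

#: Smallest admissible input standard deviation (mV.ms^-1/2).  The diffusion
#: approximation and the numerics of the stationary/spectral problems degrade
#: below roughly this value, so parametrizations under the floor are rejected.
SIGMA_FLOOR = 0.5


@dataclass(frozen=True)
class NeuronParams:
    """Adaptive exponential integrate-and-fire (aEIF) single-neuron parameters.

    Defaults describe a regular-spiking cortical pyramidal neuron.  The
    voltage equation is C dV/dt = -g_L(V-E_L) + g_L Delta_T exp((V-V_T)/Delta_T)
    - w + I_syn; the adaptation current w relaxes with time constant tau_w
    toward a(V-E_w) and jumps by b at each spike.  On reaching ``V_s`` the
    voltage is reset to ``V_r`` and clamped for ``T_ref``.  ``V_lb`` is the
    reflecting lower bound used by the Fokker-Planck description.
    """

    C: float = 200.0        # pF
    g_L: float = 10.0       # nS
    E_L: float = -65.0      # mV
    Delta_T: float = 1.5    # mV
    V_T: float = -50.0      # mV
    V_s: float = -40.0      # mV
    V_r: float = -70.0      # mV
    T_ref: float = 0.0      # ms
    a: float = 4.0          # nS
    b: float = 40.0         # pA
    E_w: float = -80.0      # mV
    tau_w: float = 200.0    # ms
    V_lb: float = -200.0    # mV

    def __post_init__(self) -> None:
        if not (self.V_lb < self.V_r < self.V_T < self.V_s):
            raise ValueError(
                "require V_lb < V_r < V_T < V_s, got "
                f"{self.V_lb}, {self.V_r}, {self.V_T}, {self.V_s}"
            )
        if self.Delta_T <= 0 or self.C <= 0 or self.g_L <= 0 or self.tau_w <= 0:
            raise ValueError("Delta_T, C, g_L, tau_w must be positive")
        if self.T_ref < 0 or self.a < 0 or self.b < 0:
            raise ValueError("T_ref, a, b must be nonnegative")

    # --- EIF membrane current, per capacitance (mV/ms) ---------------------
    def g(self, V):
        """Drift [I_L(V) + I_exp(V)]/C of the detached EIF membrane."""
        import numpy as np

        arg = (np.minimum(V, self.V_s) - self.V_T) / self.Delta_T
        return (
            -self.g_L * (V - self.E_L)
            + self.g_L * self.Delta_T * np.exp(arg)
        ) / self.C

    def eif_hash(self) -> str:
        """Hash of the parameters the (mu, sigma) quantities depend on.

        Adaptation (a, b, tau_w, E_w) deliberately excluded: the tabulated
        quantities describe the detached EIF membrane, so changing the
        adaptation or coupling parameters must not invalidate a table.
        """
        key = {
            k: getattr(self, k)
            for k in ("C", "g_L", "E_L", "Delta_T", "V_T", "V_s", "V_r",
                      "T_ref", "V_lb")
        }
        return hashlib.sha256(
            json.dumps(key, sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass(frozen=True)
class CouplingParams:
    """Recurrent pulse-coupling: K random presynaptic partners, voltage jump J.

    ``delay_kind`` selects the propagation-delay distribution: "exponential"
    (mean ``tau_d``), "identical" (fixed ``d``) or "none".
    """

    K: int = 0
    J: float = 0.0          # mV
    delay_kind: str = "exponential"
    tau_d: float = 3.0      # ms, exponential mean delay
    d: float = 0.0          # ms, identical delay

    def __post_init__(self) -> None:
        if self.K < 0 or int(self.K) != self.K:
            raise ValueError("K must be a nonnegative integer")
        if self.delay_kind not in ("exponential", "identical", "none"):
            raise ValueError(f"unknown delay_kind {self.delay_kind!r}")
        if self.delay_kind == "exponential" and self.tau_d <= 0:
            raise ValueError("tau_d must be positive for exponential delays")
        if self.delay_kind == "identical" and self.d < 0:
            raise ValueError("identical delay d must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck process parameters for a time-varying input moment.

    The stationary law is Normal(mean, theta^2) with correlation time
    ``tau_ou``; realizations are smoothed with a Gaussian kernel of width
    ``sigma_t`` to make them twice differentiable.
    """

    mean: float
    theta: float = 0.0
    tau_ou: float = 50.0    # ms
    sigma_t: float = 1.0    # ms

    def __post_init__(self) -> None:
        if self.tau_ou <= 0:
            raise ValueError("tau_ou must be positive")
        if self.theta < 0 or self.sigma_t < 0:
            raise ValueError("theta and sigma_t must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OUParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass(frozen=True)
class InputMoments:
    """Overall synaptic input moments mu_syn (mV/ms), sigma_syn^2 (mV^2/ms)."""

    mu_syn: float
    sigma_syn_sq: float

    def __post_init__(self) -> None:
        if self.sigma_syn_sq <= 0:
            raise ValueError("sigma_syn_sq must be positive")


def synaptic_moments(mu_ext: float, sigma_ext_sq: float, r_d: float,
                     coupling: CouplingParams) -> InputMoments:
    """Overall synaptic moments of the diffusion approximation.

    mu_syn = mu_ext + J K r_d and sigma_syn^2 = sigma_ext^2 + J^2 K r_d:
    the delayed population rate r_d (kHz) adds J K r_d to the mean and,
    irrespective of the sign of J, J^2 K r_d to the variance.
    """
    if r_d < 0:
        raise ValueError("delayed spike rate r_d must be nonnegative")
    mu = mu_ext + coupling.J * coupling.K * r_d
    s2 = sigma_ext_sq + coupling.J ** 2 * coupling.K * r_d
    return InputMoments(mu_syn=mu, sigma_syn_sq=s2)
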