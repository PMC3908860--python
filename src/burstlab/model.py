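"""Single-neuron vector field of the reduced leech-heart-interneuron burster.

The model is a four-dimensional Hodgkin-Huxley-type cell retaining the
currents that survive the Co2+/4-AP pharmacological reduction: a fast
sodium current ``I_Na`` (instantaneous cubic activation, inactivating), a
non-inactivating slow potassium current ``I_K2`` (squared gate, the slow
variable of the burster), a hyperpolarization-activated current ``I_h``
(squared gate), an ohmic leak, and a constant polarizing current.

Units are self-consistent throughout the package: volts, seconds, nA, nS
and nF (nS * V = nA, nA / nF * s = V).  Voltages are kept in volts, never
millivolts.

The two regulated parameters are the half-activation voltages of the K2
and h gates.  They enter the Boltzmann exponents as ``(V + theta)``, so the
physiological half-activation voltage is ``-theta``: ``theta_k2`` around
-0.0105..-0.006 V corresponds to a K2 half-activation of +0.006..+0.0105 V,
and ``theta_h`` around 0.0375..0.0415 V to an h half-activation near
-0.041 V.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TauRule",
    "GateSpec",
    "NeuronParams",
    "NeuronState",
    "CurrentBreakdown",
    "gate_steady_state",
    "gate_tau",
    "ionic_currents",
    "rhs",
    "steady_state_current",
    "steady_state_gates",
]


@dataclass(frozen=True)
class TauRule:
    """Voltage-dependent time constant ``tau(V) = t_min + t_amp * s(V)``.

    ``s(V) = 1 / (1 + exp(-k (V + theta)))`` is a Boltzmann ramp, so the
    time constant interpolates smoothly between ``t_min`` (far on one side
    of ``-theta``) and ``t_min + t_amp`` (far on the other side).
    """

    t_min: float
    t_amp: float
    k: float
    theta: float

    def __call__(self, v: float) -> float:
        return self.t_min + self.t_amp / (1.0 + np.exp(-self.k * (v + self.theta)))


@dataclass(frozen=True)
class GateSpec:
    """Boltzmann gate: slope, half-activation offset, power, kinetics.

    The steady state is ``x_inf(V) = 1/(1+exp(-orientation*k*(V+theta)))``;
    ``orientation=+1`` activates with depolarization, ``-1`` with
    hyperpolarization.  ``tau`` is a constant (seconds), a :class:`TauRule`,
    or ``None`` for an instantaneous gate.
    """

    k: float
    theta: float
    power: int
    tau: float | TauRule | None
    orientation: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"gate slope must be positive, got {self.k}")
        if self.power not in (1, 2, 3):
            raise ValueError(f"gate power must be 1, 2 or 3, got {self.power}")
        if self.orientation not in (+1, -1):
            raise ValueError("orientation must be +1 or -1")
        if isinstance(self.tau, (int, float)) and self.tau <= 0:
            raise ValueError("constant tau must be positive")


def gate_steady_state(v, spec: GateSpec):
    """Steady-state activation of a Boltzmann gate, strictly inside (0, 1)."""
    return 1.0 / (1.0 + np.exp(-spec.orientation * spec.k * (np.asarray(v, float) + spec.theta)))


def gate_tau(v, spec: GateSpec):
    """Time constant of a gate at voltage ``v`` (None for instantaneous gates)."""
    if spec.tau is None:
        return None
    if isinstance(spec.tau, TauRule):
        return spec.tau(v)
    return spec.tau * np.ones_like(np.asarray(v, float)) if np.ndim(v) else float(spec.tau)


# Gate shape constants inherited from the predecessor reduced interneuron
# model; I_pol, the h-gate slope and the Na-inactivation time constant are
# calibrated against the published saddle-node anchor locations of the
# reference parameterization (see docs/methods.md and
# scripts/calibrate_model.py, which reproduces these numbers).
_K_MNA, _TH_MNA = 150.0, 0.0305
_K_HNA, _TH_HNA = 500.0, 0.0325
_K_MK2, _TAU_MK2 = 83.0, 2.0
_TAU_MH_DEFAULT = TauRule(t_min=0.07, t_amp=0.17, k=100.0, theta=0.073)

# The h-gate steady state is a double-exponential sigmoid,
#   m_inf_h(V) = 1 / (1 + 2 exp(k1 (V + theta_h)) + exp(k2 (V + theta_h))),
# after the h-current literature this model descends from: the shallow k1
# component shapes the activation foot around rest (where the SNIC fold
# lives) while the steep k2 component switches the current off during
# interspike dips, which keeps the fold of periodic orbits nearly
# independent of theta_h.  k2 is the canonical steep slope; k1 and I_pol
# come out of the equilibrium-fold calibration.
_K_MH2_DEFAULT = 500.0

_I_POL_DEFAULT = -0.00600400354335309  # nA, equilibrium-fold anchor + path-side constraint
_K_MH_DEFAULT = 180.7425229692763  # 1/V, same solve
_TAU_HNA_DEFAULT = 0.16330279762105945  # s, from the orbit-fold anchor (dynamical bisection)


@dataclass(frozen=True)
class NeuronParams:
    """Full biophysical parameterization of the single cell.

    Conductances in nS, reversal potentials in volts, capacitance in nF,
    polarizing current in nA.  ``theta_k2`` and ``theta_h`` are the two
    bifurcation parameters (volts).
    """

    g_na: float = 105.0
    g_k2: float = 30.0
    g_h: float = 4.0
    g_leak: float = 8.0
    e_na: float = 0.045
    e_k: float = -0.07
    e_h: float = -0.021
    e_leak: float = -0.046
    c: float = 2.0
    i_pol: float = _I_POL_DEFAULT
    theta_k2: float = -0.0075
    theta_h: float = 0.038
    k_mna: float = _K_MNA
    theta_mna: float = _TH_MNA
    k_hna: float = _K_HNA
    theta_hna: float = _TH_HNA
    tau_hna: float = _TAU_HNA_DEFAULT
    k_mk2: float = _K_MK2
    tau_mk2: float = _TAU_MK2
    k_mh: float = _K_MH_DEFAULT
    k_mh2: float = _K_MH2_DEFAULT
    tau_mh: TauRule = field(default=_TAU_MH_DEFAULT)

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k2", "g_h", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.c <= 0:
            raise ValueError("capacitance must be positive")
        if not (self.e_k < self.e_leak < self.e_h < self.e_na):
            raise ValueError("reversal potentials must be ordered E_K < E_leak < E_h < E_Na")

    # -- gate specifications -------------------------------------------------
    @property
    def m_na(self) -> GateSpec:
        return GateSpec(self.k_mna, self.theta_mna, 3, None, +1)

    @property
    def h_na(self) -> GateSpec:
        return GateSpec(self.k_hna, self.theta_hna, 1, self.tau_hna, -1)

    @property
    def m_k2(self) -> GateSpec:
        return GateSpec(self.k_mk2, self.theta_k2, 2, self.tau_mk2, +1)

    def m_h_inf(self, v):
        """Steady state of the h gate: double-exponential sigmoid in
        ``(V + theta_h)`` (see the module constants for the form)."""
        x = np.asarray(v, dtype=float) + self.theta_h
        m = 1.0 / (1.0 + 2.0 * np.exp(self.k_mh * x) + np.exp(self.k_mh2 * x))
        return m if m.ndim else float(m)

    def replace(self, **kwargs) -> "NeuronParams":
        return dataclasses.replace(self, **kwargs)

    def pack(self) -> np.ndarray:
        """Flatten into the parameter vector consumed by the numba kernels."""
        t = self.tau_mh
        return np.array(
            [
                self.g_na, self.g_k2, self.g_h, self.g_leak,
                self.e_na, self.e_k, self.e_h, self.e_leak,
                self.c, self.i_pol,
                self.k_mna, self.theta_mna,
                self.k_hna, self.theta_hna, self.tau_hna,
                self.k_mk2, self.theta_k2, self.tau_mk2,
                self.k_mh, self.theta_h,
                t.t_min, t.t_amp, t.k, t.theta,
                self.k_mh2,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class NeuronState:
    """Membrane potential (V) and the three dynamic gates, all dimensionless in [0, 1]."""

    v: float
    h_na: float
    m_k2: float
    m_h: float

    _GATE_SLACK = 1e-9

    def __post_init__(self) -> None:
        for name in ("h_na", "m_k2", "m_h"):
            x = getattr(self, name)
            if not (-self._GATE_SLACK <= x <= 1.0 + self._GATE_SLACK):
                raise ValueError(f"gate {name}={x} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.h_na, self.m_k2, self.m_h], dtype=float)

    @classmethod
    def from_array(cls, y) -> "NeuronState":
        v, h, m, mh = (float(x) for x in y)
        return cls(v, min(max(h, 0.0), 1.0), min(max(m, 0.0), 1.0), min(max(mh, 0.0), 1.0))


@dataclass(frozen=True)
class CurrentBreakdown:
    """Per-current contributions (nA) and the resulting dV/dt (V/s)."""

    i_na: float
    i_k2: float
    i_h: float
    i_leak: float
    i_ext: float
    total: float  # dV/dt = (-i_na - i_k2 - i_h - i_leak + i_pol + i_ext) / C


def steady_state_gates(v, params: NeuronParams):
    """(h_Na, m_K2, m_h) with every gate at its steady state for voltage ``v``."""
    return (
        gate_steady_state(v, params.h_na),
        gate_steady_state(v, params.m_k2),
        params.m_h_inf(v),
    )


def ionic_currents(state: NeuronState, params: NeuronParams, i_ext: float = 0.0) -> CurrentBreakdown:
    """Evaluate every membrane current at a state (outward positive)."""
    v = state.v
    m_na = gate_steady_state(v, params.m_na)
    i_na = params.g_na * m_na**3 * state.h_na * (v - params.e_na)
    i_k2 = params.g_k2 * state.m_k2**2 * (v - params.e_k)
    i_h = params.g_h * state.m_h**2 * (v - params.e_h)
    i_leak = params.g_leak * (v - params.e_leak)
    total = (-i_na - i_k2 - i_h - i_leak + params.i_pol + i_ext) / params.c
    return CurrentBreakdown(float(i_na), float(i_k2), float(i_h), float(i_leak), float(i_ext), float(total))


def rhs(state: NeuronState, params: NeuronParams, i_ext: float = 0.0) -> np.ndarray:
    """Time derivative (dV/dt, dh_Na/dt, dm_K2/dt, dm_h/dt) at a state."""
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state {y}: integration blow-up")
    dv = ionic_currents(state, params, i_ext).total
    dh = (gate_steady_state(state.v, params.h_na) - state.h_na) / params.tau_hna
    dm = (gate_steady_state(state.v, params.m_k2) - state.m_k2) / params.tau_mk2
    tau_mh = params.tau_mh(state.v)
    dmh = (params.m_h_inf(state.v) - state.m_h) / tau_mh
    return np.array([dv, dh, dm, dmh], dtype=float)


def steady_state_current(v, params: NeuronParams, theta_h: float | None = None):
    """Total membrane current (nA, outward positive) with all gates at steady state.

    Zeros of this function are full-system equilibria; a simultaneous zero
    of its V-derivative marks the saddle-node of equilibria.  ``theta_h``
    optionally overrides the h half-activation parameter, which is the
    variable solved for when locating that fold.
    """
    p = params if theta_h is None else params.replace(theta_h=theta_h)
    v = np.asarray(v, dtype=float)
    m_na = gate_steady_state(v, p.m_na)
    h_na, m_k2, m_h = steady_state_gates(v, p)
    i = (
        p.g_na * m_na**3 * h_na * (v - p.e_na)
        + p.g_k2 * m_k2**2 * (v - p.e_k)
        + p.g_h * m_h**2 * (v - p.e_h)
        + p.g_leak * (v - p.e_leak)
        - p.i_pol
    )
    return i if i.ndim else float(i)


def steady_state_current_dv(v, params: NeuronParams, theta_h: float | None = None, h: float = 1e-7):
    """Central-difference V-derivative of :func:`steady_state_current` (nA/V)."""
    return (
        steady_state_current(np.asarray(v, float) + h, params, theta_h)
        - steady_state_current(np.asarray(v, float) - h, params, theta_h)
    ) / (2.0 * h)


def equilibrium_state(v: float, params: NeuronParams) -> NeuronState:
    """State with all gates at steady state for voltage ``v``."""
    h_na, m_k2, m_h = steady_state_gates(v, params)
    return NeuronState(float(v), float(h_na), float(m_k2), float(m_h))
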