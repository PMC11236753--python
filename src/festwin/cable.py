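"""Linear cable model of a myelinated fiber.

The model collapses all ionic currents at each node of Ranvier into one
time-invariant leak and treats the myelinated internode as a perfect
insulator bridged by a single axial conductance.  With V_m,n the membrane
potential deviation from rest at node n and V_e,n the extracellular
potential there, the node equation is

    C_m dV_m,n/dt = G_a (V_m,n-1 - 2 V_m,n + V_m,n+1
                         + V_e,n-1 - 2 V_e,n + V_e,n+1) - G_m V_m,n

with sealed ends (one-sided differences at the terminal nodes).  A fiber is
considered activated when the absolute membrane potential V_r + V_m reaches
the firing threshold V_th at any node within the simulated window.

The system is linear and time-invariant with a symmetric negative-definite
state matrix, so the default integrator diagonalises it once and advances
each eigenmode exactly for the piecewise-linear drive — no time-step error
and unconditional stability.  A backward-Euler integrator is provided as an
independent alternative and for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded, eigh

from . import fixtures
from .errors import ModelError
from .pulse import StimulusPulse

_UM = 1e-6   # µm -> m
_US = 1e-6   # µs -> s


@dataclass(frozen=True)
class CableParams:
    """Axon and membrane constants of the linear cable model.

    Units: rho_i in Ohm*m, g_m in S/m^2, c_m in F/m^2, node_length in µm,
    potentials in mV, times in µs.  ``axon_ratio`` is the axon-to-fiber
    diameter ratio (the node diameter convention is not fixed by the source
    tables; 0.7 is the classical value in this model lineage).
    """

    axon_ratio: float = 0.7
    rho_i_ohm_m: float = 0.7
    g_m_S_per_m2: float = 304.0          # 30.4 mS/cm^2
    c_m_F_per_m2: float = 0.02           # 2 µF/cm^2
    node_length_um: float = 2.5
    v_rest_mV: float = -70.0
    v_thresh_mV: float = -55.0
    dt_us: float = 1.0
    post_pulse_us: float = 1000.0        # simulated window extends past the pulse

    def __post_init__(self) -> None:
        if self.v_thresh_mV <= self.v_rest_mV:
            raise ValueError("threshold potential must exceed resting potential")
        if self.dt_us <= 0:
            raise ValueError("dt must be > 0")
        for name in ("axon_ratio", "rho_i_ohm_m", "g_m_S_per_m2",
                     "c_m_F_per_m2", "node_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def threshold_depolarization_mV(self) -> float:
        return self.v_thresh_mV - self.v_rest_mV

    @classmethod
    def from_fixture(cls, **overrides) -> "CableParams":
        """Build from the shipped constants table (unit conversions applied)."""
        c = fixtures.load_cable_constants()
        kw = dict(
            rho_i_ohm_m=c["specific_axon_resistance"],
            g_m_S_per_m2=c["membrane_conductance_per_area"] * 10.0,   # mS/cm^2 -> S/m^2
            c_m_F_per_m2=c["membrane_capacitance_per_area"] * 1e-2,   # µF/cm^2 -> F/m^2
            node_length_um=c["node_length"],
            v_rest_mV=c["resting_potential"],
            v_thresh_mV=c["threshold_potential"],
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class NodeConstants:
    """Lumped per-node electrical constants (SI units)."""

    C_m: float   # node capacitance, F
    G_a: float   # internodal axial conductance, S
    G_m: float   # node membrane conductance, S

    def __post_init__(self) -> None:
        if min(self.C_m, self.G_a, self.G_m) <= 0:
            raise ValueError("node constants must be > 0")


def derive_node_constants(d_fiber_um: float, delta_x_um: float,
                          params: CableParams) -> NodeConstants:
    """Diameter-dependent node constants.

    With axon diameter d_a = axon_ratio * d_fiber:
    G_a = pi d_a^2 / (4 rho_i delta_x),  C_m = c_m pi d_a L,
    G_m = g_m pi d_a L.
    """
    d_a = params.axon_ratio * d_fiber_um * _UM
    dx = delta_x_um * _UM
    L = params.node_length_um * _UM
    return NodeConstants(
        C_m=params.c_m_F_per_m2 * np.pi * d_a * L,
        G_a=np.pi * d_a ** 2 / (4.0 * params.rho_i_ohm_m * dx),
        G_m=params.g_m_S_per_m2 * np.pi * d_a * L,
    )


def second_difference_matrix(n: int) -> np.ndarray:
    """Sealed-end second-difference operator (symmetric, tridiagonal)."""
    if n < 3:
        raise ModelError(f"cable model needs >= 3 nodes, got {n}")
    L = np.zeros((n, n))
    idx = np.arange(n - 1)
    L[idx, idx + 1] = 1.0
    L[idx + 1, idx] = 1.0
    L[np.arange(n), np.arange(n)] = -2.0
    L[0, 0] = L[-1, -1] = -1.0
    return L


@dataclass
class ActivationVerdict:
    """Outcome of one fiber's excitation test."""

    fiber_id: int
    activated: bool
    peak_depolarization_mV: float
    peak_node: int
    model: str   # "LC" | "AF"


@dataclass
class LCResult:
    """Membrane trajectory and verdict from one cable-model run."""

    t_us: np.ndarray
    v_m_mV: np.ndarray        # (n_nodes, n_t), deviation from rest
    verdict: ActivationVerdict


def _system(constants: NodeConstants, n_nodes: int):
    L = second_difference_matrix(n_nodes)
    A = (constants.G_a * L - constants.G_m * np.eye(n_nodes)) / constants.C_m
    drive_gain = constants.G_a / constants.C_m
    return L, A, drive_gain


def _phi_coeffs(lam: np.ndarray, h: float):
    """Exact per-step mode propagation for linearly interpolated drive."""
    lh = lam * h
    E = np.exp(lh)
    em1 = np.expm1(lh)
    hphi1 = em1 / lam
    hphi2 = (em1 - lh) / (lam ** 2 * h)
    return E, hphi1 - hphi2, hphi2


def simulate_lc(ve_mV: np.ndarray, t_us: np.ndarray, constants: NodeConstants,
                params: CableParams, method: str = "exact",
                fiber_id: int = -1) -> LCResult:
    """Integrate the cable equation for sampled extracellular potentials.

    ``ve_mV`` has shape (n_nodes, n_t) on the uniform time grid ``t_us``;
    the drive is treated as piecewise linear between samples.  ``method``
    is ``"exact"`` (modal exponential integrator, default) or
    ``"backward_euler"``.
    """
    ve = np.atleast_2d(np.asarray(ve_mV, dtype=float))
    t = np.asarray(t_us, dtype=float)
    if ve.shape[1] != len(t):
        raise ModelError("ve_mV and t_us have inconsistent lengths")
    steps = np.diff(t)
    if len(steps) == 0 or not np.allclose(steps, steps[0]):
        raise ModelError("t_us must be a uniform grid with >= 2 samples")
    h = steps[0] * _US

    n = ve.shape[0]
    L, A, gain = _system(constants, n)
    drive = gain * (L @ ve)          # mV/s

    if method == "exact":
        lam, Q = eigh(A)
        G = Q.T @ drive
        E, c0, c1 = _phi_coeffs(lam, h)
        y = np.zeros_like(G)
        for k in range(1, G.shape[1]):
            y[:, k] = E * y[:, k - 1] + c0 * G[:, k - 1] + c1 * G[:, k]
        vm = Q @ y
    elif method == "backward_euler":
        M = np.eye(n) - h * A
        ab = np.zeros((2, n))
        ab[0, 1:] = np.diag(M, 1)
        ab[1, :] = np.diag(M)
        cb = cholesky_banded(ab)
        vm = np.zeros_like(ve)
        for k in range(1, ve.shape[1]):
            vm[:, k] = cho_solve_banded((cb, False),
                                        vm[:, k - 1] + h * drive[:, k])
            if not np.all(np.isfinite(vm[:, k])):
                raise ModelError(
                    "backward-Euler integration diverged; reduce dt_us")
    else:
        raise ValueError(f"unknown integration method {method!r}")

    flat = int(np.argmax(vm))
    peak_node, peak_t = np.unravel_index(flat, vm.shape)
    peak = float(vm[peak_node, peak_t])
    activated = params.v_rest_mV + peak >= params.v_thresh_mV - 1e-12
    return LCResult(t, vm, ActivationVerdict(fiber_id, bool(activated),
                                             peak, int(peak_node), "LC"))


def _pwl_modal_response(lam: np.ndarray, gamma: np.ndarray,
                        bt_s: np.ndarray, bi: np.ndarray,
                        t_s: np.ndarray) -> np.ndarray:
    """Exact modal response y(t) to drive gamma * w(t), w piecewise linear.

    ``lam`` (m,) eigenvalues (< 0), ``gamma`` (m,) modal drive amplitudes,
    breakpoints (bt_s, bi) of w, evaluation times t_s.  Returns (m, T).
    """
    m, T = len(lam), len(t_s)
    y = np.zeros((m, T))
    y0 = np.zeros(m)
    t_prev = bt_s[0]
    lam_c = lam[:, None]

    for seg in range(len(bt_s) - 1):
        t0, t1 = bt_s[seg], bt_s[seg + 1]
        if t1 <= t0:
            continue
        w0, w1 = bi[seg], bi[seg + 1]
        slope = (w1 - w0) / (t1 - t0)
        sel = (t_s > t0) & (t_s <= t1)
        if np.any(sel):
            tau = (t_s[sel] - t0)[None, :]
            elt = np.exp(lam_c * tau)
            phi_a = (elt - 1.0) / lam_c
            phi_b = (elt - 1.0 - lam_c * tau) / lam_c ** 2
            y[:, sel] = elt * y0[:, None] + gamma[:, None] * (w0 * phi_a + slope * phi_b)
        tau_f = t1 - t0
        elt_f = np.exp(lam * tau_f)
        y0 = elt_f * y0 + gamma * (w0 * (elt_f - 1.0) / lam +
                                   slope * (elt_f - 1.0 - lam * tau_f) / lam ** 2)
        t_prev = t1

    sel = t_s > t_prev
    if np.any(sel):
        y[:, sel] = np.exp(lam_c * (t_s[sel] - t_prev)[None, :]) * y0[:, None]
    return y


def lc_response_to_pulse(ve_unit_mV: np.ndarray, pulse: StimulusPulse,
                         constants: NodeConstants, params: CableParams,
                         t_us: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Membrane trajectory for a separable field ``V_e = ve_unit * I(t)``.

    ``ve_unit_mV`` holds the per-node unit-current potentials (mV per mA);
    the pulse supplies I(t).  Exact modal integration against the
    piecewise-linear waveform; returns (t_us, v_m_mV).
    """
    ve_unit = np.asarray(ve_unit_mV, dtype=float)
    n = len(ve_unit)
    L, A, gain = _system(constants, n)
    lam, Q = eigh(A)
    gamma = Q.T @ (gain * (L @ ve_unit))
    if t_us is None:
        t_end = pulse.duration_us + params.post_pulse_us
        t_us = np.arange(0.0, t_end + params.dt_us / 2.0, params.dt_us)
    bt, bi = pulse.breakpoints
    y = _pwl_modal_response(lam, gamma, bt * _US, bi, np.asarray(t_us) * _US)
    return np.asarray(t_us), Q @ y


class FiberResponseOperator:
    """Precomputed modal operator for one fiber under a fixed unit field.

    Factors the state matrix once so responses and thresholds for many
    pulse widths (e.g. a whole strength-duration curve) reuse the same
    eigendecomposition.
    """

    def __init__(self, ve_unit_mV: np.ndarray, constants: NodeConstants,
                 params: CableParams):
        ve_unit = np.asarray(ve_unit_mV, dtype=float)
        L, A, gain = _system(constants, len(ve_unit))
        self.params = params
        self.lam, self.Q = eigh(A)
        self.gamma = self.Q.T @ (gain * (L @ ve_unit))

    def response(self, pulse: StimulusPulse,
                 t_us: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        if t_us is None:
            t_end = pulse.duration_us + self.params.post_pulse_us
            t_us = np.arange(0.0, t_end + self.params.dt_us / 2.0,
                             self.params.dt_us)
        bt, bi = pulse.breakpoints
        y = _pwl_modal_response(self.lam, self.gamma, bt * _US, bi,
                                np.asarray(t_us) * _US)
        return np.asarray(t_us), self.Q @ y

    def peak_depolarization(self, pulse: StimulusPulse) -> float:
        _, vm = self.response(pulse)
        return float(vm.max())

    def threshold_amplitude(self, pulse_width_us: float,
                            ramp_in_us: float = 10.0,
                            ramp_out_us: float = 10.0) -> float:
        """Closed-form threshold (mA); +inf when nothing depolarizes."""
        unit = StimulusPulse(1.0, pulse_width_us, ramp_in_us, ramp_out_us)
        peak = self.peak_depolarization(unit)
        if peak <= 0.0:
            return float("inf")
        return self.params.threshold_depolarization_mV / peak


def fiber_threshold_amplitude(ve_unit_mV: np.ndarray, pulse_width_us: float,
                              constants: NodeConstants, params: CableParams,
                              ramp_in_us: float = 10.0,
                              ramp_out_us: float = 10.0) -> float:
    """Smallest pulse amplitude (mA) that activates the fiber.

    Exploits linearity: the depolarization response D_n(t) to a 1 mA pulse
    scales with amplitude, so the threshold is
    (V_th - V_r) / max_{n,t} D_n(t).  If the field hyperpolarizes every
    node at all times the fiber is unexcitable and +inf is returned.
    """
    unit = StimulusPulse(1.0, pulse_width_us, ramp_in_us, ramp_out_us)
    _, vm = lc_response_to_pulse(ve_unit_mV, unit, constants, params)
    peak = float(vm.max())
    if peak <= 0.0:
        return float("inf")
    return params.threshold_depolarization_mV / peak
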