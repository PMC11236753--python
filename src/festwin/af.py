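"""Activating function: second spatial difference of the external potential.

The activating function (AF) approximates the drive term of the cable
equation: f = d^2 V_e / dx^2 along the fiber.  Discretely, at interior
nodes,

    AF_n = (V_e,n-1 - 2 V_e,n + V_e,n+1) / delta_x^2

with the terminal nodes excluded (no centred difference exists there).
Positive values indicate membrane depolarization; a cathodic electrode
therefore produces positive AF beneath itself.  AF values and thresholds
are expressed in V/m^2.

Whether a given peak AF suffices for activation depends mainly on axon
diameter and pulse width, so prediction uses a threshold lookup over
(d, PW).  The cited lookup values are not reproduced in the source
material; the default table shipped here is a stand-in generated by
calibrating against the linear cable model on a canonical point-source
field (for each grid point, the field strength at the LC threshold is
found and the corresponding peak AF recorded).  A user-supplied CSV table
overrides the calibrated default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .cable import (ActivationVerdict, CableParams, derive_node_constants,
                    fiber_threshold_amplitude)
from .errors import ModelError
from .fibers import internodal_distance_um


def activating_function(ve_mV: np.ndarray, delta_x_um: float) -> np.ndarray:
    """Discrete AF at the interior nodes, in V/m^2.

    ``ve_mV`` holds per-node extracellular potentials in mV (typically at
    the pulse plateau); endpoints are excluded, so the result has n-2
    entries.  1 mV/mm^2 equals 1000 V/m^2; the conversion is applied here.
    """
    ve = np.asarray(ve_mV, dtype=float)
    if ve.ndim != 1 or len(ve) < 3:
        raise ModelError("activating function needs >= 3 nodes")
    dx_mm = delta_x_um / 1000.0
    return 1000.0 * (ve[:-2] - 2.0 * ve[1:-1] + ve[2:]) / dx_mm ** 2


def point_source_potential_mV(points_mm: np.ndarray, source_mm: np.ndarray,
                              rho_ohm_m: float, current_mA: float) -> np.ndarray:
    """Monopole potential rho*I/(4 pi r) in an infinite homogeneous medium.

    Used as the canonical calibration field and as an analytic oracle.
    Potentials in mV for currents in mA and distances in mm.
    """
    r_m = np.linalg.norm(np.atleast_2d(points_mm) - source_mm, axis=1) * 1e-3
    return 1000.0 * rho_ohm_m * (current_mA * 1e-3) / (4.0 * np.pi * r_m)


@dataclass
class AFThresholdTable:
    """Peak-AF activation thresholds over a (diameter, pulse width) grid.

    Thresholds are in V/m^2, positive, and non-increasing in diameter at
    fixed pulse width (thicker fibers need less drive).  Queries inside the
    grid interpolate bilinearly; outside they clamp to the edge with a
    warning.
    """

    diameters_um: np.ndarray
    pulse_widths_us: np.ndarray
    thresholds: np.ndarray    # (n_d, n_pw)

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        self.pulse_widths_us = np.asarray(self.pulse_widths_us, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.size == 0:
            raise ModelError("empty AF threshold table")
        if self.thresholds.shape != (len(self.diameters_um),
                                     len(self.pulse_widths_us)):
            raise ModelError("AF table shape mismatch")
        if np.any(self.thresholds <= 0):
            raise ModelError("AF thresholds must be > 0")
        if np.any(np.diff(self.thresholds, axis=0) > 1e-9):
            warnings.warn("AF thresholds not non-increasing in diameter",
                          stacklevel=2)

    def lookup(self, d_um: float, pw_us: float) -> float:
        d_lo, d_hi = self.diameters_um[0], self.diameters_um[-1]
        p_lo, p_hi = self.pulse_widths_us[0], self.pulse_widths_us[-1]
        if not (d_lo <= d_um <= d_hi) or not (p_lo <= pw_us <= p_hi):
            warnings.warn(
                f"(d={d_um:g} µm, PW={pw_us:g} µs) outside AF table grid; "
                f"clamping to the edge", stacklevel=2)
        d = float(np.clip(d_um, d_lo, d_hi))
        p = float(np.clip(pw_us, p_lo, p_hi))
        interp = RegularGridInterpolator(
            (self.diameters_um, self.pulse_widths_us), self.thresholds)
        return float(interp([[d, p]])[0])

    # -- CSV round trip ---------------------------------------------------
    def to_csv(self, path) -> None:
        rows = [(d, p, self.thresholds[i, j])
                for i, d in enumerate(self.diameters_um)
                for j, p in enumerate(self.pulse_widths_us)]
        pd.DataFrame(rows, columns=["d_um", "pw_us", "threshold"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AFThresholdTable":
        df = pd.read_csv(path)
        d = np.sort(df["d_um"].unique())
        p = np.sort(df["pw_us"].unique())
        thr = df.pivot(index="d_um", columns="pw_us",
                       values="threshold").loc[d, p].to_numpy()
        return cls(d, p, thr)


def af_predict(af_values_mV_mm2: np.ndarray, d_um: float, pw_us: float,
               table: AFThresholdTable, fiber_id: int = -1) -> ActivationVerdict:
    """AF-based activation verdict: max interior AF vs interpolated threshold."""
    af = np.asarray(af_values_mV_mm2, dtype=float)
    peak = float(af.max()) if af.size else 0.0
    thr = table.lookup(d_um, pw_us)
    node = int(np.argmax(af)) + 1 if af.size else -1
    return ActivationVerdict(fiber_id, bool(peak >= thr), peak, node, "AF")


# calibration field: point source 10 mm above the fiber in a muscle-like medium
_CAL_HEIGHT_MM = 10.0
_CAL_RHO_OHM_M = 3.0
_CAL_FIBER_LEN_MM = 60.0


def _calibration_nodes(d_um: float) -> tuple[np.ndarray, float]:
    dx_um = float(internodal_distance_um(d_um))
    dx_mm = dx_um / 1000.0
    half = _CAL_FIBER_LEN_MM / 2.0
    x = np.arange(-half, half + 1e-9, dx_mm)
    nodes = np.zeros((len(x), 3))
    nodes[:, 0] = x
    return nodes, dx_um


def calibration_unit_potentials(d_um: float) -> tuple[np.ndarray, float]:
    """Per-node potentials (mV per mA, cathodic) of the calibration field."""
    nodes, dx_um = _calibration_nodes(d_um)
    src = np.array([0.0, 0.0, _CAL_HEIGHT_MM])
    ve = point_source_potential_mV(nodes, src, _CAL_RHO_OHM_M, -1.0)
    return ve, dx_um


@lru_cache(maxsize=8)
def _default_table_cached(params: CableParams,
                          diameters: tuple, pulse_widths: tuple) -> AFThresholdTable:
    thr = np.empty((len(diameters), len(pulse_widths)))
    for i, d in enumerate(diameters):
        ve_unit, dx_um = calibration_unit_potentials(d)
        constants = derive_node_constants(d, dx_um, params)
        af_unit_peak = float(activating_function(ve_unit, dx_um).max())
        for j, pw in enumerate(pulse_widths):
            a_th = fiber_threshold_amplitude(ve_unit, pw, constants, params)
            thr[i, j] = a_th * af_unit_peak
    return AFThresholdTable(np.array(diameters), np.array(pulse_widths), thr)


def default_af_threshold_table(
        params: CableParams | None = None,
        diameters_um: tuple = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0),
        pulse_widths_us: tuple = (20.0, 50.0, 100.0, 200.0, 300.0, 500.0),
) -> AFThresholdTable:
    """Calibrate the default AF threshold table against the LC model.

    Deterministic (no randomness) and cached per parameter set.  For each
    (d, PW) the LC threshold amplitude on the canonical point-source field
    is found in closed form and the peak AF at that amplitude recorded as
    the threshold.
    """
    params = params or CableParams()
    return _default_table_cached(params, tuple(diameters_um), tuple(pulse_widths_us))
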