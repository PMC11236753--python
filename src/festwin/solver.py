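"""Resistive quasi-static potential solve on the conductor grid.

The capacitive term of the full quasi-static formulation is dropped (linear
media, rectangular pulses), leaving the conduction problem

    div( sigma grad V ) = 0

with a total current +I injected uniformly over the active electrode face,
-I drained over the indifferent face, and zero normal flux elsewhere (the
surrounding air is neglected).  The indifferent electrode face is the
potential reference (V = 0).  Discretization is a 7-point finite-volume
stencil with harmonic-mean face conductances; the sink is imposed as a
Dirichlet condition on the outer faces of the indifferent hydrogel voxels,
so the reference sits on the electrode *face*, half a voxel outside the
last voxel centre.

Because the problem is linear, one unit-current solve (1 mA) determines the
potential for every amplitude and, combined with the pulse waveform, every
instant: V_e(p, t) = V_unit(p) * I(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt

from .errors import GeometryError, SolverError
from .grid import ConductorGrid
from .pulse import StimulusPulse

_MM = 1e-3  # mm -> m


@dataclass
class PotentialField:
    """Grid potential for a given injected current.

    ``v_per_mA`` is the potential in volts per 1 mA of injected current at
    every voxel centre (NaN in air).  The field is linear in the injected
    current by construction.
    """

    grid: ConductorGrid
    v_per_mA: np.ndarray
    injected_current_mA: float
    residual: float
    interpolation_order: int = 1
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            filled = self.v_per_mA
            if np.any(np.isnan(filled)):
                # extend values into air so trilinear stencils near the
                # boundary have data; queries are still restricted to the box
                mask = np.isnan(filled)
                _, idx = distance_transform_edt(mask, return_indices=True)
                filled = filled[tuple(idx)]
            self._interp = RegularGridInterpolator(
                self.grid.axes_mm(), filled, method="linear",
                bounds_error=False, fill_value=np.nan)
        return self._interp

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear sample of the unit-current potential, volts per mA."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        xs, ys, zs = self.grid.axes_mm()
        lo = np.array([xs[0], ys[0], zs[0]])
        hi = np.array([xs[-1], ys[-1], zs[-1]])
        bad = np.any((pts < lo - 1e-9) | (pts > hi + 1e-9), axis=1)
        if np.any(bad):
            raise GeometryError(
                f"points outside the solved grid: {pts[bad][:5].tolist()}")
        return self._interpolator()(pts)

    def sample_time_course(self, points_mm: np.ndarray, pulse: StimulusPulse,
                           t_us: np.ndarray) -> np.ndarray:
        """Extracellular potential time courses, mV, shape (n_points, n_t).

        Space and time separate under the resistive approximation:
        V_e(p, t) = V_unit(p) x I(t), with V_unit in V/mA and I in mA.
        """
        v_unit = self.sample(points_mm)          # V per mA
        i_t = pulse.waveform(np.asarray(t_us))   # mA
        return 1000.0 * np.outer(v_unit, i_t)    # mV


def _assemble(grid: ConductorGrid, active: int, indifferent: int):
    res_m = grid.resolution * _MM
    conducting = grid.conducting
    n = int(conducting.sum())
    index = np.full(grid.shape, -1, dtype=np.int64)
    index[conducting] = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        both = conducting[sl_a] & conducting[sl_b]
        sa = grid.sigma[..., axis][sl_a][both]
        sb = grid.sigma[..., axis][sl_b][both]
        g = res_m * 2.0 * sa * sb / (sa + sb)
        ia = index[sl_a][both]
        ib = index[sl_b][both]
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-g, -g])
        np.add.at(diag, ia, g)
        np.add.at(diag, ib, g)

    # Dirichlet V=0 on the outer faces of the indifferent electrode voxels
    sink = grid.face_sets.get(indifferent)
    if sink is None or len(sink) == 0:
        raise SolverError("missing sink: indifferent electrode has no face voxels")
    src = grid.face_sets.get(active)
    if src is None or len(src) == 0:
        raise SolverError("active electrode has no face voxels")
    if {tuple(i) for i in src.idx} & {tuple(i) for i in sink.idx}:
        raise SolverError("active and indifferent electrode footprints overlap")

    for (i, j, k), axis in zip(sink.idx, sink.axis):
        fi = index[i, j, k]
        if fi < 0:
            raise SolverError("indifferent face voxel is not conducting")
        diag[fi] += 2.0 * grid.sigma[i, j, k, axis] * res_m

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))

    src_flat = index[src.idx[:, 0], src.idx[:, 1], src.idx[:, 2]]
    if np.any(src_flat < 0):
        raise SolverError("active face voxel is not conducting")
    return A, index, src_flat


def solve_potential(grid: ConductorGrid, current_mA: float = 1.0,
                    active: int | None = None, indifferent: int | None = None,
                    tol: float = 1e-8) -> PotentialField:
    """Solve for the potential of one electrode pair at a given current.

    ``active``/``indifferent`` are electrode indices into ``grid.face_sets``;
    by default they are found from the electrode roles.  Raises
    :class:`SolverError` for a missing sink or a residual above ``tol``.
    """
    if active is None or indifferent is None:
        roles = grid.electrode_roles
        try:
            active = next(i for i, r in roles.items() if r == "different")
            indifferent = next(i for i, r in roles.items() if r == "indifferent")
        except StopIteration as exc:
            raise SolverError(
                "grid must carry one 'different' and one 'indifferent' electrode"
            ) from exc

    A, index, src_flat = _assemble(grid, active, indifferent)
    n = A.shape[0]
    b = np.zeros(n)
    i_si = current_mA * 1e-3
    b[src_flat] += i_si / len(src_flat)

    if current_mA == 0.0:
        v = np.zeros(n)
        residual = 0.0
    else:
        try:
            lu = spla.splu(A.tocsc())
            v = lu.solve(b)
        except RuntimeError as exc:  # pragma: no cover - singular factorization
            raise SolverError(f"singular or ill-posed system: {exc}") from exc
        residual = float(np.linalg.norm(A @ v - b) / np.linalg.norm(b))
        if not np.isfinite(residual) or residual > tol:
            raise SolverError(f"solver did not converge: residual {residual:.3e}")

    v_grid = np.full(grid.shape, np.nan)
    v_grid[grid.conducting] = v
    v_per_mA = v_grid / current_mA if current_mA != 0 else v_grid
    return PotentialField(grid, v_per_mA, current_mA, residual)


def plane_current_mA(field: PotentialField, z_mm: float) -> float:
    """Total axial current (mA per mA injected) through a z = const plane.

    Sums the finite-volume face currents crossing the plane between the two
    voxel layers bracketing ``z_mm``; used to verify current conservation.
    """
    grid = field.grid
    xs, ys, zs = grid.axes_mm()
    if not zs[0] <= z_mm <= zs[-1]:
        raise GeometryError(f"plane z={z_mm} outside grid axial range")
    k = int(np.searchsorted(zs, z_mm))
    k = min(max(k, 1), len(zs) - 1)
    res_m = grid.resolution * _MM
    va = field.v_per_mA[:, :, k - 1]
    vb = field.v_per_mA[:, :, k]
    sa = grid.sigma[:, :, k - 1, 2]
    sb = grid.sigma[:, :, k, 2]
    ok = np.isfinite(va) & np.isfinite(vb) & (sa > 0) & (sb > 0)
    g = res_m * 2.0 * sa[ok] * sb[ok] / (sa[ok] + sb[ok])
    return float(np.sum(g * (va[ok] - vb[ok])) * 1e3)  # A/mA -> mA/mA
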