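"""Linear cable model: node constants, integrators, thresholds, SD shape."""

import numpy as np
import pytest
from scipy.linalg import expm

from festwin.cable import (CableParams, FiberResponseOperator,
                           derive_node_constants, fiber_threshold_amplitude,
                           second_difference_matrix, simulate_lc)
from festwin.errors import ModelError
from festwin.fibers import internodal_distance_um
from festwin.pulse import StimulusPulse

from conftest import bisect_threshold, point_source_fiber


class TestNodeConstants:
    def test_capacitance_for_10um_fiber(self, cable_params):
        """c_m * pi * d_a * L with d_a = 7 µm gives about 1.10 pF."""
        c = derive_node_constants(10.0, 923.6, cable_params)
        assert c.C_m == pytest.approx(1.0996e-12, rel=1e-3)

    def test_axial_conductance_doubles_when_spacing_halves(self, cable_params):
        g1 = derive_node_constants(10.0, 1000.0, cable_params).G_a
        g2 = derive_node_constants(10.0, 500.0, cable_params).G_a
        assert g2 == pytest.approx(2.0 * g1, rel=1e-12)

    def test_threshold_depolarization_is_15_mV(self, cable_params):
        assert cable_params.threshold_depolarization_mV == pytest.approx(15.0)
        assert cable_params.v_rest_mV == -70.0
        assert cable_params.v_thresh_mV == -55.0


class TestRestAndDegenerate:
    @pytest.mark.parametrize("method", ["exact", "backward_euler"])
    def test_zero_drive_holds_rest_for_1e4_steps(self, cable_params, method):
        c = derive_node_constants(8.0, 731.4, cable_params)
        t = np.arange(0.0, 10_000.0, 1.0)
        ve = np.zeros((5, len(t)))
        res = simulate_lc(ve, t, c, cable_params, method=method)
        assert np.max(np.abs(res.v_m_mV)) == 0.0
        assert not res.verdict.activated

    def test_spatially_uniform_field_cannot_activate(self, cable_params):
        """The drive is a spatial second difference; a uniform V_e(t)
        vanishes under it regardless of amplitude."""
        c = derive_node_constants(8.0, 731.4, cable_params)
        t = np.arange(0.0, 500.0, 1.0)
        ve = np.tile(-500.0 * np.sin(t / 50.0), (7, 1))
        res = simulate_lc(ve, t, c, cable_params)
        assert np.max(np.abs(res.v_m_mV)) < 1e-9
        assert not res.verdict.activated

    def test_fewer_than_three_nodes_rejected(self):
        with pytest.raises(ModelError, match="3 nodes"):
            second_difference_matrix(2)


def _augmented_expm_oracle(A, drive, h):
    """Exact trajectory via matrix exponentials of the augmented system.

    For piecewise-linear drive b(t) the block matrix [[A, b0, b1],[0,0,1],
    [0,0,0]] propagates the state exactly over one step."""
    n = A.shape[0]
    x = np.zeros(n)
    out = [x.copy()]
    for k in range(1, drive.shape[1]):
        b0, b1 = drive[:, k - 1], (drive[:, k] - drive[:, k - 1]) / h
        # augmented state [x, s, 1] with ds/dt = 1: x' = A x + b1 s + b0
        M = np.zeros((n + 2, n + 2))
        M[:n, :n] = A
        M[:n, n] = b1
        M[:n, n + 1] = b0
        M[n, n + 1] = 1.0
        phi = expm(M * h)
        x = phi[:n, :n] @ x + phi[:n, n + 1]
        out.append(x.copy())
    return np.array(out).T


class TestIntegratorOracle:
    @pytest.mark.parametrize("n_nodes", [3, 5, 9])
    def test_integrators_match_matrix_exponential(self, cable_params, n_nodes):
        """Both integrators vs the augmented-expm oracle at dt = 1 µs."""
        c = derive_node_constants(10.0, 900.0, cable_params)
        t = np.arange(0.0, 301.0, 1.0)
        rng = np.random.default_rng(42)
        ve = np.zeros((n_nodes, len(t)))
        ve[:, (t >= 10) & (t <= 210)] = rng.normal(0, 30, (n_nodes, 1))
        L = second_difference_matrix(n_nodes)
        A = (c.G_a * L - c.G_m * np.eye(n_nodes)) / c.C_m
        drive = (c.G_a / c.C_m) * (L @ ve)
        oracle = _augmented_expm_oracle(A, drive, 1e-6)
        scale = np.max(np.abs(oracle))

        exact = simulate_lc(ve, t, c, cable_params, method="exact")
        assert np.max(np.abs(exact.v_m_mV - oracle)) / scale < 1e-3

        # backward Euler is first order: its error against the exact modal
        # solution of the same piecewise-linear drive shrinks with dt
        errs = []
        for refine in (1, 4):
            tf = np.arange(0.0, 300.0 + 1e-9, 1.0 / refine)
            vef = np.vstack([np.interp(tf, t, ve[i]) for i in range(n_nodes)])
            be = simulate_lc(vef, tf, c, cable_params, method="backward_euler")
            ex = simulate_lc(vef, tf, c, cable_params, method="exact")
            errs.append(np.max(np.abs(be.v_m_mV - ex.v_m_mV)) / scale)
        assert errs[1] < errs[0]

    def test_three_node_center_step_matches_closed_form(self, cable_params):
        """Analytic solution of the 3-node system under a centre-node step."""
        c = derive_node_constants(10.0, 900.0, cable_params)
        t = np.arange(0.0, 201.0, 1.0)
        ve = np.zeros((3, len(t)))
        ve[1, t >= 1.0] = -40.0
        res = simulate_lc(ve, t, c, cable_params)
        L = second_difference_matrix(3)
        A = (c.G_a * L - c.G_m * np.eye(3)) / c.C_m
        drive = (c.G_a / c.C_m) * (L @ ve)
        oracle = _augmented_expm_oracle(A, drive, 1e-6)
        assert np.max(np.abs(res.v_m_mV - oracle)) / np.max(np.abs(oracle)) < 1e-3


class TestLinearityAndThreshold:
    def test_response_scales_exactly_with_amplitude(self, cable_params):
        ve, dx, _ = point_source_fiber(8.0)
        c = derive_node_constants(8.0, dx, cable_params)
        op = FiberResponseOperator(ve, c, cable_params)
        _, v1 = op.response(StimulusPulse(1.0, 100.0))
        _, v3 = op.response(StimulusPulse(3.0, 100.0))
        assert np.allclose(v3, 3.0 * v1, rtol=1e-12, atol=1e-12)

    def test_doubling_field_halves_threshold(self, cable_params):
        ve, dx, _ = point_source_fiber(8.0)
        c = derive_node_constants(8.0, dx, cable_params)
        t1 = fiber_threshold_amplitude(ve, 100.0, c, cable_params)
        t2 = fiber_threshold_amplitude(2.0 * ve, 100.0, c, cable_params)
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-12)

    def test_unexcitable_field_returns_infinite_sentinel(self, cable_params):
        """A uniform V_e drives nothing (zero second difference, sealed
        ends included), so the threshold is the unexcitable sentinel.  Any
        spatially varying finite-cable field polarizes some node - even an
        affine one polarizes the sealed ends - so uniform is the clean
        degenerate case."""
        _, dx, x = point_source_fiber(8.0)
        c = derive_node_constants(8.0, dx, cable_params)
        ve = np.full_like(x, 7.5)
        assert fiber_threshold_amplitude(ve, 100.0, c, cable_params) == np.inf
        # affine fields DO polarize the sealed ends (virtual cathode)
        assert np.isfinite(
            fiber_threshold_amplitude(3.0 - 0.5 * x, 100.0, c, cable_params))

    def test_closed_form_agrees_with_bisection(self, cable_params):
        """20 random fibers: closed-form threshold vs bisection < 0.5%."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            d = rng.uniform(3.0, 16.0)
            depth = rng.uniform(6.0, 15.0)
            lat = rng.uniform(-5.0, 5.0)
            pw = rng.uniform(30.0, 400.0)
            ve, dx, _ = point_source_fiber(d, depth, lat)
            c = derive_node_constants(d, dx, cable_params)
            closed = fiber_threshold_amplitude(ve, pw, c, cable_params)
            oracle = bisect_threshold(ve, pw, c, cable_params, rel_tol=5e-4)
            assert closed == pytest.approx(oracle, rel=5e-3)


class TestRecruitmentOrderAndSDShape:
    def test_larger_diameter_has_lower_threshold(self, cable_params):
        """100 random co-located pairs: recruitment order by diameter."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            d_small, d_large = np.sort(rng.uniform(2.0, 16.0, 2))
            if d_large - d_small < 0.5:
                continue
            depth = rng.uniform(8.0, 20.0)
            pw = rng.uniform(50.0, 300.0)
            ths = []
            for d in (d_small, d_large):
                ve, dx, _ = point_source_fiber(d, depth)
                c = derive_node_constants(d, dx, cable_params)
                ths.append(fiber_threshold_amplitude(ve, pw, c, cable_params))
            assert ths[1] <= ths[0] * 1.001

    def test_sd_curve_monotone_convex_with_rheobase_plateau(self, cable_params):
        ve, dx, _ = point_source_fiber(10.0)
        c = derive_node_constants(10.0, dx, cable_params)
        op = FiberResponseOperator(ve, c, cable_params)
        pws = np.arange(20.0, 501.0, 20.0)
        thr = np.array([op.threshold_amplitude(pw) for pw in pws])
        assert np.all(np.diff(thr) <= 1e-9)                  # non-increasing
        assert np.all(np.diff(thr, 2) >= -1e-6 * thr[0])     # convex
        plateau = op.threshold_amplitude(5000.0)
        assert op.threshold_amplitude(500.0) == pytest.approx(plateau, rel=0.10)
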