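"""Muscle recruitment: activation fractions, SD curves, intensity curves."""

import numpy as np
import pytest

from festwin.cable import CableParams, derive_node_constants, simulate_lc
from festwin.errors import ModelError
from festwin.fibers import FiberPopulation
from festwin.pulse import StimulusPulse
from festwin.recruitment import (AthTable, intensity_activation_curve,
                                 population_node_potentials,
                                 population_thresholds,
                                 roi_activation_fraction, sd_curve)

from conftest import point_source_fiber


@pytest.fixture(scope="module")
def demo_thresholds(demo_population, cuboid_field, cable_params):
    return population_thresholds(demo_population, cuboid_field,
                                 [100.0], cable_params)[:, 0]


class TestActivationFraction:
    def test_zero_amplitude_gives_zero_fraction(self, demo_population,
                                                cuboid_field, cable_params):
        frac = roi_activation_fraction(demo_population, cuboid_field,
                                       StimulusPulse(1e-9, 100.0), cable_params)
        assert frac == 0.0

    def test_saturating_amplitude_gives_full_recruitment(
            self, demo_population, cuboid_field, cable_params, demo_thresholds):
        amp = float(np.max(demo_thresholds)) * 1.01
        frac = roi_activation_fraction(demo_population, cuboid_field,
                                       StimulusPulse(amp, 100.0), cable_params)
        assert frac == 1.0

    def test_fraction_matches_independent_verdict_count(
            self, demo_population, cuboid_field, cable_params):
        """Count oracle: simulate every fiber at a fixed amplitude with the
        time-domain model and compare the verdict count."""
        pulse = StimulusPulse(8.0, 100.0)
        frac = roi_activation_fraction(demo_population, cuboid_field, pulse,
                                       cable_params)
        ve_list = population_node_potentials(demo_population, cuboid_field)
        t = np.arange(0.0, pulse.duration_us + cable_params.post_pulse_us,
                      cable_params.dt_us)
        w = pulse.waveform(t)
        n_active = 0
        for fiber, ve_unit in zip(demo_population.fibers, ve_list):
            c = derive_node_constants(fiber.diameter_um, fiber.delta_x_um,
                                      cable_params)
            res = simulate_lc(np.outer(ve_unit, w), t, c, cable_params)
            n_active += int(res.verdict.activated)
        assert frac == pytest.approx(n_active / len(demo_population), abs=1e-9)

    def test_af_model_gives_valid_fraction(self, demo_population, cuboid_field,
                                           cable_params):
        frac = roi_activation_fraction(demo_population, cuboid_field,
                                       StimulusPulse(8.0, 100.0), cable_params,
                                       model="AF")
        assert 0.0 <= frac <= 1.0

    def test_empty_population_rejected(self, demo_roi, cuboid_field):
        empty = FiberPopulation(demo_roi, [])
        with pytest.raises(ModelError, match="empty"):
            roi_activation_fraction(empty, cuboid_field,
                                    StimulusPulse(1.0, 100.0))


class TestSDCurve:
    def test_order_statistic_equals_bisection_search(
            self, demo_population, cuboid_field, cable_params):
        """The closed-form order-statistic threshold equals a bisection on
        the activation fraction for random (PW, ath) pairs."""
        rng = np.random.default_rng(13)
        for _ in range(5):
            pw = float(rng.uniform(30, 450))
            ath = float(rng.uniform(0.1, 0.6))
            curve = sd_curve(demo_population, cuboid_field, [pw], ath,
                             cable_params, amplitude_bounds_mA=(0.0, 500.0))
            target = curve.threshold_mA[0]

            def frac(amp):
                return roi_activation_fraction(
                    demo_population, cuboid_field, StimulusPulse(amp, pw),
                    cable_params)

            lo, hi = 1e-3, 500.0
            for _ in range(22):
                mid = 0.5 * (lo + hi)
                if frac(mid) >= ath:
                    hi = mid
                else:
                    lo = mid
            assert target == pytest.approx(hi, rel=1e-3)

    def test_thresholds_non_increasing_in_pulse_width(
            self, demo_population, cuboid_field, cable_params):
        pws = np.array([20.0, 50.0, 100.0, 200.0, 350.0, 500.0])
        curve = sd_curve(demo_population, cuboid_field, pws, 0.2, cable_params,
                         amplitude_bounds_mA=(0.0, 1e6))
        assert np.all(np.diff(curve.threshold_mA) <= 1e-9)

    def test_experimental_pw_grid_accepted(self, demo_population, cuboid_field,
                                           cable_params):
        from festwin.fixtures import experiment_pw_grid

        grid = experiment_pw_grid()
        assert len(grid) == 13
        curve = sd_curve(demo_population, cuboid_field, grid, 0.2,
                         cable_params, amplitude_bounds_mA=(0.0, 1e6))
        assert len(curve.threshold_mA) == 13

    def test_grid_mode_rounds_up_to_stimulator_steps(
            self, demo_population, cuboid_field, cable_params):
        pws = [50.0, 200.0, 500.0]
        cont = sd_curve(demo_population, cuboid_field, pws, 0.2, cable_params,
                        amplitude_bounds_mA=(1.0, 1e6), mode="continuous")
        grid = sd_curve(demo_population, cuboid_field, pws, 0.2, cable_params,
                        amplitude_bounds_mA=(1.0, 1e6), mode="grid",
                        grid_step_mA=1.0)
        assert np.all(grid.threshold_mA >= cont.threshold_mA - 1e-9)
        assert np.allclose(grid.threshold_mA, np.round(grid.threshold_mA))

    def test_unreachable_threshold_recorded_as_nan(
            self, demo_population, cuboid_field, cable_params, demo_thresholds):
        hi = float(np.sort(demo_thresholds)[int(0.2 * len(demo_thresholds))])
        curve = sd_curve(demo_population, cuboid_field, [100.0], 0.9,
                         cable_params, amplitude_bounds_mA=(0.0, hi))
        assert np.isnan(curve.threshold_mA[0])

    def test_identical_seeds_give_bit_identical_curves(self, cuboid_field,
                                                       cable_params, demo_roi):
        from festwin.fibers import DiameterDistribution, place_fibers

        pws = [50.0, 150.0, 400.0]
        curves = []
        for _ in range(2):
            pop = place_fibers(demo_roi, n=40, dist=DiameterDistribution(),
                               seed=21)
            c = sd_curve(pop, cuboid_field, pws, 0.25, cable_params,
                         amplitude_bounds_mA=(0.0, 1e6))
            curves.append(c.threshold_mA)
        assert np.array_equal(curves[0], curves[1])


class TestIntensityCurve:
    def test_fraction_monotone_and_onset_consistent(
            self, demo_population, cuboid_field, cable_params):
        ath = 0.2
        amps = np.linspace(0.5, 40.0, 80)
        df = intensity_activation_curve(demo_population, cuboid_field, 150.0,
                                        amps, AthTable({"DEMO": (ath, ath)}),
                                        cable_params)
        frac = df["fraction"].to_numpy()
        assert np.all(np.diff(frac) >= 0)
        onset = df.loc[df["active"], "amplitude_mA"].min()
        curve = sd_curve(demo_population, cuboid_field, [150.0], ath,
                         cable_params, amplitude_bounds_mA=(0.0, 1e6))
        # onset is the first grid amplitude at/above the SD threshold
        expected = amps[np.searchsorted(amps, curve.threshold_mA[0] - 1e-9)]
        assert onset == pytest.approx(expected)

    def test_sigmoid_like_rise_over_finite_span(self, demo_population,
                                                cuboid_field, cable_params):
        amps = np.linspace(0.1, 60.0, 240)
        df = intensity_activation_curve(demo_population, cuboid_field, 200.0,
                                        amps, params=cable_params)
        frac = df["fraction"].to_numpy()
        a10 = amps[np.argmax(frac >= 0.1)]
        a90 = amps[np.argmax(frac >= 0.9)]
        assert 0.0 < a90 - a10 < 60.0

    def test_descending_amplitude_grid_rejected(self, demo_population,
                                                cuboid_field):
        with pytest.raises(ValueError, match="ascending"):
            intensity_activation_curve(demo_population, cuboid_field, 100.0,
                                       np.array([3.0, 1.0]))
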