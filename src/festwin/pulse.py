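"""Stimulation pulse: rectangular current pulse with linear ramps.

The stimulator delivers a single rectangular pulse with short ramp-in and
ramp-out flanks; the waveform is the piecewise-linear map

    0 -> ramp_in -> plateau (pulse_width) -> ramp_out -> 0

and is identically zero outside ``[0, ramp_in + pulse_width + ramp_out]``.
Under the resistive quasi-static approximation the extracellular potential
is separable: ``V_e(p, t) = V_unit(p) * waveform(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StimulusPulse:
    """Single stimulation pulse.

    amplitude_mA : plateau current in mA.
    pulse_width_us : plateau duration in µs.
    ramp_in_us / ramp_out_us : linear flank durations in µs (default 10 µs,
        short relative to every pulse width of interest).
    """

    amplitude_mA: float
    pulse_width_us: float
    ramp_in_us: float = 10.0
    ramp_out_us: float = 10.0

    def __post_init__(self) -> None:
        if self.pulse_width_us <= 0:
            raise ValueError("pulse_width_us must be > 0")
        if self.ramp_in_us < 0 or self.ramp_out_us < 0:
            raise ValueError("ramp times must be >= 0")

    @property
    def duration_us(self) -> float:
        return self.ramp_in_us + self.pulse_width_us + self.ramp_out_us

    @property
    def breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(times µs, currents mA) of the piecewise-linear waveform."""
        t = np.array(
            [
                0.0,
                self.ramp_in_us,
                self.ramp_in_us + self.pulse_width_us,
                self.duration_us,
            ]
        )
        i = np.array([0.0, self.amplitude_mA, self.amplitude_mA, 0.0])
        # zero-length ramps collapse duplicate breakpoints; np.interp copes
        return t, i

    def waveform(self, t_us) -> np.ndarray:
        """Current in mA at times ``t_us`` (scalar or array, µs)."""
        t_us = np.asarray(t_us, dtype=float)
        bt, bi = self.breakpoints
        return np.interp(t_us, bt, bi, left=0.0, right=0.0)

    def scaled(self, amplitude_mA: float) -> "StimulusPulse":
        """Same timing, different plateau amplitude."""
        return StimulusPulse(
            amplitude_mA, self.pulse_width_us, self.ramp_in_us, self.ramp_out_us
        )
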