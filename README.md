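# festwin

A desk-scale digital twin of transcutaneous functional electrical
stimulation (FES) on the human forearm, with **muscle-specific activation
resolution**.

FES of the forearm is hard to make selective: many small muscles lie in
several layers, and which one contracts depends on electrode position,
pulse amplitude and pulse width. `festwin` implements the full simulation
chain needed to predict, for a given electrode pair and stimulation
setting, the activation of each individual forearm muscle:

1. **Volume conductor** — a parametric layered phantom (bone, muscle, fat,
   1 mm skin) built from per-station ellipses, with anisotropic muscle
   conductivity (σ_axial = 1/3 S/m, σ_radial = 1/9 S/m) and hydrogel skin
   electrodes placed by an axial/radial surface convention.  The
   quasi-static potential `∇·(σ∇V) = 0` is solved once per electrode pair
   for unit current on a finite-volume voxel grid; linearity and a
   piecewise-linear pulse waveform give `V_e(p, t) = V_unit(p) · I(t)`.
2. **Fiber arrangement** — 20 muscle-specific regions of interest (ROIs)
   anchored at published nerve-entry-point positions, each holding 500
   straight myelinated fibers with a bimodal diameter distribution
   (support 2–16 µm, modes at 5 and 11 µm) and diameter-dependent
   node-of-Ranvier spacing Δx ∈ [155, 1500] µm.
3. **Nerve models** — the linear cable model

   `C_m dV_m,n/dt = G_a (Δ²V_m + Δ²V_e)_n − G_m V_m,n`

   with sealed ends, integrated exactly per eigenmode, plus the activating
   function `f = ∂²V_e/∂x²` with a calibrated (diameter, pulse-width)
   threshold table.  A fiber activates when V_r + V_m reaches −55 mV.
4. **Recruitment & calibration** — the fraction of activated fibers per
   ROI is the muscle activation; a muscle counts as "on" once that
   fraction reaches its activation threshold *ath*.  Strength–duration
   (SD) curves, intensity–activation curves, Weiss fits
   `A(PW) = b(1 + c/PW)`, the relative-difference metric, and the
   per-muscle / per-PW-range *ath* selection pipeline (defaults 0.20 for
   20–200 µs and 0.12 for 201–500 µs) are all provided.

Intended users: biomedical engineers and neurostimulation researchers who
want to explore electrode placements and stimulation settings in
simulation before (or instead of) lengthy, fatigue-limited experiments.

## Worked example

Simulate the extensor carpi ulnaris (ECU) with its published electrode
pair at a coarse 6 mm grid and 100 fibers:

```python
from festwin.config import default_config
from festwin.pipeline import run_pipeline

cfg = default_config()
cfg["solver"]["resolution_mm"] = 6.0
cfg["fibers"]["n_fibers"] = 100
report = run_pipeline(cfg, "out", seed=42)
```

which prints/writes (abridged):

```
muscle: ECU   ath: {'pw_20_200': 0.3, 'pw_201_500': 0.2}   residual: 1.1e-13
  PW    20 µs -> threshold 24.77 mA
  PW    60 µs -> threshold 17.75 mA
  PW   100 µs -> threshold 16.19 mA
  PW   200 µs -> threshold 15.52 mA
  PW   300 µs -> threshold 10.60 mA
  PW   500 µs -> threshold 10.59 mA
```

Reading the numbers: the ECU's calibrated activation threshold is 0.30
(30% of its ROI fibers) below 200 µs and 0.20 above, which is why the
curve steps down past 200 µs; within each range the threshold amplitude
falls with pulse width and flattens toward the rheobase, the
characteristic SD-curve shape.  A Weiss fit of the 20–200 µs branch gives
b = 14.3 mA, c = 14.8 µs.  Amplitudes above the 50 mA stimulator bound
are reported as not reached.

The same pipeline is available from the shell:

```bash
fes-twin calibrate-ath          # -> {"pw_20_200": 0.2, "pw_201_500": 0.12}
fes-twin run --seed 42          # full phantom -> field -> SD-curve run
fes-twin gen-experiment --muscle FCR --seed 1   # synthetic SD measurements
```

## Layout

| Module | Contents |
| --- | --- |
| `festwin.geometry` | layered phantom, ellipse stations, electrode placement |
| `festwin.grid`, `festwin.solver` | voxelization, finite-volume potential solve |
| `festwin.nep`, `festwin.fibers` | NEP table, ROIs, fiber/diameter/node generators |
| `festwin.cable`, `festwin.af` | linear cable model, activating function + thresholds |
| `festwin.recruitment` | activation fractions, SD and intensity curves |
| `festwin.calibration` | Weiss fits, relative differences, ath selection, RSD |
| `festwin.synthetic` | synthetic experimental SD measurements |
| `festwin.fixtures` | packaged reference tables (CSV) |
| `festwin.pipeline`, `festwin.cli` | end-to-end runs, `fes-twin` command |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
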