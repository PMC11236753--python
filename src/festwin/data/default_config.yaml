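# Default run configuration: one muscle, the published electrode positions,
# the shipped standard materials, and the default simulation settings grid.
phantom:
  leh_rsp_length_mm: 242.0
  skin_thickness_mm: 1.0
solver:
  resolution_mm: 4.0
  tol: 1.0e-8
electrodes:
  muscle: ECU                  # chooses the evaluated electrode pair
  active_diameter_mm: 25.0     # round active electrode
  indifferent_edge_mm: 50.0    # square indifferent electrode
fibers:
  n_fibers: 500
  seed: 42
stimulation:
  pulse_widths_us: [20, 40, 60, 80, 100, 150, 200, 250, 300, 350, 400, 450, 500]
  ramp_in_us: 10.0
  ramp_out_us: 10.0
  amplitude_bounds_mA: [1.0, 50.0]
  mode: continuous             # or "grid" for 1 mA stimulator increments
  ath: null                    # null -> calibrated per-muscle/default table
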