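# Methods

This note documents the models implemented in `festwin`, the parameter
choices that matter, and what the shipped defaults and synthetic data do
and do not represent.

## Volume conductor

**Model.** The forearm is a stack of axial *stations*; at each station the
skin surface, the muscle–fat interface and the bone cross sections are
ellipses, and all ellipse parameters interpolate linearly between
stations.  The axial coordinate runs from the lateral epicondyle of the
humerus (LEH, z = 0) to the radial styloid process (RSP, z = L, default
L = 242 mm), with a 5% proximal extension (total 254.1 mm) so the most
proximal ROI fits.  The skin is a thin shell (1 mm default); the fat layer
is the space between the muscle ellipse and the skin shell.  Electrode
positions are given as a percentage of L (axial) and a percentage of the
skin circumference measured counterclockwise — viewed from elbow to wrist
— from a reference line along the ulna (radial).  The default phantom is a
smoothly tapered two-station elliptical cylinder with adult-forearm
dimensions; an individual anatomy can be supplied as a full station table.

**Physics.** Biological tissue at stimulation pulse time scales is treated
as purely resistive: the capacitive term of the quasi-static formulation
is dropped and `∇·(σ∇V) = 0` is solved.  Relative permittivities are
carried in the material table for future extension but unused.  Muscle is
anisotropic (σ = 1/3 S/m along the arm axis, 1/9 S/m across); skin
(1/700), fat (1/33), bone (1/50, cortical values for the whole layer) and
electrode hydrogel (1/11) are isotropic.  Because the problem is linear
and the pulse rectangular with short linear ramps, space and time
separate: one unit-current (1 mA) solve per electrode pair determines
`V_e(p, t) = V_unit(p) · I(t)` for every amplitude and instant.

**Discretization.** A 7-point finite-volume stencil on a regular voxel
grid with harmonic-mean face conductances, assembled sparse and solved by
direct factorization; the residual is checked against a configurable
tolerance (default 1e-8) and a failure raises.  Current is injected
uniformly over the outer faces of the active electrode's hydrogel voxels;
the indifferent electrode's outer faces are fixed to V = 0 (sink and
potential reference), imposed on the face — half a voxel outside the last
voxel centre — so the uniform-column solution matches the closed-form
resistor exactly.  Zero normal flux holds elsewhere (the surrounding air
is neglected).  When the voxel size exceeds the skin thickness the skin
band is dilated to one voxel (with a warning): losing the most resistive
layer would change the solution far more than thickening it.  Accuracy is
controlled by grid-refinement convergence, verified in the test suite on a
closed-form cuboid oracle.

**Polarity.** The active ("different") electrode delivers the cathodic
phase: sampled unit potentials enter the nerve models with a negative
sign relative to the +I field solve.  Cathodic stimulation depolarizes
fibers beneath the electrode (positive activating function), the
conventional configuration for motor-point stimulation.

## Fiber arrangement

Each muscle's excitable region is an elliptical cylinder (ROI) centred at
the median nerve-entry-point position from cadaver data, extended ±10 mm
axially.  Loading the shipped table applies two documented exclusions
(measurements on extended arms vs the flexed reference anatomy): the
brachioradialis is dropped and the ECRL's negative proximal bound is
clamped to zero; the two long finger flexors are split into proximal and
distal sub-ROIs, for 20 ROIs in total.

The per-muscle ROI cross sections and in-muscle positions of the
underlying individual segmentation are not published; the package ships a
**synthetic hint table** (azimuth, depth fraction, semi-axes per muscle,
clearly labelled as such in the file) that places each ROI plausibly
inside the muscle layer.  It is fully overridable via CSV.  A ROI that
protrudes from the muscle layer warns; one outside the axial range raises.

Each ROI receives 500 straight fibers (positions uniform over the ellipse,
axes parallel to the ROI orientation).  Diameters follow a two-component
truncated-normal mixture — means 5 and 11 µm, spreads 1.5 and 2.0 µm,
weights 0.55/0.45, truncated to [2, 16] µm.  Only the support and the two
mode locations are constrained by the literature; the spreads and weights
are the package's choice and are configurable.  Node-of-Ranvier spacing
maps diameter linearly, 2 µm → 155 µm and 16 µm → 1500 µm (the simplest
map consistent with the tabulated endpoints and with standard
internode-scaling data at intermediate diameters, e.g. ≈828 µm at 9 µm).
The first node sits at a uniform random offset in [0, Δx) below one ROI
face so node phases decorrelate across fibers.  Random streams are per-ROI
(seed = global seed + muscle index), so adding a muscle never perturbs the
others.

## Nerve models

**Linear cable model.** Ionic currents at each node collapse into a
time-invariant leak `I_ionic = G_m V_m` (V_m is the deviation from the
−70 mV rest), and the myelinated internode is a perfect insulator bridged
by an axial conductance.  With d_a = 0.7 d (classical axon-to-fiber
ratio; the node-diameter convention is configurable):

- G_a = π d_a² / (4 ρ_i Δx), ρ_i = 0.7 Ωm
- C_m = c_m π d_a L, c_m = 2 µF/cm², node length L = 2.5 µm
- G_m = g_m π d_a L, g_m = 30.4 mS/cm²

Terminal nodes are sealed ends (single-neighbour differences), consistent
with a finite fiber of random end offsets.  A fiber activates when any
node reaches −55 mV (15 mV depolarization) within the simulated window
(pulse + 1 ms, covering post-pulse peaks).

**Integration.** The state matrix is symmetric negative definite, so the
default integrator diagonalises it once and advances each eigenmode
*exactly* for piecewise-linear drive — unconditionally stable and free of
time-step error; the 1 µs grid only samples the trajectory.  This matters
because the stiffest membrane time constants (≈5 µs for mid-size fibers)
would make a first-order implicit scheme at 1 µs visibly inaccurate; a
backward-Euler integrator is nevertheless provided (`method=
"backward_euler"`) and cross-checked against the exact path and an
independent matrix-exponential oracle in the tests.  Linearity gives each
fiber a closed-form threshold amplitude, `(V_th − V_r) / max D_n(t)` with
D the unit-pulse depolarization; a field that depolarizes nothing (e.g. a
spatially uniform one) yields an infinite-threshold sentinel.

**Activating function.** `AF_n = (V_e,n−1 − 2V_e,n + V_e,n+1)/Δx²` at
interior nodes (endpoints excluded), in V/m²; positive values predict
depolarization.  Activation requires the peak AF to exceed a threshold
depending on diameter and pulse width.  The cited lookup values are not
reproduced in the source material, so the default table is a clearly
flagged stand-in **calibrated against the cable model**: for each (d, PW)
on an 8 × 6 grid, the cable-model threshold on a canonical point-source
field (10 mm above the fiber, 3 Ωm medium) is computed in closed form and
the peak AF at that amplitude recorded.  Queries interpolate bilinearly
and clamp at the grid edge with a warning; a user CSV overrides.

## Recruitment and calibration

Muscle activation is the fraction of ROI fibers activated; a muscle is
"on" once the fraction reaches its activation threshold *ath*.  Because
per-fiber thresholds are exact, the amplitude at which the fraction first
reaches *ath* is the ⌈ath·n⌉-th order statistic of the fiber thresholds
(ties resolve to the shared value); a grid mode rounds up to the 1 mA
stimulator increments and amplitudes beyond the 1–50 mA bounds are
recorded as not reached.

The calibration pipeline compares simulated and experimental SD curves via
the mean, over integer pulse widths in a range, of the relative amplitude
difference, and selects per muscle and per range (20–200 µs, 201–500 µs)
the *ath* with the smallest mean difference.  Comparison happens first at
the table's printed precision (3 decimals); ties are broken by the
full-precision values and remaining exact ties by the smaller *ath* — the
packaged table carries two 4-decimal cells precisely so the documented ED
tie-break reproduces from data.  Curves enter the metric through a Weiss
fit `A(PW) = b(1 + c/PW)` (the standard SD parameterization; the form is
pluggable), evaluated at 1 µs steps.

Muscles without their own calibration receive the mean of the selected
*ath* values, **rounded up** to two decimals — a threshold is rounded
conservatively, and this convention reproduces the published defaults
(0.20 and 0.12) from the packaged table's selections (raw means 0.19375
and 0.11875).  Repeat variability uses the sample (n−1) standard deviation
per pulse width divided by the mean, averaged over pulse widths — the
convention is documented because small-n repeats make it material.

## Synthetic experimental data

Raw measurement data are not deposited, so the generator emulates the
evaluation protocol: 4 repeats on the experimental pulse-width grid
(20–100 µs step 20, 150–500 µs step 50; 13 points), amplitudes
`b(1 + c/PW)(1 + ε)` with ε zero-mean Gaussian per point and repeat.
Defaults b = 4 mA, c = 250 µs are typical motor SD values; the relative
noise of 0.06 places the repeat RSD inside the reported 0.04–0.09 band.
The generator reproduces grid, repeat structure and noise level — not
electrode-repositioning bias, fatigue drift or inter-muscle correlations —
so passing tests validate the pipeline arithmetic, not measurement
realism.

## Problem sizes and numerics

Tests and the shipped examples use coarse grids (2–6 mm), tens of fibers
and short pulse-width lists; these sizes were chosen as the package's own
smoke-scale defaults and every algorithm scales to finer settings by
configuration.  Key tolerances: solver residual 1e-8; SD-fit via bounded
Levenberg–Marquardt with b > 0, c ≥ 0; histogram modes use 1 µm bins
centred on integer diameters (so the expected modes fall on the 5 and
11 µm bins rather than half-integer bin centres); eigen-decompositions are
per fiber and reused across pulse widths.

## Known limitations

- The individual MRI-derived station geometry behind the published twin is
  unavailable; only the construction rules are reproduced, so per-muscle
  absolute thresholds from the default phantom are illustrative.
- No nonlinear channel kinetics (no action-potential propagation or
  repetitive-pulse effects); the linear model is chosen for closed-form
  thresholds and optimization-loop speed.
- Straight, ROI-parallel fibers; real terminal branches fan out.
- The AF threshold table is self-calibrated against the cable model, not
  an independent experimental lookup.
- The electrode–skin interface is the hydrogel layer plus the resistive
  solve; no explicit interface impedance network is parameterized.
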