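"""End-to-end pipeline: phantom -> field -> fibers -> SD curve -> report.

Every stage is deterministic given the config and seed; rerunning a config
reproduces bit-identical CSV outputs.  Stage failures propagate wrapped
with the stage name.
"""

from __future__ import annotations

import json
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures
from .calibration import calibrate_ath
from .cable import CableParams
from .config import validate_config
from .errors import ConfigError, FestwinError
from .fibers import DiameterDistribution, place_fibers, roi_rng
from .geometry import (ElectrodeSpec, ForearmPhantom, PhantomParams,
                       build_default_phantom)
from .grid import voxelize
from .nep import build_roi, load_nep_table
from .recruitment import population_node_potentials, population_operators, sd_curve
from .solver import solve_potential


@contextmanager
def _stage(name: str):
    try:
        yield
    except FestwinError as exc:
        raise type(exc)(f"stage {name!r}: {exc}") from exc


def electrode_pair_for_muscle(muscle: str,
                              active_diameter_mm: float = 25.0,
                              indifferent_edge_mm: float = 50.0
                              ) -> tuple[ElectrodeSpec, ElectrodeSpec]:
    """The evaluated electrode pair (active + indifferent) for one muscle."""
    pos = fixtures.load_electrode_positions()
    row = pos[pos["roi"] == muscle]
    if len(row) == 0:
        raise ConfigError(
            f"no shipped electrode position for muscle {muscle!r}; "
            f"available: {sorted(pos['roi'])}")
    r = row.iloc[0]
    active = ElectrodeSpec.round_active(float(r["diff_axial_pct"]),
                                        float(r["diff_radial_pct"]),
                                        active_diameter_mm)
    indiff = ElectrodeSpec.square_indifferent(float(r["indiff_axial_pct"]),
                                              float(r["indiff_radial_pct"]),
                                              indifferent_edge_mm)
    return active, indiff


def export_phantom_stl(phantom: ForearmPhantom, path,
                       n_rings: int = 24, n_theta: int = 64) -> None:
    """Export the outer (skin) surface as a closed STL mesh."""
    import trimesh

    zs = np.linspace(phantom.z_min, phantom.z_max, n_rings)
    ts = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    verts, rings = [], []
    for z in zs:
        outer = phantom.station_at(z).outer
        ring = outer.point(ts)
        rings.append(len(verts))
        verts.extend([[p[0], p[1], z] for p in ring])
    faces = []
    for r in range(n_rings - 1):
        a, b = rings[r], rings[r + 1]
        for i in range(n_theta):
            j = (i + 1) % n_theta
            faces.append([a + i, a + j, b + i])
            faces.append([a + j, b + j, b + i])
    # end caps
    for r, flip in ((0, True), (n_rings - 1, False)):
        center = len(verts)
        ring = rings[r]
        verts.append([*np.mean(np.asarray(verts)[ring:ring + n_theta, :2], axis=0),
                      zs[r]])
        for i in range(n_theta):
            j = (i + 1) % n_theta
            tri = [ring + i, ring + j, center]
            faces.append(tri[::-1] if flip else tri)
    trimesh.Trimesh(vertices=verts, faces=faces, process=True).export(path)


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full simulation pipeline for one muscle.

    Returns the report dict (also written as ``report.json``); writes the
    SD curve and fiber node table as CSV and the unit-current field as NPZ.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    muscle = config["electrodes"]["muscle"]
    global_seed = int(seed if seed is not None else config["fibers"]["seed"])

    with _stage("phantom"):
        params = PhantomParams(
            leh_rsp_length_mm=float(config["phantom"]["leh_rsp_length_mm"]),
            skin_thickness_mm=float(config["phantom"]["skin_thickness_mm"]))
        phantom = build_default_phantom(params)

    with _stage("electrodes"):
        active, indiff = electrode_pair_for_muscle(
            muscle,
            float(config["electrodes"].get("active_diameter_mm", 25.0)),
            float(config["electrodes"].get("indifferent_edge_mm", 50.0)))

    with _stage("field"):
        resolution = float(config["solver"]["resolution_mm"])
        grid = voxelize(phantom, [active, indiff], resolution)
        field = solve_potential(grid, 1.0,
                                tol=float(config["solver"].get("tol", 1e-8)))
        np.savez_compressed(out / "field.npz", v_per_mA=field.v_per_mA,
                            origin=grid.origin, resolution=grid.resolution)

    with _stage("fibers"):
        records = load_nep_table()
        idx, record = next((i, r) for i, r in enumerate(records)
                           if r.muscle == muscle)
        roi = build_roi(record, phantom)
        population = place_fibers(roi, int(config["fibers"]["n_fibers"]),
                                  DiameterDistribution(),
                                  roi_rng(global_seed, idx))
        population.to_dataframe().to_csv(out / "fiber_nodes.csv", index=False)

    with _stage("recruitment"):
        cable = CableParams.from_fixture()
        ve = population_node_potentials(population, field)
        operators = population_operators(population, ve, cable)
        stim = config["stimulation"]
        ath_cfg = stim.get("ath")
        if ath_cfg is None:
            ath_table = calibrate_ath().ath_table
            ath_lo = ath_table.lookup(muscle, 100.0)
            ath_hi = ath_table.lookup(muscle, 300.0)
        else:
            ath_lo = ath_hi = float(ath_cfg)
        pws = np.asarray(stim["pulse_widths_us"], dtype=float)
        bounds = tuple(stim.get("amplitude_bounds_mA", (1.0, 50.0)))
        mode = stim.get("mode", "continuous")
        # the two-range activation-threshold logic: ath_lo up to 200 µs,
        # ath_hi above
        frames, thr_all = [], np.empty_like(pws)
        for ath, mask in ((ath_lo, pws <= 200.0), (ath_hi, pws > 200.0)):
            if not np.any(mask):
                continue
            part = sd_curve(population, field, pws[mask], ath, cable, bounds,
                            mode=mode, operators=operators)
            thr_all[mask] = part.threshold_mA
            frames.append(part.to_dataframe())
        curve_df = pd.concat(frames, ignore_index=True).sort_values("pw_us")
        curve_df.to_csv(out / "sd_curve.csv", index=False)

    report = {
        "muscle": muscle,
        "seed": global_seed,
        "grid_resolution_mm": resolution,
        "grid_shape": list(grid.shape),
        "solver_residual": field.residual,
        "n_fibers": len(population),
        "ath": {"pw_20_200": ath_lo, "pw_201_500": ath_hi},
        "pulse_widths_us": [float(p) for p in pws],
        "threshold_mA": [None if not np.isfinite(v) else float(v)
                         for v in thr_all],
        "runtime_s": round(time.perf_counter() - t_start, 3),
        "outputs": ["field.npz", "fiber_nodes.csv", "sd_curve.csv",
                    "report.json"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
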