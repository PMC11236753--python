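"""Packaged reference tables.

The package ships, as plain CSV, the printed tables a user needs to rebuild
the published study conditions: standard material properties, the
nerve-entry-point (NEP) table that anchors the muscle ROIs, the cable-model
constants, the stimulation settings grids, the evaluated electrode
positions, and the relative-difference table from which the muscle-specific
activation thresholds are selected.  Conductivities are stored as the exact
fraction strings (``1/700``) and parsed with :class:`fractions.Fraction` so
no decimal truncation sneaks in.

The ROI placement hints are *synthetic defaults* (the underlying individual
segmentation is not published); they are clearly marked as such in the file
and overridable via CSV.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from importlib import resources

import pandas as pd

from .materials import MaterialSpec

_DATA = resources.files("festwin") / "data"


def _path(name: str):
    return _DATA / name


def _read_csv(name: str, **kw) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p, **kw)


def parse_fraction(text: str) -> float:
    """Parse ``"1/700"`` or ``"0.7"`` to a float."""
    return float(Fraction(str(text)))


@lru_cache(maxsize=None)
def load_materials() -> dict[str, MaterialSpec]:
    """Standard material table: conductivity and relative permittivity."""
    df = _read_csv("materials.csv", dtype=str)
    out: dict[str, MaterialSpec] = {}
    for row in df.itertuples(index=False):
        out[row.name] = MaterialSpec(
            name=row.name,
            sigma_axial=parse_fraction(row.sigma_axial_S_per_m),
            sigma_radial=parse_fraction(row.sigma_radial_S_per_m),
            epsilon_r=float(row.epsilon_r_axial),
        )
    return out


def load_nep_table_raw() -> pd.DataFrame:
    """The full NEP table as shipped (21 rows, BR included, bounds as printed).

    ``relative_bounds == 1`` marks the finger-flexor sub-ROIs whose
    proximal/distal bounds are offsets (in % points) from the median rather
    than absolute positions.
    """
    return _read_csv("nep_table.csv")


@lru_cache(maxsize=None)
def load_cable_constants() -> dict[str, float]:
    """Cable-model constants keyed by parameter name (units in the CSV)."""
    df = _read_csv("cable_params.csv")
    return dict(zip(df["parameter"], df["value"].astype(float)))


@lru_cache(maxsize=None)
def load_settings_grid() -> dict[str, dict[str, str]]:
    """Stimulation-settings grids for simulation and experiment modes."""
    df = _read_csv("settings_grid.csv", dtype=str)
    out: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.mode, {})[row.key] = row.value
    return out


def experiment_pw_grid() -> list[float]:
    """Pulse-width grid used in the evaluation experiments (13 values, µs)."""
    raw = load_settings_grid()["experiment"]["pw_grid_us"]
    return [float(v) for v in raw.split(";")]


def load_electrode_positions() -> pd.DataFrame:
    """Evaluated per-muscle electrode positions (axial/radial %)."""
    return _read_csv("electrode_positions.csv")


def load_rel_diff_table() -> pd.DataFrame:
    """Mean relative differences between simulated and experimental SD curves.

    Tidy layout: ``muscle``, ``pw_range`` (``"20-200"`` / ``"201-500"``),
    ``ath`` (candidate activation threshold) and ``mean_rel_diff``.  Two
    cells carry a fourth decimal so the documented tie-break between ath
    0.15 and 0.20 for the ED muscle is reproducible from data.
    """
    df = _read_csv("rel_diff_table.csv")
    df["ath"] = df["ath"].round(2)
    return df


def load_roi_hints() -> pd.DataFrame:
    """Synthetic default ROI orientation/size hints (see file header)."""
    return _read_csv("roi_hints.csv", comment="#")
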