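"""Muscle-specific regions of interest anchored at nerve entry points.

Each forearm muscle is excited where its terminal nerve branch enters the
muscle (the nerve entry point, NEP).  Cadaver studies report, per muscle,
the proximal maximum, median and distal maximum NEP position as a
percentage of the LEH-RSP distance.  The median position anchors an
elliptical-cylinder region of interest (ROI) that extends 10 mm proximally
and distally and approximates the innervation zone; the ROI cross-section
ellipse and orientation come from a per-muscle hint table because the
underlying individual segmentation is not published.

Two exclusion rules apply when loading the shipped table: the
brachioradialis (BR) is dropped entirely and the negative proximal bound of
the ECRL is clamped to zero, both because those positions were measured on
extended arms while the reference anatomy is flexed.  The two long finger
flexors get two sub-ROIs each (their NEPs spread over more than half the
forearm), leaving 20 muscle-specific ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fixtures
from .errors import GeometryError
from .geometry import MUSCLE, ForearmPhantom


@dataclass(frozen=True)
class NEPRecord:
    """Nerve-entry-point summary for one muscle (percent of LEH-RSP length)."""

    muscle: str
    group: str
    proximal_max_pct: float
    median_pct: float
    distal_max_pct: float

    def __post_init__(self) -> None:
        if not (self.proximal_max_pct <= self.median_pct <= self.distal_max_pct):
            raise ValueError(
                f"{self.muscle}: NEP bounds must be ordered "
                f"(prox <= median <= distal)")


@dataclass
class ROISpec:
    """Elliptical-cylinder fiber region for one muscle.

    ``center_mm`` is the 3D centre, ``axis`` the unit orientation vector,
    ``semi_axes_mm`` the cross-section ellipse, ``length_mm`` the axial
    extent (default 20 mm, i.e. +-10 mm about the NEP median).
    """

    muscle: str
    center_mm: np.ndarray
    axis: np.ndarray
    semi_axes_mm: tuple[float, float]
    length_mm: float = 20.0
    cross_roll: float = 0.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise GeometryError(f"{self.muscle}: ROI length must be > 0")
        if min(self.semi_axes_mm) <= 0:
            raise GeometryError(f"{self.muscle}: ROI semi-axes must be > 0")
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise GeometryError(f"{self.muscle}: ROI axis must be non-zero")
        self.axis = axis / n

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane basis (u, v) of the cross-section."""
        w = self.axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(w @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(w, helper)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        c, s = np.cos(self.cross_roll), np.sin(self.cross_roll)
        return c * u + s * v, -s * u + c * v


def load_nep_table(source: str | pd.DataFrame | None = None) -> list[NEPRecord]:
    """Load NEP records, applying the documented exclusion rules.

    ``source`` may be a CSV path or DataFrame with the fixture columns; by
    default the shipped table is used.  Returns 20 records: BR is dropped,
    the ECRL proximal bound is clamped to 0, and the relative (+-) bounds of
    the finger-flexor sub-ROIs are resolved about their medians.
    """
    if source is None:
        df = fixtures.load_nep_table_raw()
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    required = {"code", "proximal_max_pct", "median_pct", "distal_max_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"NEP table missing columns: {sorted(missing)}")
    known = set(fixtures.load_nep_table_raw()["code"])
    unknown = set(df["code"]) - known
    if unknown:
        raise ValueError(f"unknown muscle code(s): {sorted(unknown)}")

    records = []
    for row in df.itertuples(index=False):
        code = row.code
        if code == "BR":
            continue  # excluded: measured on extended arms
        prox, med, dist = (float(row.proximal_max_pct), float(row.median_pct),
                           float(row.distal_max_pct))
        if getattr(row, "relative_bounds", 0):
            prox, dist = med + prox, med + dist
        if code == "ECRL":
            prox = max(prox, 0.0)
        records.append(NEPRecord(code, getattr(row, "muscle_group", ""),
                                 prox, med, dist))
    return records


def build_roi(record: NEPRecord, phantom: ForearmPhantom,
              hints: pd.DataFrame | None = None,
              length_mm: float = 20.0) -> ROISpec:
    """Place the ROI of one muscle inside the phantom.

    The NEP median sets the axial centre; orientation, in-muscle position
    and cross-section come from the hint table (default: the shipped
    synthetic hints; with no hint row the ROI is centred in the muscle
    layer and aligned with the phantom long axis).  A ROI that protrudes
    from the muscle layer triggers a warning, one outside the phantom's
    axial range an error.
    """
    z = record.median_pct / 100.0 * phantom.leh_rsp_length
    half = length_mm / 2.0
    if z - half < phantom.z_min or z + half > phantom.z_max:
        raise GeometryError(
            f"{record.muscle}: ROI at z={z:g} mm (+-{half:g}) outside phantom "
            f"axial range [{phantom.z_min:g}, {phantom.z_max:g}] mm")

    hints = fixtures.load_roi_hints() if hints is None else hints
    row = hints[hints["code"] == record.muscle]
    station = phantom.station_at(z)
    if len(row) == 0:
        center2d = np.asarray(station.muscle.center)
        semi_axes = (6.0, 4.0)
    else:
        r = row.iloc[0]
        az = np.deg2rad(float(r["azimuth_deg"])) + phantom.reference_azimuth
        boundary = station.muscle.point(station.muscle.param_for_azimuth(az))
        c = np.asarray(station.muscle.center)
        center2d = c + float(r["depth_frac"]) * (boundary - c)
        semi_axes = (float(r["semi_a_mm"]), float(r["semi_b_mm"]))

    roi = ROISpec(record.muscle,
                  np.array([center2d[0], center2d[1], z]),
                  np.array([0.0, 0.0, 1.0]),
                  semi_axes, length_mm)
    _warn_if_outside_muscle(roi, phantom)
    return roi


def _warn_if_outside_muscle(roi: ROISpec, phantom: ForearmPhantom) -> None:
    u, v = roi.frame()
    ts = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    ring = (roi.semi_axes_mm[0] * np.cos(ts)[:, None] * u +
            roi.semi_axes_mm[1] * np.sin(ts)[:, None] * v)
    pts = []
    for frac in (-0.5, 0.0, 0.5):
        pts.append(roi.center_mm + frac * roi.length_mm * roi.axis + ring)
    pts = np.concatenate(pts)
    mats = phantom.material_at(pts)
    if np.any(mats != MUSCLE):
        warnings.warn(
            f"ROI {roi.muscle}: {int(np.sum(mats != MUSCLE))}/{len(pts)} boundary "
            f"sample points fall outside the muscle layer", stacklevel=3)
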