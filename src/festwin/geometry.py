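"""Parametric layered forearm phantom and skin-electrode placement.

The phantom is a stack of axial *stations*; at each station the skin
surface, the muscle-fat interface and the bone cross sections are ellipses.
Between stations every ellipse parameter is interpolated linearly, which
yields a smoothly tapered volume whose layers stay mathematically defined
(the point of approximating the anatomy with regular geometries).  The
axial coordinate runs from the lateral epicondyle of the humerus (LEH,
z = 0) to the radial styloid process (RSP, z = leh_rsp_length); a proximal
extension at negative z covers the most proximal ROI and brings the total
model length to 1.05 x the LEH-RSP distance.

Electrode positions follow the axial/radial convention: the axial value is
a percentage of the LEH-RSP length, the radial value a percentage of the
skin circumference at that height, measured counterclockwise (viewed from
elbow to wrist) from a fixed reference line along the ulna.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .materials import MaterialSpec

# material codes used on the voxel grid
AIR = 0
SKIN = 1
FAT = 2
MUSCLE = 3
BONE = 4
HYDROGEL = 5

MATERIAL_NAMES = {AIR: "air", SKIN: "skin", FAT: "fat", MUSCLE: "muscle",
                  BONE: "bone", HYDROGEL: "hydrogel"}


@dataclass
class Ellipse:
    """Planar ellipse: centre (mm), semi-axes a,b (mm), roll (rad)."""

    center: tuple[float, float]
    a: float
    b: float
    roll: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise GeometryError(f"ellipse semi-axes must be > 0, got ({self.a}, {self.b})")

    # -- geometry ---------------------------------------------------------
    def _to_local(self, pts: np.ndarray) -> np.ndarray:
        d = np.asarray(pts, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.roll), np.sin(self.roll)
        return np.stack([d[..., 0] * c + d[..., 1] * s,
                         -d[..., 0] * s + d[..., 1] * c], axis=-1)

    def norm_radius(self, pts: np.ndarray) -> np.ndarray:
        """sqrt((x/a)^2 + (y/b)^2) in the ellipse frame; 1 on the boundary."""
        loc = self._to_local(pts)
        return np.hypot(loc[..., 0] / self.a, loc[..., 1] / self.b)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.norm_radius(pts) <= 1.0

    def shrunk(self, offset: float) -> "Ellipse":
        """Inward parallel offset, approximated by reducing both semi-axes."""
        if offset >= min(self.a, self.b):
            raise GeometryError(f"offset {offset} mm swallows ellipse ({self.a}, {self.b})")
        return Ellipse(self.center, self.a - offset, self.b - offset, self.roll)

    def grown(self, offset: float) -> "Ellipse":
        return Ellipse(self.center, self.a + offset, self.b + offset, self.roll)

    def point(self, t) -> np.ndarray:
        """Boundary point(s) at parameter t (rad)."""
        t = np.asarray(t, dtype=float)
        c, s = np.cos(self.roll), np.sin(self.roll)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.stack([self.center[0] + x * c - y * s,
                         self.center[1] + x * s + y * c], axis=-1)

    def param_for_azimuth(self, azimuth) -> np.ndarray:
        """Parameter t whose boundary point lies in world direction `azimuth`."""
        psi = np.asarray(azimuth, dtype=float) - self.roll
        return np.arctan2(self.a * np.sin(psi), self.b * np.cos(psi))

    def azimuth_of(self, pts: np.ndarray) -> np.ndarray:
        """World direction angle of points about the ellipse centre."""
        d = np.asarray(pts, dtype=float) - np.asarray(self.center)
        return np.arctan2(d[..., 1], d[..., 0])

    def circumference(self, n: int = 720) -> float:
        t = np.linspace(0, 2 * np.pi, n + 1)
        p = self.point(t)
        return float(np.sum(np.hypot(*np.diff(p, axis=0).T)))

    def arc_table(self, start_azimuth: float, n: int = 1440):
        """Cumulative arc length vs parameter offset from ``start_azimuth``.

        Returns (u, s): parameter offsets in [0, 2*pi] measured CCW from the
        starting parameter, and the matching cumulative arc lengths (mm).
        """
        t0 = float(self.param_for_azimuth(start_azimuth))
        u = np.linspace(0, 2 * np.pi, n + 1)
        p = self.point(t0 + u)
        seg = np.hypot(*np.diff(p, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return u, s, t0


def _interp_ellipse(e0: Ellipse, e1: Ellipse, w: float) -> Ellipse:
    c = (1 - w) * np.asarray(e0.center) + w * np.asarray(e1.center)
    # interpolate roll along the shorter arc
    droll = (e1.roll - e0.roll + np.pi) % (2 * np.pi) - np.pi
    return Ellipse((float(c[0]), float(c[1])),
                   (1 - w) * e0.a + w * e1.a,
                   (1 - w) * e0.b + w * e1.b,
                   e0.roll + w * droll)


@dataclass
class Station:
    """Layer cross sections at one axial position."""

    z: float
    outer: Ellipse          # skin surface
    muscle: Ellipse         # muscle-fat interface
    bones: tuple[Ellipse, ...]


@dataclass
class ForearmPhantom:
    """Layered forearm volume: bone c muscle c fat c skin.

    ``reference_azimuth`` anchors the radial electrode coordinate: it is the
    world-frame direction (rad) of the reference line on the skin surface.
    """

    stations: list[Station]
    leh_rsp_length: float
    skin_thickness: float = 1.0
    reference_azimuth: float = 0.0
    axial_range: tuple[float, float] | None = None  # needed for 1-station prisms

    def __post_init__(self) -> None:
        if self.skin_thickness <= 0:
            raise GeometryError("skin_thickness must be > 0")
        if not self.stations:
            raise GeometryError("phantom needs at least one station")
        self.stations = sorted(self.stations, key=lambda st: st.z)
        nb = {len(st.bones) for st in self.stations}
        if len(nb) > 1:
            raise GeometryError("all stations must list the same number of bone ellipses")
        self._validate_nesting()

    # -- extent -----------------------------------------------------------
    @property
    def z_min(self) -> float:
        return self.axial_range[0] if self.axial_range else self.stations[0].z

    @property
    def z_max(self) -> float:
        return self.axial_range[1] if self.axial_range else self.stations[-1].z

    @property
    def total_length(self) -> float:
        return self.z_max - self.z_min

    def _validate_nesting(self) -> None:
        ts = np.linspace(0, 2 * np.pi, 64)
        for i, st in enumerate(self.stations):
            inner_skin = st.outer.shrunk(self.skin_thickness)
            if not np.all(inner_skin.contains(st.muscle.point(ts))):
                raise GeometryError(
                    f"station {i} (z={st.z:g} mm): muscle ellipse not nested "
                    f"inside the fat/skin boundary")
            for j, bone in enumerate(st.bones):
                if not np.all(st.muscle.contains(bone.point(ts))):
                    raise GeometryError(
                        f"station {i} (z={st.z:g} mm): bone ellipse {j} not "
                        f"nested inside the muscle ellipse")

    # -- interpolation ----------------------------------------------------
    def station_at(self, z: float) -> Station:
        """Layer ellipses at axial position z (linear interpolation, clamped)."""
        sts = self.stations
        if len(sts) == 1:
            return sts[0]
        zs = [st.z for st in sts]
        if z <= zs[0]:
            return sts[0]
        if z >= zs[-1]:
            return sts[-1]
        i = int(np.searchsorted(zs, z)) - 1
        s0, s1 = sts[i], sts[i + 1]
        w = (z - s0.z) / (s1.z - s0.z)
        return Station(
            z,
            _interp_ellipse(s0.outer, s1.outer, w),
            _interp_ellipse(s0.muscle, s1.muscle, w),
            tuple(_interp_ellipse(b0, b1, w) for b0, b1 in zip(s0.bones, s1.bones)),
        )

    # -- material queries -------------------------------------------------
    def materials_in_slice(self, xy: np.ndarray, z: float,
                           skin_thickness: float | None = None) -> np.ndarray:
        """Material code for each 2D point of one axial slice."""
        st = self.station_at(z)
        thick = self.skin_thickness if skin_thickness is None else skin_thickness
        xy = np.asarray(xy, dtype=float)
        out = np.full(xy.shape[:-1], AIR, dtype=np.int8)
        in_outer = st.outer.contains(xy)
        out[in_outer] = SKIN
        in_fat = st.outer.shrunk(thick).contains(xy)
        out[in_fat] = FAT
        in_muscle = st.muscle.contains(xy)
        out[in_muscle] = MUSCLE
        for bone in st.bones:
            out[bone.contains(xy)] = BONE
        return out

    def material_at(self, points: np.ndarray) -> np.ndarray:
        """Material code for 3D points (mm). Points outside the axial range are air."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(points), AIR, dtype=np.int8)
        inside = (points[:, 2] >= self.z_min) & (points[:, 2] <= self.z_max)
        for z in np.unique(points[inside, 2]):
            sel = inside & (points[:, 2] == z)
            out[sel] = self.materials_in_slice(points[sel, :2], z)
        return out

    # -- surface coordinates ----------------------------------------------
    def circumference(self, z: float) -> float:
        return self.station_at(z).outer.circumference()

    def surface_point(self, z: float, s_mm: float) -> np.ndarray:
        """3D point on the skin surface at arc length s from the reference line."""
        outer = self.station_at(z).outer
        u, cum, t0 = outer.arc_table(self.reference_azimuth)
        s_mm = float(s_mm) % cum[-1]
        ui = np.interp(s_mm, cum, u)
        p = outer.point(t0 + ui)
        return np.array([p[0], p[1], z])

    def arc_coordinate(self, xy: np.ndarray, z: float) -> np.ndarray:
        """Arc length (mm, CCW from the reference line) of 2D points at height z."""
        outer = self.station_at(z).outer
        u, cum, t0 = outer.arc_table(self.reference_azimuth)
        t = outer.param_for_azimuth(outer.azimuth_of(xy))
        ui = (np.asarray(t) - t0) % (2 * np.pi)
        return np.interp(ui, u, cum)


# ---------------------------------------------------------------------------
# default phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomParams:
    """Parameters of the default smoothly tapered phantom.

    The individual per-slice geometry behind the published model is not
    available, so the default is a two-station taper with realistic adult
    forearm dimensions; a full custom station table can be passed to
    :class:`ForearmPhantom` directly to mimic an individual.
    """

    leh_rsp_length_mm: float = 242.0
    extension_frac: float = 0.05        # proximal extension, fraction of LEH-RSP
    skin_thickness_mm: float = 1.0
    outer_proximal: tuple[float, float] = (45.0, 38.0)
    outer_distal: tuple[float, float] = (28.0, 22.0)
    fat_thickness_proximal: float = 4.0
    fat_thickness_distal: float = 3.0
    bone_centers_proximal: tuple[tuple[float, float], ...] = ((11.0, 0.0), (-11.0, 0.0))
    bone_semi_axes_proximal: tuple[tuple[float, float], ...] = ((7.0, 6.0), (7.0, 6.0))
    bone_centers_distal: tuple[tuple[float, float], ...] = ((8.0, 0.0), (-8.0, 0.0))
    bone_semi_axes_distal: tuple[tuple[float, float], ...] = ((5.5, 4.5), (5.5, 4.5))
    reference_azimuth_rad: float = -np.pi / 2


def build_default_phantom(params: PhantomParams | None = None) -> ForearmPhantom:
    """Build the default tapered elliptical-cylinder phantom.

    The LEH-RSP segment spans z in [0, L]; the proximal extension continues
    to z = -extension_frac * L, so the total length is 1.05 L for the
    default 5% extension (254.1 mm for L = 242 mm).
    """
    p = params or PhantomParams()
    L = p.leh_rsp_length_mm
    skin = p.skin_thickness_mm

    def station(z, outer_ab, fat_t, bone_centers, bone_ab):
        outer = Ellipse((0.0, 0.0), *outer_ab)
        muscle = outer.shrunk(skin + fat_t)
        bones = tuple(Ellipse(c, a, b) for c, (a, b) in zip(bone_centers, bone_ab))
        return Station(z, outer, muscle, bones)

    stations = [
        station(-p.extension_frac * L, p.outer_proximal, p.fat_thickness_proximal,
                p.bone_centers_proximal, p.bone_semi_axes_proximal),
        station(L, p.outer_distal, p.fat_thickness_distal,
                p.bone_centers_distal, p.bone_semi_axes_distal),
    ]
    return ForearmPhantom(stations, leh_rsp_length=L, skin_thickness=skin,
                          reference_azimuth=p.reference_azimuth_rad)


# ---------------------------------------------------------------------------
# electrodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeSpec:
    """Skin electrode described in the axial/radial surface convention.

    ``dimensions_mm`` is ``(diameter,)`` for circles and
    ``(width_circumferential, height_axial)`` for rectangles.
    """

    role: str                      # "different" (active) | "indifferent"
    shape: str                     # "circle" | "rectangle"
    dimensions_mm: tuple[float, ...]
    axial_pct: float
    radial_pct: float
    hydrogel_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("different", "indifferent"):
            raise GeometryError(f"unknown electrode role {self.role!r}")
        if self.shape not in ("circle", "rectangle"):
            raise GeometryError(f"unknown electrode shape {self.shape!r}")
        if not 0 <= self.axial_pct <= 105:
            raise GeometryError("axial_pct must be within [0, 105]")
        if not 0 <= self.radial_pct < 100:
            raise GeometryError("radial_pct must be within [0, 100)")
        if any(d <= 0 for d in self.dimensions_mm):
            raise GeometryError("electrode footprint area must be > 0")
        n = 1 if self.shape == "circle" else 2
        if len(self.dimensions_mm) != n:
            raise GeometryError(
                f"{self.shape} electrode needs {n} dimension(s), got {self.dimensions_mm}")

    @classmethod
    def round_active(cls, axial_pct: float, radial_pct: float,
                     diameter_mm: float = 25.0) -> "ElectrodeSpec":
        """Default active electrode: 25 mm diameter circle."""
        return cls("different", "circle", (diameter_mm,), axial_pct, radial_pct)

    @classmethod
    def square_indifferent(cls, axial_pct: float, radial_pct: float,
                           edge_mm: float = 50.0) -> "ElectrodeSpec":
        """Default indifferent electrode: 50 mm square."""
        return cls("indifferent", "rectangle", (edge_mm, edge_mm), axial_pct, radial_pct)


@dataclass
class ElectrodeFootprint:
    """Resolved surface footprint of one electrode on a specific phantom."""

    spec: ElectrodeSpec
    z_center: float
    s_center: float
    circumference: float
    center_point: np.ndarray        # 3D point on the skin surface

    def contains_surface(self, z_mm: np.ndarray, s_mm: np.ndarray,
                         circumference: np.ndarray | float | None = None) -> np.ndarray:
        """Whether surface coordinates (z, s) fall under the electrode pad."""
        circ = self.circumference if circumference is None else circumference
        dz = np.asarray(z_mm, dtype=float) - self.z_center
        ds = np.asarray(s_mm, dtype=float) - self.s_center
        ds = (ds + circ / 2.0) % circ - circ / 2.0
        if self.spec.shape == "circle":
            r = self.spec.dimensions_mm[0] / 2.0
            return dz ** 2 + ds ** 2 <= r ** 2
        w, h = self.spec.dimensions_mm
        return (np.abs(ds) <= w / 2.0) & (np.abs(dz) <= h / 2.0)


def place_electrode(phantom: ForearmPhantom, spec: ElectrodeSpec) -> ElectrodeFootprint:
    """Resolve an electrode spec to its footprint on the phantom surface.

    The footprint centre lies at arc length ``radial_pct%`` of the skin
    circumference, counterclockwise (viewed elbow to wrist) from the
    reference line, at axial position ``axial_pct%`` of the LEH-RSP length.
    """
    z = spec.axial_pct / 100.0 * phantom.leh_rsp_length
    if not (phantom.z_min - 1e-9 <= z <= phantom.z_max + 1e-9):
        raise GeometryError(
            f"electrode axial position {z:g} mm outside phantom [{phantom.z_min:g}, "
            f"{phantom.z_max:g}] mm")
    circ = phantom.circumference(z)
    width = spec.dimensions_mm[0]
    if width > 0.5 * circ:
        raise GeometryError(
            f"electrode width {width:g} mm wraps more than half the {circ:.1f} mm "
            f"circumference (electrode larger than arm)")
    s = spec.radial_pct / 100.0 * circ
    return ElectrodeFootprint(spec, z, s, circ, phantom.surface_point(z, s))
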