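"""Voxelization of the phantom into a structured conductor grid.

The grid replaces unstructured FEM meshing with a regular voxel lattice:
each voxel carries a material id and a diagonal conductivity tensor whose
axial component is aligned with the phantom long axis (relevant only for
muscle, the one anisotropic tissue).  Electrode hydrogel pads become voxel
bands just outside the skin surface; the outermost hydrogel voxels form the
"electrode face" through which current is injected or drained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import (AIR, BONE, FAT, HYDROGEL, MUSCLE, SKIN,
                       ElectrodeSpec, ForearmPhantom, place_electrode)
from .materials import MaterialSpec, default_materials

_NEIGHBOR_STEPS = [(0, (1, 0, 0)), (0, (-1, 0, 0)),
                   (1, (0, 1, 0)), (1, (0, -1, 0)),
                   (2, (0, 0, 1)), (2, (0, 0, -1))]


@dataclass
class FaceSet:
    """Outer boundary faces of one electrode: voxel indices + outward axis/sign."""

    idx: np.ndarray      # (n, 3) int voxel indices
    axis: np.ndarray     # (n,) int in {0,1,2}
    sign: np.ndarray     # (n,) int in {-1, +1}

    def __len__(self) -> int:
        return len(self.idx)


@dataclass
class ConductorGrid:
    """Structured voxel grid ready for the finite-volume solve.

    ``sigma`` holds the per-voxel diagonal conductivity tensor in S/m with
    component order (x, y, z); air voxels have zero conductivity and are
    excluded from the solve.
    """

    origin: np.ndarray              # centre of voxel (0,0,0), mm
    resolution: float               # voxel edge, mm
    material: np.ndarray            # (nx,ny,nz) int8 material codes
    sigma: np.ndarray               # (nx,ny,nz,3) S/m
    face_sets: dict[int, FaceSet] = field(default_factory=dict)
    electrode_roles: dict[int, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material.shape

    @property
    def conducting(self) -> np.ndarray:
        return self.material != AIR

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        return tuple(self.origin[k] + self.resolution * np.arange(n)
                     for k, n in enumerate((nx, ny, nz)))

    def voxel_centers(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + self.resolution * np.asarray(idx, dtype=float)


_SIGMA_KEYS = {SKIN: "skin", FAT: "fat", MUSCLE: "muscle", BONE: "bone",
               HYDROGEL: "hydrogel"}


def _sigma_lookup(materials: dict[str, MaterialSpec]) -> dict[int, tuple[float, float, float]]:
    out = {AIR: (0.0, 0.0, 0.0)}
    for code, name in _SIGMA_KEYS.items():
        m = materials[name]
        # axial component along z (phantom long axis); radial in the plane
        out[code] = (m.sigma_radial, m.sigma_radial, m.sigma_axial)
    return out


def voxelize(phantom: ForearmPhantom,
             electrodes: list[ElectrodeSpec],
             resolution: float,
             materials: dict[str, MaterialSpec] | None = None) -> ConductorGrid:
    """Voxelize the phantom and its electrodes at the given resolution (mm).

    Material assignment uses point-in-ellipse tests on the station ellipses
    interpolated to each voxel-centre height.  When the resolution is
    coarser than the skin thickness, the skin band is dilated to the voxel
    size (with a warning) so the highly resistive skin layer is never lost.
    """
    if resolution <= 0:
        raise GeometryError("resolution must be > 0")
    materials = materials or default_materials()
    eff_skin = phantom.skin_thickness
    if resolution > phantom.skin_thickness:
        eff_skin = resolution
        warnings.warn(
            f"resolution {resolution:g} mm coarser than skin thickness "
            f"{phantom.skin_thickness:g} mm; dilating skin to one voxel",
            stacklevel=2)

    footprints = [place_electrode(phantom, spec) for spec in electrodes]
    hydro_bands = [max(spec.hydrogel_thickness_mm, resolution) for spec in electrodes]
    margin = (max(hydro_bands) if hydro_bands else 0.0) + resolution

    half_extent = max(max(st.outer.a, st.outer.b) +
                      max(abs(st.outer.center[0]), abs(st.outer.center[1]))
                      for st in phantom.stations) + margin
    x = np.arange(-half_extent, half_extent + resolution, resolution)
    y = np.arange(-half_extent, half_extent + resolution, resolution)
    z = np.arange(phantom.z_min + resolution / 2.0,
                  phantom.z_max - resolution / 2.0 + 1e-9, resolution)
    if len(z) == 0:
        z = np.array([(phantom.z_min + phantom.z_max) / 2.0])
    origin = np.array([x[0], y[0], z[0]])

    XX, YY = np.meshgrid(x, y, indexing="ij")
    xy = np.stack([XX, YY], axis=-1)

    material = np.full((len(x), len(y), len(z)), AIR, dtype=np.int8)
    elec_id = np.full(material.shape, -1, dtype=np.int8)

    for iz, zz in enumerate(z):
        material[:, :, iz] = phantom.materials_in_slice(xy, zz, eff_skin)
        st_outer = phantom.station_at(zz).outer
        nr = st_outer.norm_radius(xy)
        for ei, (fp, band) in enumerate(zip(footprints, hydro_bands)):
            if abs(zz - fp.z_center) > max(fp.spec.dimensions_mm) / 2.0 + resolution:
                continue
            shell = (nr > 1.0) & st_outer.grown(band).contains(xy)
            shell &= material[:, :, iz] == AIR
            if not np.any(shell):
                continue
            s = phantom.arc_coordinate(xy[shell], zz)
            circ = st_outer.circumference()
            hit = fp.contains_surface(np.full(s.shape, zz), s, circ)
            ii, jj = np.nonzero(shell)
            material[ii[hit], jj[hit], iz] = HYDROGEL
            elec_id[ii[hit], jj[hit], iz] = ei

    sigma_map = _sigma_lookup(materials)
    sigma = np.zeros(material.shape + (3,), dtype=float)
    for code, s3 in sigma_map.items():
        sigma[material == code] = s3

    face_sets = _electrode_faces(phantom, material, elec_id, origin, resolution,
                                 len(electrodes))
    roles = {i: spec.role for i, spec in enumerate(electrodes)}
    for i, spec in enumerate(electrodes):
        if len(face_sets.get(i, FaceSet(np.empty((0, 3), int), np.empty(0, int),
                                        np.empty(0, int)))) == 0:
            raise GeometryError(
                f"electrode {i} ({spec.role}) produced an empty footprint on the grid")
    return ConductorGrid(origin, resolution, material, sigma, face_sets, roles)


def _electrode_faces(phantom, material, elec_id, origin, resolution, n_elec):
    """Outermost hydrogel voxels per electrode (air neighbour farther out)."""
    face_sets: dict[int, FaceSet] = {}
    nx, ny, nz = material.shape
    for ei in range(n_elec):
        vox = np.argwhere(elec_id == ei)
        rows = []
        for i, j, k in vox:
            zz = origin[2] + resolution * k
            outer = phantom.station_at(zz).outer
            own = outer.norm_radius(origin[:2] + resolution * np.array([i, j]))
            best = None
            for axis, step in _NEIGHBOR_STEPS:
                ni, nj, nk = i + step[0], j + step[1], k + step[2]
                if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                    continue
                if material[ni, nj, nk] != AIR:
                    continue
                if axis == 2:
                    continue  # outward direction is radial, not axial
                nr = outer.norm_radius(origin[:2] + resolution * np.array([ni, nj]))
                if nr > own and (best is None or nr > best[0]):
                    best = (nr, axis, step[axis])
            if best is not None:
                rows.append((i, j, k, best[1], best[2]))
        if rows:
            arr = np.array(rows, dtype=int)
            face_sets[ei] = FaceSet(arr[:, :3], arr[:, 3], arr[:, 4])
        else:
            face_sets[ei] = FaceSet(np.empty((0, 3), int), np.empty(0, int),
                                    np.empty(0, int))
    return face_sets


def homogeneous_cuboid_grid(size_mm: tuple[float, float, float],
                            resolution: float,
                            sigma: float | tuple[float, float, float],
                            electrode_patch_mm: tuple[float, float] | None = None
                            ) -> ConductorGrid:
    """Homogeneous cuboid with electrode faces on both z ends.

    A closed-form test bed: full (or centred partial) end faces act as the
    active (z = 0) and indifferent (z = L) electrodes.  ``electrode_patch_mm``
    restricts *both* end electrodes to a centred (wx, wy) patch, which makes
    the problem genuinely three-dimensional for convergence studies.
    """
    if isinstance(sigma, (int, float)):
        sigma = (float(sigma),) * 3
    nx, ny, nz = (max(1, int(round(s / resolution))) for s in size_mm)
    material = np.full((nx, ny, nz), MUSCLE, dtype=np.int8)
    sig = np.zeros(material.shape + (3,), dtype=float)
    sig[...] = np.asarray(sigma)
    origin = np.array([resolution / 2.0] * 3)

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    if electrode_patch_mm is not None:
        cx, cy = size_mm[0] / 2.0, size_mm[1] / 2.0
        xc = origin[0] + resolution * ii
        yc = origin[1] + resolution * jj
        sel = (np.abs(xc - cx) <= electrode_patch_mm[0] / 2.0) & \
              (np.abs(yc - cy) <= electrode_patch_mm[1] / 2.0)
    else:
        sel = np.ones_like(ii, dtype=bool)
    ii, jj = ii[sel], jj[sel]

    def faces(k, sign):
        idx = np.stack([ii, jj, np.full_like(ii, k)], axis=1)
        return FaceSet(idx, np.full(len(idx), 2), np.full(len(idx), sign))

    face_sets = {0: faces(0, -1), 1: faces(nz - 1, +1)}
    roles = {0: "different", 1: "indifferent"}
    return ConductorGrid(origin, resolution, material, sig, face_sets, roles)
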