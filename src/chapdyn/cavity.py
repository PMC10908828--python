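"""Luminal-cavity voxel volumetrics and client occupancy.

The interfacial cavity between the two chaperone protomers is measured on
a regular voxel grid with a two-grid scheme:

1. *exterior sealing*: bulk solvent is identified by flood fill (6-
   connectivity) from the grid boundary over free voxels of a grid whose
   atoms are inflated by the probe radius (default 1.4 A), so the probe
   cannot leak into the cavity through sub-probe wall gaps;
2. *volume*: the cavity is the flood-fill component of the seed point over
   free voxels of the plain (uninflated) grid, intersected with non-
   exterior voxels.  Volume = voxel count x h^3.

Client occupancy is the fraction of cavity voxels covered by the client
atoms' van der Waals spheres (no inflation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from chapdyn.core_io import MolecularStructure

__all__ = [
    "VoxelGrid",
    "CavityResult",
    "voxelize",
    "make_cavity_grids",
    "luminal_cavity",
    "occupancy_fraction",
    "atom_occupied_mask",
    "write_cavity_pdb",
]

logger = logging.getLogger(__name__)

_CONN6 = ndimage.generate_binary_structure(3, 1)  # face connectivity


@dataclass
class VoxelGrid:
    """Regular grid over the analysis region.

    ``occupied`` marks voxels whose center lies within the (optionally
    inflated) van der Waals radius of any selected atom.
    """

    origin: np.ndarray  # (3,), A
    spacing: float  # A
    occupied: np.ndarray  # (nx, ny, nz) bool

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupied.shape

    def voxel_volume(self) -> float:
        return self.spacing**3

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        return tuple(idx)

    def in_bounds(self, idx) -> bool:
        return all(0 <= idx[d] < self.dims[d] for d in range(3))

    def centers(self, mask: np.ndarray) -> np.ndarray:
        """(k, 3) centers of the voxels selected by a boolean mask."""
        ii = np.argwhere(mask)
        return self.origin + (ii + 0.5) * self.spacing


@dataclass
class CavityResult:
    """Cavity volume (A^3), client volume inside it, and occupancy."""

    cavity_volume: float
    cavity_mask: np.ndarray
    grid: VoxelGrid
    seed_point: np.ndarray
    client_volume: float | None = None
    occupancy: float | None = None


def _rasterize(
    origin: np.ndarray, spacing: float, dims, coords: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Mark voxels whose center is within radius of any atom."""
    occ = np.zeros(dims, dtype=bool)
    inv = 1.0 / spacing
    for (x, y, z), r in zip(coords, radii):
        lo = np.floor((np.array([x, y, z]) - r - origin) * inv).astype(int)
        hi = np.ceil((np.array([x, y, z]) + r - origin) * inv).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, dims)
        if np.any(lo >= hi):
            continue
        gx = origin[0] + (np.arange(lo[0], hi[0]) + 0.5) * spacing
        gy = origin[1] + (np.arange(lo[1], hi[1]) + 0.5) * spacing
        gz = origin[2] + (np.arange(lo[2], hi[2]) + 0.5) * spacing
        d2 = (
            (gx[:, None, None] - x) ** 2
            + (gy[None, :, None] - y) ** 2
            + (gz[None, None, :] - z) ** 2
        )
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return occ


def voxelize(
    structure: MolecularStructure,
    selection: np.ndarray,
    spacing: float = 0.5,
    inflation: float = 0.0,
    radii: np.ndarray | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> VoxelGrid:
    """Build an occupancy grid for the selected atoms.

    ``radii`` are per-selected-atom van der Waals radii (default 1.7 A);
    ``inflation`` (e.g. the probe radius) is added to every radius.  The
    grid covers the selection plus a padding of probe + max radius unless
    explicit ``bounds`` (origin, top corner) are supplied — pass shared
    bounds when two grids must be co-registered.
    """
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("voxelize requires a non-empty selection")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if inflation < 0:
        raise ValueError("inflation must be >= 0")
    coords = structure.coords[idx]
    r = np.full(idx.size, 1.7) if radii is None else np.asarray(radii, dtype=float)
    if r.shape != (idx.size,):
        raise ValueError("radii must have one value per selected atom")
    if bounds is None:
        pad = float(r.max() + inflation) + 2.0 * spacing
        origin = coords.min(axis=0) - pad
        top = coords.max(axis=0) + pad
    else:
        origin, top = (np.asarray(b, dtype=float) for b in bounds)
    dims = tuple(np.ceil((top - origin) / spacing).astype(int))
    occ = _rasterize(origin, spacing, dims, coords, r + inflation)
    return VoxelGrid(origin=origin, spacing=spacing, occupied=occ)


def make_cavity_grids(
    structure: MolecularStructure,
    wall_selection: np.ndarray,
    spacing: float = 0.5,
    probe_radius: float = 1.4,
    radii: np.ndarray | None = None,
) -> tuple[VoxelGrid, VoxelGrid]:
    """Co-registered (probe-inflated, plain) wall grids for cavity analysis."""
    idx = np.asarray(wall_selection, dtype=int)
    coords = structure.coords[idx]
    r = np.full(idx.size, 1.7) if radii is None else np.asarray(radii, dtype=float)
    pad = float(r.max() + probe_radius) + 2.0 * spacing
    bounds = (coords.min(axis=0) - pad, coords.max(axis=0) + pad)
    inflated = voxelize(structure, idx, spacing, probe_radius, r, bounds)
    plain = voxelize(structure, idx, spacing, 0.0, r, bounds)
    return inflated, plain


def _exterior_mask(grid: VoxelGrid) -> np.ndarray:
    """Free voxels connected (6-connectivity) to the grid boundary."""
    free = ~grid.occupied
    labels, _ = ndimage.label(free, structure=_CONN6)
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels |= set(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)
    return np.isin(labels, sorted(boundary_labels))


def _snap_seed(grid: VoxelGrid, seed_point: np.ndarray, free: np.ndarray) -> tuple[int, int, int]:
    idx = grid.index_of(seed_point)
    if grid.in_bounds(idx) and free[idx]:
        return idx
    # snap to the nearest free voxel within 3 A
    centers_idx = np.argwhere(free)
    if centers_idx.size == 0:
        raise ValueError("no free voxels available for the cavity seed")
    centers = grid.origin + (centers_idx + 0.5) * grid.spacing
    d = np.linalg.norm(centers - np.asarray(seed_point), axis=1)
    best = int(np.argmin(d))
    if d[best] > 3.0:
        raise ValueError(f"seed point is {d[best]:.1f} A from the nearest free voxel (> 3 A)")
    logger.info("cavity seed snapped by %.2f A to the nearest free voxel", d[best])
    return tuple(centers_idx[best])


def luminal_cavity(
    grid_inflated: VoxelGrid,
    grid_plain: VoxelGrid,
    seed_point: np.ndarray,
) -> CavityResult:
    """Seeded cavity volume with the two-grid scheme.

    Raises when the seed's probe-inflated free region reaches the grid
    boundary ("cavity open to solvent at this probe radius").
    """
    if grid_inflated.occupied.shape != grid_plain.occupied.shape or not np.allclose(
        grid_inflated.origin, grid_plain.origin
    ):
        raise ValueError("the two grids must be co-registered (same origin and dims)")
    exterior = _exterior_mask(grid_inflated)

    free_infl = ~grid_inflated.occupied
    seed_idx = _snap_seed(grid_inflated, seed_point, free_infl)
    if exterior[seed_idx]:
        raise ValueError(
            "cavity open to solvent at this probe radius; "
            "increase the probe/inflation radius to seal the walls"
        )

    free_plain = ~grid_plain.occupied
    labels_plain, _ = ndimage.label(free_plain, structure=_CONN6)
    seed_plain = seed_idx if free_plain[seed_idx] else _snap_seed(grid_plain, seed_point, free_plain)
    component = labels_plain == labels_plain[seed_plain]
    cavity = component & ~exterior
    volume = float(cavity.sum()) * grid_plain.voxel_volume()
    seed_center = grid_plain.origin + (np.array(seed_idx) + 0.5) * grid_plain.spacing
    return CavityResult(
        cavity_volume=volume, cavity_mask=cavity, grid=grid_plain, seed_point=seed_center
    )


def atom_occupied_mask(
    grid: VoxelGrid,
    structure: MolecularStructure,
    selection: np.ndarray,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Voxels of ``grid`` covered by the selected atoms' vdW spheres."""
    idx = np.asarray(selection, dtype=int)
    r = np.full(idx.size, 1.7) if radii is None else np.asarray(radii, dtype=float)
    return _rasterize(grid.origin, grid.spacing, grid.dims, structure.coords[idx], r)


def occupancy_fraction(
    result: CavityResult,
    structure: MolecularStructure,
    client_selection: np.ndarray,
    radii: np.ndarray | None = None,
) -> CavityResult:
    """Client volume inside the cavity and occupancy fraction (in place).

    Client voxels are those covered by the client atoms' vdW radii (no
    inflation) that fall inside the cavity component.  Warns when the
    client lies entirely outside the cavity.
    """
    client_occ = atom_occupied_mask(result.grid, structure, client_selection, radii)
    inside = client_occ & result.cavity_mask
    client_volume = float(inside.sum()) * result.grid.voxel_volume()
    if client_volume == 0.0:
        logger.warning("client atoms lie entirely outside the cavity; occupancy 0")
    occupancy = client_volume / result.cavity_volume if result.cavity_volume > 0 else 0.0
    result.client_volume = client_volume
    result.occupancy = occupancy
    return result


def write_cavity_pdb(result: CavityResult, path) -> None:
    """Pseudo-atom PDB of cavity voxel centers for visualization."""
    centers = result.grid.centers(result.cavity_mask)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(centers, start=1):
            fh.write(
                f"HETATM{i % 100000:>5}  C   CAV V{1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
            )
        fh.write("END\n")
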