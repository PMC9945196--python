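"""Hexahedral mesh in 1:1 correspondence with VOI voxels.

Each true voxel of the VOI mask becomes one 8-node cubic element centred at
the voxel location; nodes shared by neighbouring voxels are deduplicated so
face-adjacent elements share 4 nodes, edge-adjacent 2 and corner-adjacent 1.
A single voxel contributes 8 vertices and 12 unique edges.  Node and element
numbering is deterministic (lexicographic in z, y, x), so identical inputs
yield byte-identical connectivity.

Coordinates: node lattice point (i, j, k) sits at (i, j, k) * spacing, in mm;
the element for voxel (i, j, k) is centred at (i+1/2, j+1/2, k+1/2) * spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import BoundaryError, MeshError

log = logging.getLogger(__name__)

# VTK hexahedron corner ordering as (dx, dy, dz) offsets
_CORNERS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
], dtype=np.int64)

# the 12 edges of a hexahedron as local corner index pairs
_EDGES = np.array([
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
], dtype=np.int64)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class HexMesh:
    """Voxel-conforming hexahedral mesh.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array, mm
    elements : (n_elements, 8) int array of node indices (VTK ordering)
    element_to_voxel : (n_elements, 3) int array of source voxel indices
    spacing : float, voxel edge in micrometres
    shape : voxel-grid shape the mesh was built from
    edge_count : number of unique element edges
    node_sets : named node index sets (filled by :func:`boundary_sets`)
    """

    node_coords: np.ndarray
    elements: np.ndarray
    element_to_voxel: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    edge_count: int
    node_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def edge_length_mm(self) -> float:
        return self.spacing * 1e-3

    def extent_mm(self, axis: int = 2) -> float:
        """Mesh height along an axis in mm."""
        c = self.node_coords[:, axis]
        return float(c.max() - c.min())

    def top_surface_elements(self, axis: int = 2) -> np.ndarray:
        """Indices of elements whose upper face lies on the top mesh surface."""
        zmax = self.element_to_voxel[:, axis].max()
        return np.flatnonzero(self.element_to_voxel[:, axis] == zmax)


def _unique_edge_count(elements: np.ndarray) -> int:
    pairs = elements[:, _EDGES]              # (ne, 12, 2)
    pairs = np.sort(pairs.reshape(-1, 2), axis=1)
    # encode as single int for fast unique
    nmax = int(elements.max()) + 1
    codes = pairs[:, 0].astype(np.int64) * nmax + pairs[:, 1]
    return int(np.unique(codes).size)


def build_mesh(mask: np.ndarray, spacing: float, drop_floating: bool = False) -> HexMesh:
    """Build the voxel-conforming hexahedral mesh for a boolean VOI mask.

    Parameters
    ----------
    mask : 3D boolean array indexed [x, y, z]; each True voxel becomes an element.
    spacing : isotropic voxel edge in micrometres.
    drop_floating : if True, 26-connected components not touching the lowest
        occupied z-layer are removed (they would make the stiffness matrix
        singular under bottom-anchored loading); if False they are retained
        with a warning.

    Raises
    ------
    MeshError for an empty mask or non-positive spacing.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise MeshError(f"mask must be 3D, got ndim={mask.ndim}")
    if not mask.any():
        raise MeshError("mask is empty; nothing to mesh")
    if not spacing > 0:
        raise MeshError(f"spacing must be positive, got {spacing}")

    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp > 1:
        zmin = np.flatnonzero(mask.any(axis=(0, 1)))[0]
        anchored = np.unique(labels[:, :, zmin])
        anchored = set(anchored[anchored > 0].tolist())
        floating = [c for c in range(1, n_comp + 1) if c not in anchored]
        if floating:
            if drop_floating:
                log.warning("dropping %d floating component(s) not reaching the bottom layer",
                            len(floating))
                mask = mask & np.isin(labels, sorted(anchored))
                if not mask.any():
                    raise MeshError("all components dropped; mask empty")
            else:
                log.warning(
                    "mesh has %d component(s) not anchored to the bottom surface; "
                    "the stiffness matrix will be singular under bottom-fixed loading "
                    "(build with drop_floating=True to remove them)", len(floating))
        else:
            log.warning("mesh has %d disconnected components (all bottom-anchored)", n_comp)

    nx, ny, nz = mask.shape
    # voxels in z-major (z, y, x) lexicographic order
    vox_zyx = np.argwhere(mask.transpose(2, 1, 0))
    voxels = vox_zyx[:, ::-1]                # back to (x, y, z)

    node_grid = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    for dx, dy, dz in _CORNERS:
        node_grid[voxels[:, 0] + dx, voxels[:, 1] + dy, voxels[:, 2] + dz] = True

    node_id = np.full(node_grid.shape, -1, dtype=np.int64)
    used_zyx = np.argwhere(node_grid.transpose(2, 1, 0))
    used = used_zyx[:, ::-1]
    node_id[used[:, 0], used[:, 1], used[:, 2]] = np.arange(used.shape[0])

    node_coords = used.astype(float) * (spacing * 1e-3)  # mm

    corners = voxels[:, None, :] + _CORNERS[None, :, :]  # (ne, 8, 3)
    elements = node_id[corners[..., 0], corners[..., 1], corners[..., 2]]

    return HexMesh(
        node_coords=node_coords,
        elements=elements,
        element_to_voxel=voxels,
        spacing=float(spacing),
        shape=mask.shape,
        edge_count=_unique_edge_count(elements),
    )


def boundary_sets(mesh: HexMesh, axis: str = "z") -> tuple[np.ndarray, np.ndarray]:
    """Loading-surface node sets: (top, bottom) along a grid axis.

    The loading surfaces are the extreme node planes along the axis (by
    default z, matching a platen-compression setup).  The mesh must be at
    least two voxels tall along the axis so the loaded and fixed surfaces
    do not belong to the same element layer.

    The sets are also cached on ``mesh.node_sets`` under ``top``/``bottom``.
    """
    if axis not in _AXES:
        raise BoundaryError(f"axis must be one of {tuple(_AXES)}, got {axis!r}")
    ax = _AXES[axis]
    vox = mesh.element_to_voxel[:, ax]
    if vox.max() - vox.min() < 1:
        raise BoundaryError(
            f"mesh is a single voxel layer along {axis}; loading surfaces are degenerate")
    coord = mesh.node_coords[:, ax]
    top = np.flatnonzero(np.isclose(coord, coord.max()))
    bottom = np.flatnonzero(np.isclose(coord, coord.min()))
    mesh.node_sets["top"] = top
    mesh.node_sets["bottom"] = bottom
    return top, bottom


def write_vtk(mesh: HexMesh, path, cell_data: dict | None = None) -> None:
    """Export the mesh as a legacy ASCII VTK unstructured grid (cell type 12).

    ``cell_data`` maps field names to per-element scalar arrays.
    """
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntbfe voxel mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.node_coords, fmt="%.9g")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {ne * 9}\n")
        cells = np.column_stack([np.full(ne, 8, dtype=np.int64), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, 12, dtype=np.int64), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {ne}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr, dtype=float), fmt="%.9g")
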