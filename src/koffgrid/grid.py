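"""Regular 3D lattices and voxel-set operations on scalar fields.

A field lives on a point-centered lattice: point (i, j, k) sits at
``origin + (i, j, k) * spacing`` (0-based indices) and owns a voxel of
volume ``spacing**3``.  Sublevel sets use strict inequality (E < level);
connected components use 26-connectivity; ties are broken lexicographically
so every operation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lattice: origin (A), spacing (A), dims."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be positive, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def point(self, i: int, j: int, k: int) -> np.ndarray:
        return np.asarray(self.origin) + np.array([i, j, k]) * self.spacing

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), in C (i-major) order."""
        nx, ny, nz = self.dims
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return np.asarray(self.origin) + idx * self.spacing

    def index_coords(self) -> np.ndarray:
        """Coordinates as an array of shape dims + (3,)."""
        return self.points().reshape(*self.dims, 3)


@dataclass
class MIFGrid:
    """One probe's interaction energies (kcal/mol) on a lattice."""

    grid: GridSpec
    probe_name: str
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != self.grid.dims:
            raise ValueError(
                f"energies shape {self.energies.shape} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("field energies must be finite everywhere")


def build_grid(mol, spacing: float = 0.5, margin: float = 5.0) -> GridSpec:
    """Lattice covering the molecule's bounding box expanded by ``margin``.

    Per axis, dims = floor((extent + 2*margin)/spacing) + 1 and the origin is
    the min corner minus the margin.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    coords = np.asarray(mol.coords, dtype=float)
    if coords.shape[0] < 1:
        raise ValueError("molecule must have at least one atom")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    extent = hi - lo
    dims = tuple(int(np.floor((e + 2 * margin) / spacing)) + 1 for e in extent)
    origin = tuple(lo - margin)
    return GridSpec(origin=origin, spacing=spacing, dims=dims)


def sublevel_volume(field: MIFGrid, level: float) -> float:
    """Volume (A^3) of the strict sublevel set {E < level}."""
    if not np.isfinite(level):
        raise ValueError("level must be finite")
    return float(np.count_nonzero(field.energies < level)) * field.grid.voxel_volume


def superlevel_volume(field: MIFGrid, level: float) -> float:
    """Volume (A^3) of {E >= level}; used for the repulsive molecular core."""
    if not np.isfinite(level):
        raise ValueError("level must be finite")
    return float(np.count_nonzero(field.energies >= level)) * field.grid.voxel_volume


def sublevel_components(
    field: MIFGrid, level: float
) -> list[tuple[float, np.ndarray]]:
    """Connected components of {E < level} under 26-connectivity.

    Returns (volume A^3, barycenter A) pairs sorted by volume descending,
    volume ties broken by lexicographic barycenter.  Component volumes sum
    to :func:`sublevel_volume` at the same level.
    """
    if not np.isfinite(level):
        raise ValueError("level must be finite")
    mask = field.energies < level
    labels, n = ndimage.label(mask, structure=_STRUCTURE_26)
    if n == 0:
        return []
    vv = field.grid.voxel_volume
    origin = np.asarray(field.grid.origin)
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        volume = len(idx) * vv
        barycenter = origin + idx.mean(axis=0) * field.grid.spacing
        out.append((float(volume), barycenter))
    out.sort(key=lambda c: (-c[0], tuple(c[1])))
    return out


def local_minima(
    field: MIFGrid, max_count: int = 3
) -> list[tuple[float, np.ndarray]]:
    """Up to ``max_count`` strict local minima with E < 0, deepest first.

    A point is a minimum iff strictly lower than all of its existing (<= 26)
    neighbors; boundary points compare only against in-grid neighbors.
    Equal-energy minima are ordered by lexicographic (i, j, k).
    """
    e = field.energies
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbor_min = ndimage.minimum_filter(
        e, footprint=footprint, mode="constant", cval=np.inf
    )
    mask = (e < neighbor_min) & (e < 0)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return []
    entries = sorted(
        ((float(e[tuple(i)]), tuple(i)) for i in idx), key=lambda t: (t[0], t[1])
    )
    origin = np.asarray(field.grid.origin)
    return [
        (energy, origin + np.array(ijk) * field.grid.spacing)
        for energy, ijk in entries[:max_count]
    ]
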