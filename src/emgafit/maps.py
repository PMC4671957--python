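"""Density maps: data model, MRC/CCP4 I/O, and map simulation by Gaussian blurring.

The grid is indexed ``grid[ix, iy, iz]``; ``origin`` is the Å position of the
centre of voxel ``(0, 0, 0)`` and voxels are isotropic.  Simulated maps follow
the convention that each atom is blurred by an isotropic Gaussian of standard
deviation sigma_factor × resolution.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "SimulationParams",
    "GridSpec",
    "read_map",
    "write_map",
    "simulate_map",
    "threshold_mask",
]

DEFAULT_SIGMA_FACTOR = 0.356
DEFAULT_VOXEL_SIZE = 3.5
TRUNCATION_SIGMAS = 3.0  # Gaussian support cut-off; <1.2% of mass discarded


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Target grid geometry: shape, voxel size and origin (first-voxel centre)."""

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float]


@dataclasses.dataclass
class DensityMap:
    """A 3D density grid with isotropic voxels.

    Attributes
    ----------
    grid : (nx, ny, nz) float array of density values.
    voxel_size : Å per voxel edge.
    origin : Å position of the centre of voxel (0, 0, 0).
    resolution : nominal resolution in Å (metadata; 0 when unknown).
    """

    grid: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float]
    resolution: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a non-empty 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def stats(self) -> tuple[float, float]:
        """(mean, sigma) of the grid values."""
        return float(self.grid.mean()), float(self.grid.std())

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.grid.shape, self.voxel_size, self.origin)

    @property
    def center(self) -> np.ndarray:
        """Geometric centre of the grid in Å."""
        return np.asarray(self.origin) + (np.asarray(self.grid.shape) - 1) * self.voxel_size / 2.0

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Å coordinates of voxel centres for an (n, 3) index array."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * self.voxel_size

    def same_grid(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (
            self.grid.shape == other.grid.shape
            and abs(self.voxel_size - other.voxel_size) <= tol
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Parameters of the Gaussian point-spread simulation.

    ``sigma_factor`` multiplies the nominal resolution to give the Gaussian
    standard deviation (default 0.356); the default voxel size is 3.5 Å.
    ``padding`` is the Å margin added around the structure when no target
    geometry is supplied (default 2 × resolution, so tails are not clipped).
    """

    resolution: float
    sigma_factor: float = DEFAULT_SIGMA_FACTOR
    voxel_size: float = DEFAULT_VOXEL_SIZE
    padding: float | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.voxel_size <= 0 or self.sigma_factor <= 0:
            raise ValueError("resolution, voxel_size and sigma_factor must be positive")

    @property
    def sigma(self) -> float:
        return self.sigma_factor * self.resolution

    @property
    def effective_padding(self) -> float:
        return 2.0 * self.resolution if self.padding is None else self.padding


def read_map(path: str | Path, resolution: float = 0.0) -> DensityMap:
    """Read an MRC2014/CCP4 map; axis order is normalized to x, y, z."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read map file: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"failed to parse map {path}: {exc}") from exc
    grid = np.array(ccp4.grid, copy=True, dtype=np.float64)
    cell = ccp4.grid.unit_cell
    nx, ny, nz = grid.shape
    voxels = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    vmean = float(voxels.mean())
    if np.any(np.abs(voxels - vmean) > 0.01 * vmean):
        raise ValueError(
            f"{path}: anisotropic voxel sizes {tuple(voxels)} exceed 1% tolerance"
        )
    if not np.allclose(voxels, vmean, atol=1e-12):
        log.info("%s: averaging slightly anisotropic voxel sizes %s", path, voxels)
    origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        start = np.array([ccp4.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = start * vmean
    return DensityMap(grid, vmean, tuple(origin), resolution=resolution)


def write_map(m: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014/CCP4 with correct cell, origin and statistics."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.asarray(m.grid, dtype=np.float32))
    nx, ny, nz = m.grid.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * m.voxel_size, ny * m.voxel_size, nz * m.voxel_size, 90.0, 90.0, 90.0
    )
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for i, v in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(i, float(v))
    ccp4.write_ccp4_map(str(path))


def _gather_coords(model) -> np.ndarray:
    """Accept an AssemblyModel, a Component list, or a raw (n, 3) array."""
    from .structio import AssemblyModel, Component  # local import avoids a cycle

    if isinstance(model, AssemblyModel):
        return np.vstack([c.coords for c in model.placed()])
    if isinstance(model, Component):
        return model.coords
    if isinstance(model, (list, tuple)) and model and isinstance(model[0], Component):
        return np.vstack([c.coords for c in model])
    return np.atleast_2d(np.asarray(model, dtype=float))


def simulate_map(
    model,
    p: SimulationParams,
    grid_spec: GridSpec | None = None,
) -> DensityMap:
    """Simulate a density map by blurring atom positions with a Gaussian PSF.

    Every atom contributes an identical isotropic Gaussian of standard
    deviation ``p.sigma`` (sigma_factor × resolution), normalized to unit
    mass and truncated at 3σ — so a lower resolution (broader blur) flattens
    peaks rather than raising them.  With ``grid_spec`` the density is laid
    on exactly that geometry, which is what aligns a probe map with its
    target for mutual-information scoring.
    """
    coords = _gather_coords(model)
    if len(coords) == 0:
        raise ValueError("cannot simulate a map from zero atoms")
    sigma = p.sigma
    if grid_spec is None:
        pad = p.effective_padding
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        shape = tuple(int(np.ceil((h - l) / p.voxel_size)) + 1 for l, h in zip(lo, hi))
        spec = GridSpec(shape, p.voxel_size, tuple(lo))
    else:
        spec = grid_spec

    vs = spec.voxel_size
    origin = np.asarray(spec.origin)
    shape = np.asarray(spec.shape)
    grid = np.zeros(tuple(shape), dtype=np.float64)

    r = int(np.ceil(TRUNCATION_SIGMAS * sigma / vs))
    # voxel-index position of each atom (continuous)
    pos = (coords - origin) / vs
    base = np.round(pos).astype(int)
    offsets = np.stack(
        np.meshgrid(*([np.arange(-r, r + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)  # (w, 3)

    # (n_atoms, w, 3) voxel indices and squared distances in Å
    idx = base[:, None, :] + offsets[None, :, :]
    d2 = ((idx - pos[:, None, :]) ** 2).sum(axis=2) * vs * vs
    norm = (sigma * np.sqrt(2.0 * np.pi)) ** -3
    w = norm * np.exp(-0.5 * d2 / (sigma * sigma))
    w[d2 > (TRUNCATION_SIGMAS * sigma) ** 2] = 0.0

    inside = np.all((idx >= 0) & (idx < shape), axis=2)
    flat = (idx[..., 0] * shape[1] + idx[..., 1]) * shape[2] + idx[..., 2]
    np.add.at(grid.reshape(-1), flat[inside], w[inside])
    return DensityMap(grid, vs, tuple(origin), resolution=p.resolution)


def threshold_mask(
    m: DensityMap, k_sigma: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Select voxels with density above mean + k_sigma × σ.

    Returns the boolean mask and the Å coordinates of the selected voxel
    centres.  The 2σ default mirrors the threshold used to pick the region
    of the map worth seeding component placements into.
    """
    mean, sigma = m.stats
    mask = m.grid > mean + k_sigma * sigma
    indices = np.argwhere(mask)
    coords = m.voxel_centers(indices)
    if len(coords) == 0:
        log.info("threshold_mask: empty selection at k_sigma=%.3g", k_sigma)
    return mask, coords
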