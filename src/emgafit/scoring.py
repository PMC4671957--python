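"""Fitness of a candidate assembly: mutual information minus a clash penalty.

The goodness of fit between the candidate model and the target map is the
mutual information (MI) between the binned density distributions of the
simulated probe map and the target map, computed over all aligned voxels.
Clashes between components are penalized by the sum over component pairs of
their fractional voxel overlap (PS).  The total fitness of an n-component
assembly is

    F = n * MI - PS

so that the goodness-of-fit term keeps pace with the clash term as the
component count grows.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .maps import DensityMap, GridSpec, SimulationParams, simulate_map
from .structio import AssemblyModel, Component

__all__ = [
    "JointHistogram",
    "FitnessBreakdown",
    "joint_histogram",
    "mutual_information",
    "clash_penalty",
    "clash_penalty_coords",
    "fitness",
]

DEFAULT_BINS = 20
DEFAULT_CLASH_VOXEL = 3.5


@dataclasses.dataclass
class JointHistogram:
    """Joint counts of (probe bin, target bin) over aligned voxels."""

    counts: np.ndarray  # (bins, bins)
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def bins(self) -> int:
        return self.counts.shape[0]

    @property
    def marginal_x(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def mutual_information(self) -> float:
        """MI in nats: sum p(x,y) log[p(x,y) / (p(x) p(y))], 0·log0 := 0."""
        p = self.counts / self.n
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        outer = np.outer(px, py)
        nz = p > 0
        return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


@dataclasses.dataclass(frozen=True)
class FitnessBreakdown:
    """MI, clash penalty PS and the combined fitness f = n·MI − PS."""

    mi: float
    ps: float
    n: int

    @property
    def f(self) -> float:
        return self.n * self.mi - self.ps

    def __repr__(self) -> str:  # compact, used in logs and TSV output
        return f"FitnessBreakdown(mi={self.mi:.6f}, ps={self.ps:.6f}, n={self.n}, f={self.f:.6f})"


def _bin_indices(values: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin index for every value over the array's own [min, max].

    A constant array collapses to a single occupied bin (and contributes no
    information).  The maximum value is assigned to the last bin.
    """
    lo = values.min()
    hi = values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.intp), np.array([lo, lo + 1.0])
    width = (hi - lo) / bins
    idx = np.clip(((values - lo) / width).astype(np.intp), 0, bins - 1)
    edges = lo + width * np.arange(bins + 1)
    return idx, edges


def joint_histogram(probe: DensityMap, target: DensityMap, bins: int = DEFAULT_BINS) -> JointHistogram:
    """Bin both maps over their own full density ranges and count aligned voxels."""
    if not probe.same_grid(target):
        raise ValueError("probe and target maps must share grid geometry")
    x = probe.grid.ravel()
    y = target.grid.ravel()
    xi, x_edges = _bin_indices(x, bins)
    yi, y_edges = _bin_indices(y, bins)
    counts = np.bincount(xi * bins + yi, minlength=bins * bins).reshape(bins, bins).astype(float)
    return JointHistogram(counts, x_edges, y_edges)


def mutual_information(probe: DensityMap, target: DensityMap, bins: int = DEFAULT_BINS) -> float:
    """Mutual information (nats) between aligned probe and target densities.

    Densities are divided into ``bins`` equal-width bins spanning each map's
    own [min, max]; all voxels are included.
    """
    return joint_histogram(probe, target, bins).mutual_information()


def _occupied_voxels(coords: np.ndarray, origin: np.ndarray, voxel_size: float) -> np.ndarray:
    idx = np.floor((coords - origin) / voxel_size).astype(np.int64)
    # linear addressing with a generous stride; grids here never exceed 2^20 per axis
    lin = (idx[:, 0] << 42) + (idx[:, 1] << 21) + idx[:, 2]
    return np.unique(lin)


def clash_penalty(
    placed: Sequence[Component],
    voxel_size: float = DEFAULT_CLASH_VOXEL,
) -> float:
    """Sum over component pairs of their fractional backbone/Cβ voxel overlap.

    Each component occupies the set of voxels (edge ``voxel_size``) containing
    its backbone (N, CA, C, O) or Cβ atoms; all components are voxelized on
    one shared lattice anchored at a multiple of the voxel size.  For a pair
    (i, j) the overlap fraction is |occ_i ∩ occ_j| / (|occ_i| + |occ_j|), so a
    fully superposed identical pair scores 0.5.
    """
    if len(placed) == 0:
        raise ValueError("clash_penalty needs at least one component")
    coord_sets = []
    for c in placed:
        bc = c.backbone_cb_coords
        if len(bc) == 0:
            raise ValueError(f"component {c.id!r} has no backbone/Cβ atoms")
        coord_sets.append(bc)
    return clash_penalty_coords(coord_sets, voxel_size)


def clash_penalty_coords(
    coord_sets: Sequence[np.ndarray],
    voxel_size: float = DEFAULT_CLASH_VOXEL,
) -> float:
    """Clash penalty from raw per-component backbone/Cβ coordinate arrays."""
    if len(coord_sets) == 1:
        return 0.0
    all_min = np.vstack([cs.min(axis=0) for cs in coord_sets]).min(axis=0)
    origin = np.floor(all_min / voxel_size) * voxel_size  # shared snapped lattice
    occ = [_occupied_voxels(cs, origin, voxel_size) for cs in coord_sets]
    ps = 0.0
    for i in range(len(occ)):
        for j in range(i + 1, len(occ)):
            inter = np.intersect1d(occ[i], occ[j], assume_unique=True)
            if len(inter):
                ps += len(inter) / (len(occ[i]) + len(occ[j]))
    return float(ps)


def fitness(
    model: AssemblyModel | Sequence[Component],
    target: DensityMap,
    p: SimulationParams | None = None,
    bins: int = DEFAULT_BINS,
    clash_voxel_size: float = DEFAULT_CLASH_VOXEL,
) -> FitnessBreakdown:
    """Score a placed assembly against a target map.

    The probe map is simulated from the placed components at the target's
    nominal resolution on the target's exact grid, so probe and target voxels
    align one-to-one for the MI term.
    """
    placed = model.placed() if isinstance(model, AssemblyModel) else list(model)
    if len(placed) == 0:
        raise ValueError("fitness needs at least one component")
    if p is None:
        if target.resolution <= 0:
            raise ValueError("target map needs a nominal resolution to simulate the probe")
        p = SimulationParams(resolution=target.resolution, voxel_size=target.voxel_size)
    probe = simulate_map(placed, p, grid_spec=target.spec)
    mi = mutual_information(probe, target, bins)
    ps = clash_penalty(placed, clash_voxel_size)
    return FitnessBreakdown(mi=mi, ps=ps, n=len(placed))
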