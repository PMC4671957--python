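"""Feature points: neural-gas vector quantization of a density map,
native-centroid extraction, and Hausdorff comparison of point sets.

The genetic algorithm seeds component placements on K feature points that
approximate the component centroids.  They come from a single neural-gas
vector-quantization run on the voxels above a 2σ density threshold; a user
may substitute an externally computed point set (a plain-text file with one
``x y z`` triple per line).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import directed_hausdorff, pdist

from .maps import DensityMap, threshold_mask

__all__ = [
    "PointSet",
    "NeuralGasParams",
    "vector_quantize",
    "native_centroids",
    "hausdorff",
    "min_pairwise_distance",
    "read_points",
    "write_points",
]


@dataclasses.dataclass
class PointSet:
    """An ordered set of 3D points in Å with a provenance tag."""

    points: np.ndarray
    label: str = "external"  # one of: vq, centroid, external

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            raise ValueError("a PointSet must contain at least one point")
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass(frozen=True)
class NeuralGasParams:
    """Neural-gas schedule.

    ``steps`` defaults to 10000 × k samples.  Learning rate eps and
    neighbourhood range λ decay exponentially from their initial to final
    values; λ starts at k/2 so that early updates drag the whole codebook
    toward dense regions and late updates are purely local.
    """

    k: int
    steps: int | None = None
    eps_initial: float = 0.1
    eps_final: float = 0.001
    lambda_initial: float | None = None  # defaults to k / 2
    lambda_final: float = 0.01
    threshold_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.steps is not None and self.steps < 1:
            raise ValueError("steps must be >= 1")

    @property
    def n_steps(self) -> int:
        return self.steps if self.steps is not None else 10000 * self.k

    @property
    def lam_initial(self) -> float:
        return self.lambda_initial if self.lambda_initial is not None else max(self.k / 2.0, self.lambda_final)


def vector_quantize(m: DensityMap, p: NeuralGasParams) -> PointSet:
    """Extract ``p.k`` feature points from a map by neural-gas clustering.

    Training vectors are the centres of voxels above the density threshold
    (mean + threshold_sigma × σ), sampled with probability proportional to
    their density.  The codebook is updated by the neural-gas rule
    ``w_j += eps(t) · exp(-rank_j / λ(t)) · (x − w_j)`` with exponentially
    interpolated schedules.  Deterministic for a fixed seed.
    """
    mask, coords = threshold_mask(m, p.threshold_sigma)
    if len(coords) < p.k:
        raise ValueError(
            f"only {len(coords)} voxels above threshold but k={p.k}; "
            "lower threshold_sigma"
        )
    dens = m.grid[mask].astype(float)  # same C-order as argwhere in threshold_mask
    # density-proportional sampling; densities above a 2σ threshold are positive
    weights = np.clip(dens, 0.0, None)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    prob = weights / weights.sum()

    rng = np.random.default_rng(p.seed)
    T = p.n_steps
    init_idx = rng.choice(len(coords), size=p.k, replace=False, p=prob)
    codebook = coords[init_idx].astype(float).copy()

    sample_idx = rng.choice(len(coords), size=T, p=prob)
    t_frac = np.arange(T) / max(T - 1, 1)
    eps_sched = p.eps_initial * (p.eps_final / p.eps_initial) ** t_frac
    lam_sched = p.lam_initial * (p.lambda_final / p.lam_initial) ** t_frac
    ranks_buf = np.empty(p.k)
    for t in range(T):
        x = coords[sample_idx[t]]
        d2 = ((codebook - x) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")
        ranks_buf[order] = np.arange(p.k)
        h = eps_sched[t] * np.exp(-ranks_buf / lam_sched[t])
        codebook += h[:, None] * (x - codebook)
    return PointSet(codebook, label="vq")


def native_centroids(components: Sequence) -> PointSet:
    """Centroid of each component, in component order."""
    if len(components) == 0:
        raise ValueError("need at least one component")
    pts = np.vstack([np.asarray(c.com, dtype=float) for c in components])
    return PointSet(pts, label="centroid")


def hausdorff(a: PointSet, b: PointSet) -> float:
    """Symmetric Hausdorff distance max(h(A,B), h(B,A)) in Å,
    where h(A,B) = max over a of min over b of ||a − b||."""
    d_ab = directed_hausdorff(a.points, b.points)[0]
    d_ba = directed_hausdorff(b.points, a.points)[0]
    return float(max(d_ab, d_ba))


def min_pairwise_distance(a: PointSet) -> float:
    """Minimum Euclidean distance over all unordered point pairs."""
    if len(a) < 2:
        raise ValueError("min_pairwise_distance needs at least two points")
    return float(pdist(a.points).min())


def read_points(path: str | Path, label: str = "external") -> PointSet:
    """Read a whitespace-delimited ``x y z`` per line point file ('#' comments)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = line.split()
        if len(vals) != 3:
            raise ValueError(f"{path}: expected 3 columns, got {len(vals)}: {line!r}")
        rows.append([float(v) for v in vals])
    if not rows:
        raise ValueError(f"{path}: no points found")
    return PointSet(np.asarray(rows), label=label)


def write_points(ps: PointSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {len(ps)} feature points ({ps.label}), x y z in Angstrom\n")
        for x, y, z in ps.points:
            fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
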