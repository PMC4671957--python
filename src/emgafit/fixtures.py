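"""Synthetic toy assemblies with known ground truth.

Components are compact self-avoiding pseudo-Cα chains (3.8 Å consecutive
spacing) with backbone N, C, O and Cβ atoms synthesized at ideal offsets, so
map simulation and the clash penalty see realistic occupancy.  Assemblies
pack the components without overlap, simulate a target map, and keep the
native transforms and centroids — everything an end-to-end recovery
experiment needs, with no downloads.

These fixtures emulate the geometry of protein assemblies (sizes, spacing,
blur), not real fold statistics or sidechain chemistry.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .featurepoints import PointSet
from .maps import DensityMap, SimulationParams, simulate_map
from .scoring import clash_penalty
from .structio import AssemblyModel, Component, RigidTransform, apply_transform

__all__ = ["FixtureSpec", "FixtureAssembly", "make_component", "make_assembly"]

_AA = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

CA_SPACING = 3.8  # Å between consecutive pseudo-Cα
SELF_AVOID = 4.0  # Å minimum between non-consecutive Cα


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy assembly.

    ``residues_per_component`` spans distinct sizes across components (helps
    the goodness-of-fit term tell components apart); ``packing`` is the
    minimum inter-centroid distance in Å.  Defaults produce a comfortably
    separated three-component assembly blurred to 10 Å on a 3.5 Å grid.
    """

    n_components: int = 3
    residues_per_component: tuple[int, int] = (35, 65)
    packing: float = 28.0
    resolution: float = 10.0
    voxel_size: float = 3.5
    seed: int = 0
    identical_pairs: tuple[tuple[int, int], ...] = ()
    map_padding: float = 10.0

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.packing <= 0:
            raise ValueError("n_components >= 1 and packing > 0 required")


@dataclasses.dataclass
class FixtureAssembly:
    """Everything a recovery experiment needs, ground truth included."""

    components: list[Component]  # unplaced: each centred at the origin
    native_transforms: list[RigidTransform]
    native: AssemblyModel  # components + native transforms
    target_map: DensityMap
    centroids: PointSet  # native component centroids


def _compact_walk(n: int, rng: np.random.Generator, max_restarts: int = 50) -> np.ndarray:
    """Self-avoiding 3.8 Å-step walk biased toward its own centroid."""
    for _ in range(max_restarts):
        pts = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            for _attempt in range(60):
                center = np.mean(pts, axis=0)
                bias = center - pts[-1]
                norm = np.linalg.norm(bias)
                bias = bias / norm if norm > 1e-9 else np.zeros(3)
                d = rng.normal(size=3) + 0.8 * bias
                d /= np.linalg.norm(d)
                cand = pts[-1] + CA_SPACING * d
                prev = np.asarray(pts[:-1])
                if len(prev) == 0 or np.min(np.linalg.norm(prev - cand, axis=1)) >= SELF_AVOID:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise RuntimeError(
        f"could not build a self-avoiding chain of {n} residues; try fewer residues"
    )


def make_component(n_residues: int, seed: int, label: str = "A") -> Component:
    """Build one pseudo-atomic component, centred at the origin.

    Each residue carries N, CA, C, O and (except glycine) CB at ideal
    offsets from the Cα trace.  Deterministic per seed.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    ca = _compact_walk(n_residues, rng)
    res_names = [str(_AA[i]) for i in rng.integers(0, len(_AA), size=n_residues)]

    names: list[str] = []
    res_ids: list[int] = []
    rnames: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    for i in range(n_residues):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_ca = ca[i + 1] if i < n_residues - 1 else ca[i] + (ca[i] - ca[i - 1])
        d = next_ca - prev_ca
        d /= np.linalg.norm(d)
        # a reproducible perpendicular
        p = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(d, [0.0, 1.0, 0.0])
        p /= np.linalg.norm(p)
        q = np.cross(d, p)
        atom_set = [
            ("N", "N", ca[i] - 1.46 * d + 0.30 * p),
            ("CA", "C", ca[i]),
            ("C", "C", ca[i] + 1.52 * d + 0.25 * p),
            ("O", "O", ca[i] + 1.52 * d + 1.40 * q),
        ]
        if res_names[i] != "GLY":
            atom_set.append(("CB", "C", ca[i] + 1.53 * p))
        for name, elem, xyz in atom_set:
            names.append(name)
            res_ids.append(i)
            rnames.append(res_names[i])
            elements.append(elem)
            coords.append(xyz)
    comp = Component(label, names, np.asarray(res_ids), rnames, elements,
                     np.asarray(coords))
    return comp.with_coords(comp.coords - comp.com)  # centre at origin


def _place_centroids(n: int, packing: float, rng: np.random.Generator,
                     max_attempts: int = 2000) -> np.ndarray:
    """Centroid positions with all pairwise separations >= packing, kept compact."""
    pos = [np.zeros(3)]
    for _ in range(1, n):
        for attempt in range(max_attempts):
            anchor = pos[rng.integers(0, len(pos))]
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = anchor + d * rng.uniform(packing, 1.35 * packing)
            if all(np.linalg.norm(cand - p) >= packing for p in pos):
                pos.append(cand)
                break
        else:
            raise RuntimeError("packing infeasible; reduce packing or n_components")
    arr = np.asarray(pos)
    return arr - arr.mean(axis=0)


def make_assembly(spec: FixtureSpec) -> FixtureAssembly:
    """Build a toy assembly, its simulated target map and ground truth.

    Components get distinct sizes spread over ``residues_per_component``
    (identical pairs are literal copies), native placements respect the
    packing distance, and the native model is verified to be nearly
    clash-free (PS < 0.05) before the map is simulated.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.residues_per_component
    sizes = np.linspace(lo, hi, spec.n_components).round().astype(int)

    labels = [chr(ord("A") + i) for i in range(spec.n_components)]
    components: list[Component] = []
    for i in range(spec.n_components):
        components.append(make_component(int(sizes[i]), seed=int(rng.integers(2**31)),
                                         label=labels[i]))
    for (src, dst) in spec.identical_pairs:
        copy = dataclasses.replace(components[src], id=labels[dst])
        copy.coords = components[src].coords.copy()
        components[dst] = copy

    for _attempt in range(50):
        centroids = _place_centroids(spec.n_components, spec.packing, rng)
        transforms = []
        for i in range(spec.n_components):
            rot = Rotation.random(rng=rng)
            transforms.append(RigidTransform.from_rotation(rot, tuple(centroids[i])))
        placed = [apply_transform(c, t) for c, t in zip(components, transforms)]
        if clash_penalty(placed, spec.voxel_size) < 0.05:
            break
    else:
        raise RuntimeError("could not place components without clashes")

    native = AssemblyModel(components, transforms)
    params = SimulationParams(resolution=spec.resolution, voxel_size=spec.voxel_size,
                              padding=spec.map_padding)
    target = simulate_map(placed, params)
    centroid_pts = PointSet(np.vstack([c.com for c in placed]), label="centroid")
    return FixtureAssembly(components, transforms, native, target, centroid_pts)
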