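"""Genetic-algorithm sampler for multi-component density fitting.

A genotype encodes one candidate assembly as, per component, a translation
gene (the displacement of the component centroid from the map centre, in Å)
and a rotation gene (an index into a shared library of uniform quaternions).
The population is seeded on the feature points, evolved by per-gene
crossover, mutation and a diversity operator, and pruned by elitist
selection (best N of the merged 2N parents + children), which makes the
best-fitness trace monotone.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .featurepoints import PointSet, min_pairwise_distance
from .maps import DensityMap, SimulationParams
from .scoring import (
    DEFAULT_BINS,
    DEFAULT_CLASH_VOXEL,
    FitnessBreakdown,
    _bin_indices,
    clash_penalty_coords,
)
from .structio import AssemblyModel, Component, QuaternionSet, RigidTransform, generate_quaternion_set

__all__ = [
    "Genotype",
    "GAConfig",
    "ConvergenceTrace",
    "GAContext",
    "FitnessEvaluator",
    "mutation_rate",
    "seed_population",
    "tournament_select",
    "crossover_child",
    "mutate_translation",
    "mutate_rotation",
    "diversity_child",
    "next_generation",
    "run_ga",
    "run_ensemble",
    "decode_genotype",
]


@dataclasses.dataclass(eq=False)
class Genotype:
    """Candidate assembly: per-component (translation, rotation index) genes."""

    translations: np.ndarray  # (n, 3) Å, centroid displacement from map centre
    rotation_indices: np.ndarray  # (n,) indices into the quaternion set
    fitness: FitnessBreakdown | None = None

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotation_indices = np.asarray(self.rotation_indices, dtype=np.intp)
        if len(self.translations) != len(self.rotation_indices):
            raise ValueError("translation and rotation gene counts differ")

    @property
    def n(self) -> int:
        return len(self.translations)

    def copy(self) -> "Genotype":
        return Genotype(self.translations.copy(), self.rotation_indices.copy(), self.fitness)


@dataclasses.dataclass(frozen=True)
class GAConfig:
    """Sampler settings.

    Defaults follow the method's standard operating point: population 160,
    100 generations, per-gene crossover probability 0.8, mutation rate
    decaying linearly from 0.2 to 0.01, 90%/10% crossover/diversity child
    mix, tournament size 2, 20 independent runs, 5000-quaternion library.
    """

    population_size: int = 160
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_initial: float = 0.2
    mutation_final: float = 0.01
    diversity_fraction: float = 0.10
    diversity_mutation_rate: float = 0.10
    tournament_size: int = 2
    n_runs: int = 20
    quaternion_count: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.generations < 1 or self.n_runs < 1:
            raise ValueError("sizes must be >= 1")
        for p in (self.crossover_prob, self.mutation_initial, self.mutation_final,
                  self.diversity_fraction, self.diversity_mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mutation_initial < self.mutation_final:
            raise ValueError("mutation rate must not increase over generations")

    @property
    def n_crossover_children(self) -> int:
        return round((1.0 - self.diversity_fraction) * self.population_size)

    @property
    def n_diversity_children(self) -> int:
        return self.population_size - self.n_crossover_children


@dataclasses.dataclass
class ConvergenceTrace:
    """Per-generation best fitness, population mean and population SD."""

    best: list[float] = dataclasses.field(default_factory=list)
    mean: list[float] = dataclasses.field(default_factory=list)
    sd: list[float] = dataclasses.field(default_factory=list)

    def record(self, pop: Sequence[Genotype]) -> None:
        f = np.array([g.fitness.f for g in pop])
        self.best.append(float(f.max()))
        self.mean.append(float(f.mean()))
        self.sd.append(float(f.std()))

    def __len__(self) -> int:
        return len(self.best)


def mutation_rate(generation: int, cfg: GAConfig) -> float:
    """Linear decay from mutation_initial at generation 1 to mutation_final
    at the last generation (1-based)."""
    if cfg.generations == 1:
        return cfg.mutation_initial
    frac = (generation - 1) / (cfg.generations - 1)
    return cfg.mutation_initial + frac * (cfg.mutation_final - cfg.mutation_initial)


@dataclasses.dataclass
class GAContext:
    """Everything the operators need besides the population itself."""

    components: list[Component]
    quats: QuaternionSet
    points: PointSet
    map_center: np.ndarray
    mutation_range: float  # Å; min pairwise feature-point distance (or fallback)
    evaluate: Callable[[Genotype], FitnessBreakdown]

    @classmethod
    def build(
        cls,
        target: DensityMap,
        components: Sequence[Component],
        points: PointSet,
        quats: QuaternionSet,
        sim_params: SimulationParams | None = None,
    ) -> "GAContext":
        if len(points) >= 2:
            mrange = min_pairwise_distance(points)
        else:
            # degenerate single-feature-point case: fall back to the map resolution
            mrange = target.resolution if target.resolution > 0 else target.voxel_size
        evaluator = FitnessEvaluator(target, list(components), quats, sim_params)
        return cls(list(components), quats, points, target.center, mrange, evaluator)


class FitnessEvaluator:
    """Scores genotypes against a target map; caches everything reusable.

    Rotation matrices for the whole quaternion library, centred component
    coordinates, the target's bin assignment and the Gaussian splat stencil
    are all precomputed once, so a population evaluation reduces to matrix
    products, one scatter-add and one bincount per genotype.
    """

    def __init__(
        self,
        target: DensityMap,
        components: list[Component],
        quats: QuaternionSet,
        sim_params: SimulationParams | None = None,
        bins: int = DEFAULT_BINS,
        clash_voxel_size: float = DEFAULT_CLASH_VOXEL,
    ) -> None:
        if sim_params is None:
            if target.resolution <= 0:
                raise ValueError("target map needs a nominal resolution")
            sim_params = SimulationParams(resolution=target.resolution,
                                          voxel_size=target.voxel_size)
        self.target = target
        self.components = components
        self.sim_params = sim_params
        self.bins = bins
        self.clash_voxel_size = clash_voxel_size
        self.map_center = target.center

        self.rot_mats = quats.rotations().as_matrix()  # (Q, 3, 3)
        self.centered = [c.coords - c.com for c in components]
        self.backbone_masks = [c.backbone_cb_mask for c in components]

        # target side of the MI histogram never changes
        self.target_idx, _ = _bin_indices(target.grid.ravel(), bins)
        self.n_vox = target.grid.size

        # Gaussian splat stencil on the target grid
        sigma = sim_params.sigma
        vs = target.voxel_size
        from .maps import TRUNCATION_SIGMAS

        r = int(np.ceil(TRUNCATION_SIGMAS * sigma / vs))
        self._off = np.arange(-r, r + 1)
        self._sigma = sigma
        self._trunc2 = (TRUNCATION_SIGMAS * sigma) ** 2
        self._shape = np.asarray(target.grid.shape)
        self._origin = np.asarray(target.origin)

    def place_coords(self, g: Genotype) -> list[np.ndarray]:
        """All-atom coordinates of each component under the genotype's genes."""
        out = []
        for i, cc in enumerate(self.centered):
            R = self.rot_mats[g.rotation_indices[i]]
            pos = self.map_center + g.translations[i]
            out.append(cc @ R.T + pos)
        return out

    def _probe_grid(self, coords: np.ndarray) -> np.ndarray:
        """Gaussian splat of all atoms onto the target grid.

        Mathematically identical to :func:`emgafit.maps.simulate_map` on the
        target's grid spec (same σ, same 3σ spherical truncation), but uses
        separable per-axis Gaussian factors and one weighted bincount, which
        is what makes per-genotype scoring cheap.
        """
        vs = self.target.voxel_size
        off = self._off
        pos = (coords - self._origin) / vs
        base = np.round(pos).astype(np.int64)
        # per-axis squared distances (Å²) and Gaussian factors, (n_atoms, w)
        d = off[None, :, None] - (pos - base)[:, None, :]
        d2 = d * d * vs * vs  # (n_atoms, w, 3)
        e = np.exp(-0.5 * d2 / (self._sigma ** 2)) / (self._sigma * np.sqrt(2.0 * np.pi))
        w3 = np.einsum("ni,nj,nk->nijk", e[:, :, 0], e[:, :, 1], e[:, :, 2])
        dx2, dy2, dz2 = d2[:, :, 0], d2[:, :, 1], d2[:, :, 2]
        d2tot = dx2[:, :, None, None] + dy2[:, None, :, None] + dz2[:, None, None, :]
        w3[d2tot > self._trunc2] = 0.0
        ax_idx = base[:, None, :] + off[None, :, None]  # (n_atoms, w, 3)
        valid_ax = (ax_idx >= 0) & (ax_idx < self._shape)
        ix, iy, iz = ax_idx[:, :, 0], ax_idx[:, :, 1], ax_idx[:, :, 2]
        vx, vy, vz = valid_ax[:, :, 0], valid_ax[:, :, 1], valid_ax[:, :, 2]
        valid = vx[:, :, None, None] & vy[:, None, :, None] & vz[:, None, None, :]
        flat = (ix[:, :, None, None] * (self._shape[1] * self._shape[2])
                + (iy * self._shape[2])[:, None, :, None]
                + iz[:, None, None, :])
        flat = np.where(valid, flat, 0)
        w3 *= valid
        n_vox = int(np.prod(self._shape))
        grid = np.bincount(flat.ravel(), weights=w3.ravel(), minlength=n_vox)
        return grid.reshape(tuple(self._shape))

    def __call__(self, g: Genotype) -> FitnessBreakdown:
        placed = self.place_coords(g)
        probe = self._probe_grid(np.vstack(placed))
        probe_idx, _ = _bin_indices(probe.ravel(), self.bins)
        counts = np.bincount(probe_idx * self.bins + self.target_idx,
                             minlength=self.bins * self.bins).astype(float)
        p = counts / self.n_vox
        p2 = p.reshape(self.bins, self.bins)
        px = p2.sum(axis=1)
        py = p2.sum(axis=0)
        outer = np.outer(px, py).ravel()
        nz = p > 0
        mi = float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))
        backbone = [c[m] for c, m in zip(placed, self.backbone_masks)]
        ps = clash_penalty_coords(backbone, self.clash_voxel_size)
        return FitnessBreakdown(mi=mi, ps=ps, n=len(placed))


def decode_genotype(g: Genotype, ctx: GAContext) -> AssemblyModel:
    """Turn genes into an :class:`AssemblyModel` with explicit transforms."""
    transforms = []
    for i, comp in enumerate(ctx.components):
        w, x, y, z = ctx.quats.quaternions[g.rotation_indices[i]]
        translation = ctx.map_center + g.translations[i] - comp.com
        transforms.append(RigidTransform((float(w), float(x), float(y), float(z)),
                                         tuple(float(v) for v in translation)))
    return AssemblyModel(list(ctx.components), transforms)


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def seed_population(
    points: PointSet,
    components: Sequence[Component],
    quats: QuaternionSet,
    cfg: GAConfig,
    rng: np.random.Generator,
    map_center: np.ndarray,
    mutation_range: float | None = None,
) -> list[Genotype]:
    """Seed the initial population on the feature points.

    Half the genotypes place every component centroid exactly on a uniformly
    chosen feature point (with replacement); the other half additionally
    displace each component by a random vector with length uniform in
    [0, 2 × min pairwise feature-point distance].
    """
    if len(components) == 0:
        raise ValueError("need at least one component")
    n = len(components)
    if mutation_range is None:
        mutation_range = (min_pairwise_distance(points) if len(points) >= 2 else 0.0)
    max_disp = 2.0 * mutation_range
    n_undisplaced = (cfg.population_size + 1) // 2
    center = np.asarray(map_center, dtype=float)
    pop: list[Genotype] = []
    for i in range(cfg.population_size):
        pt_idx = rng.integers(0, len(points), size=n)
        trans = points.points[pt_idx] - center
        if i >= n_undisplaced and max_disp > 0:
            for j in range(n):
                trans[j] += _random_direction(rng) * rng.uniform(0.0, max_disp)
        rot_idx = rng.integers(0, quats.size, size=n)
        pop.append(Genotype(trans, rot_idx))
    return pop


def tournament_select(
    pop: Sequence[Genotype], size: int = 2, rng: np.random.Generator | None = None
) -> Genotype:
    """Return the fittest of ``size`` genotypes drawn without replacement."""
    rng = rng or np.random.default_rng()
    size = min(size, len(pop))
    idx = rng.choice(len(pop), size=size, replace=False)
    best = max(idx, key=lambda i: pop[i].fitness.f)
    return pop[best]


def mutate_translation(
    vec: np.ndarray, max_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Add a random vector with uniformly distributed length in [0, max_length]."""
    return vec + _random_direction(rng) * rng.uniform(0.0, max_length)


def mutate_rotation(quats_size: int, rng: np.random.Generator) -> int:
    """Uniform draw of a replacement quaternion index."""
    return int(rng.integers(0, quats_size))


def crossover_child(
    parents: tuple[Genotype, Genotype],
    cfg: GAConfig,
    generation: int,
    rng: np.random.Generator,
    ctx: GAContext,
) -> Genotype:
    """Per-gene crossover of the fitter parent with the other, then mutation.

    The child starts as a copy of the fitter parent.  Independently for each
    translation gene and each rotation gene, with probability
    ``crossover_prob`` the gene is replaced by the other parent's value;
    every gene that crossed over is then mutated with the generation's
    mutation rate.
    """
    a, b = parents
    if a.n != b.n:
        raise ValueError("parents have mismatched gene counts")
    if a.fitness.f >= b.fitness.f:
        fitter, other = a, b
    else:
        fitter, other = b, a
    child = Genotype(fitter.translations.copy(), fitter.rotation_indices.copy())
    rate = mutation_rate(generation, cfg)
    for j in range(child.n):
        if rng.random() < cfg.crossover_prob:
            child.translations[j] = other.translations[j]
            if rng.random() < rate:
                child.translations[j] = mutate_translation(
                    child.translations[j], ctx.mutation_range, rng
                )
        if rng.random() < cfg.crossover_prob:
            child.rotation_indices[j] = other.rotation_indices[j]
            if rng.random() < rate:
                child.rotation_indices[j] = mutate_rotation(ctx.quats.size, rng)
    return child


def diversity_child(
    fittest: Genotype,
    cfg: GAConfig,
    rng: np.random.Generator,
    ctx: GAContext,
) -> Genotype:
    """Swap two random component gene-pairs of the fittest genotype, then
    mutate every gene with the constant diversity mutation rate (0.1)."""
    child = Genotype(fittest.translations.copy(), fittest.rotation_indices.copy())
    n = child.n
    if n >= 2:
        i, j = rng.choice(n, size=2, replace=False)
        child.translations[[i, j]] = child.translations[[j, i]]
        child.rotation_indices[[i, j]] = child.rotation_indices[[j, i]]
    rate = cfg.diversity_mutation_rate
    for j in range(n):
        if rng.random() < rate:
            child.translations[j] = mutate_translation(
                child.translations[j], ctx.mutation_range, rng
            )
        if rng.random() < rate:
            child.rotation_indices[j] = mutate_rotation(ctx.quats.size, rng)
    return child


def next_generation(
    pop: list[Genotype],
    cfg: GAConfig,
    generation: int,
    ctx: GAContext,
    rng: np.random.Generator,
) -> list[Genotype]:
    """One generation: make children, evaluate, keep the best N of 2N.

    90% of the children come from tournament-selected crossover, 10% from
    the diversity operator applied to the current fittest genotype.  The
    merged parent+child pool is sorted by fitness (ties broken in favour of
    parents, then insertion order) and truncated to the population size, so
    the incumbent best can never be lost.
    """
    N = cfg.population_size
    fittest = max(pop, key=lambda g: g.fitness.f)
    children: list[Genotype] = []
    for _ in range(cfg.n_crossover_children):
        p1 = tournament_select(pop, cfg.tournament_size, rng)
        p2 = tournament_select(pop, cfg.tournament_size, rng)
        children.append(crossover_child((p1, p2), cfg, generation, rng, ctx))
    for _ in range(cfg.n_diversity_children):
        children.append(diversity_child(fittest, cfg, rng, ctx))
    for child in children:
        child.fitness = ctx.evaluate(child)
    merged = list(pop) + children  # parents first: stable sort prefers them on ties
    merged.sort(key=lambda g: -g.fitness.f)
    return merged[:N]


def run_ga(
    target: DensityMap,
    components: Sequence[Component],
    points: PointSet,
    cfg: GAConfig,
    run_seed: int = 0,
    ctx: GAContext | None = None,
) -> tuple[Genotype, ConvergenceTrace]:
    """One full GA run; returns the fittest final genotype and its trace.

    Fully reproducible from ``(cfg.seed, run_seed)``; the quaternion library
    depends only on ``cfg.seed`` so all runs of an ensemble share it.
    """
    if ctx is None:
        quats = generate_quaternion_set(cfg.quaternion_count, cfg.seed)
        ctx = GAContext.build(target, components, points, quats)
    rng = np.random.default_rng([cfg.seed, run_seed])
    pop = seed_population(points, components, ctx.quats, cfg, rng,
                          ctx.map_center, ctx.mutation_range)
    for g in pop:
        g.fitness = ctx.evaluate(g)
    trace = ConvergenceTrace()
    for generation in range(1, cfg.generations + 1):
        pop = next_generation(pop, cfg, generation, ctx, rng)
        trace.record(pop)
    best = max(pop, key=lambda g: g.fitness.f)
    return best, trace


@dataclasses.dataclass
class EnsembleResult:
    """Ranked output of independent GA runs (rank 1 = highest fitness)."""

    genotypes: list[Genotype]  # sorted by fitness, descending
    traces: list[ConvergenceTrace]  # in rank order
    run_seeds: list[int]  # in rank order
    ctx: GAContext
    bp_rank: int | None = None  # 1-based rank of the lowest-RMSD model
    bp_rmsd: float | None = None

    def model(self, rank: int) -> AssemblyModel:
        """Decoded assembly at 1-based fitness rank."""
        return decode_genotype(self.genotypes[rank - 1], self.ctx)

    @property
    def highest_scoring(self) -> AssemblyModel:
        return self.model(1)


def run_ensemble(
    target: DensityMap,
    components: Sequence[Component],
    points: PointSet,
    cfg: GAConfig,
    reference: AssemblyModel | None = None,
) -> EnsembleResult:
    """Run ``cfg.n_runs`` independent GAs and rank the outputs by fitness.

    All runs start from the same feature points and quaternion library but
    use distinct derived seeds.  When a reference assembly is supplied, the
    best-predicted (lowest-RMSD) model and its fitness rank are reported
    alongside the highest-scoring one.
    """
    quats = generate_quaternion_set(cfg.quaternion_count, cfg.seed)
    ctx = GAContext.build(target, components, points, quats)
    results = []
    for run in range(cfg.n_runs):
        best, trace = run_ga(target, components, points, cfg, run_seed=run, ctx=ctx)
        results.append((best, trace, run))
    results.sort(key=lambda r: -r[0].fitness.f)
    ensemble = EnsembleResult(
        genotypes=[r[0] for r in results],
        traces=[r[1] for r in results],
        run_seeds=[r[2] for r in results],
        ctx=ctx,
    )
    if reference is not None:
        from .assess import assembly_rmsd, identical_groups

        groups = identical_groups(list(components))
        rmsds = []
        for rank in range(1, len(ensemble.genotypes) + 1):
            model = ensemble.model(rank)
            rmsd, _ = assembly_rmsd(model, reference, groups)
            rmsds.append(rmsd)
        bp = int(np.argmin(rmsds))
        ensemble.bp_rank = bp + 1
        ensemble.bp_rmsd = float(rmsds[bp])
    return ensemble
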