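# Methods

This note records the model, the numerical choices, and the open design
decisions behind `emgafit`, in enough detail to reproduce or audit any
result the package computes.

## Problem and model

The input is a set of rigid atomic components (one per polymer chain or
file) and a density map of their assembly with a stated nominal resolution.
The output is a ranked ensemble of assembly configurations. Components are
strictly rigid: conformational change and partial assemblies are out of
scope, as is any post-hoc real-space refinement (the ensemble is emitted
unrefined; a refinement tool can be applied downstream).

A configuration assigns each component a rotation and a position. Rotations
are always applied **about the component centroid**, positions are stored as
centroid displacements **from the map centre**; this decouples the two gene
types so that crossover can exchange them independently, and makes
translation genes comparable across genotypes. The centroid is the
unweighted mean over all heavy atoms — the same convention is used for the
topology score and feature-point seeding, so the three uses are mutually
consistent. Mass weighting would change centroids by well under an Ångström
for typical protein chains, far below the radius-of-gyration scale at which
the topology score operates.

## Map simulation

A probe (or simulated target) map places an identical isotropic Gaussian at
every heavy-atom position: σ = sigma_factor × resolution with
sigma_factor = 0.356, unit mass per atom, truncated at 3σ (discarding
< 1.2% of the mass, which the test tolerances budget for). Atoms are not
element-weighted: blurring acts on atomic positions only, which keeps the
probe map symmetric with the element-agnostic clash grid. Unit-mass (rather
than unit-amplitude) Gaussians make peak height decrease as resolution
worsens, matching the physical intuition that blur flattens features;
mutual information is invariant to the overall scale either way. Simulated
maps default to 3.5 Å voxels, with a margin of 2 × resolution around the
structure when no target geometry is given so tails are not clipped; when a
target grid is supplied the probe is laid on exactly that geometry so the
two maps align voxel-by-voxel.

Map I/O is MRC2014/CCP4 through gemmi, with axis order normalized on read.
The origin convention is the Å position of the centre of voxel (0,0,0),
taken from the MRC ORIGIN header words, falling back to NXSTART × voxel.
Voxel sizes must be isotropic within 1% (then averaged).

## Fitness

F = n·MI − PS for an n-component assembly.

**Mutual information.** Probe and target densities are each divided into 20
equal-width bins spanning that map's own [min, max]; the joint histogram is
accumulated over *all* aligned voxels and MI = Σ p(x,y) log p(x,y)/(p(x)p(y))
in natural log units, with 0·log 0 := 0. Per-map (rather than joint) bin
ranges and the all-voxel domain are deliberate: they make the score
well-defined for any pair of aligned grids without a density floor, and MI
is then invariant under any affine rescaling of either map. A constant map
collapses to a single occupied bin and contributes zero information. The
probe is simulated at the target's nominal resolution — the choice that
makes the native model's MI maximal by construction.

**Clash penalty.** Each component's backbone (N, CA, C, O) and Cβ atoms are
voxelized on one shared 3.5 Å lattice whose origin is snapped to a multiple
of the voxel size (a common lattice is required for voxel-level
intersection, and snapping removes dependence on the bounding box). For
every unordered pair, the fraction |occ_i ∩ occ_j| / (|occ_i| + |occ_j|) is
accumulated, so two fully superposed identical components score 0.5 and
three score 1.5. Mild contact overlaps cost little; severe interpenetration
dominates the fitness. PS is invariant to global rigid motion only up to
voxel-discretization jitter; the jitter shrinks as the lattice is refined,
and the tests check exactly that.

The GA's inner evaluator computes the identical quantities with cached
rotation matrices, a precomputed target bin assignment and a separable
Gaussian splat; its agreement with the reference `fitness()` path is
asserted in the tests rather than assumed.

## Feature points

K feature points (K = component count) seed the search. A single neural-gas
vector-quantization run is performed on the voxel centres above
mean + 2σ density, sampled with probability proportional to density.
Schedules use the standard neural-gas settings for map quantization:
10,000·K samples, learning rate 0.1 → 0.001 and neighbourhood range
K/2 → 0.01, both interpolated exponentially; the codebook is initialized by
density-proportional sampling of above-threshold voxel centres. Runs are
seed-deterministic; real VQ implementations show up to ~3 Å run-to-run point
variability, which is adopted as the tolerance when checking recovered blob
centres. Externally computed points (e.g. from a Gaussian-mixture fit) can
be supplied as a plain-text file and used in place of VQ. Point-set quality
is measured by the Hausdorff distance to the native component centroids;
seeds within ~5 Å of the centroids put the GA in its reliable recovery
regime.

## Genetic algorithm

Defaults: population 160, 100 generations, 20 independent runs, 5,000
quaternions. Seeding places every component on a uniformly chosen feature
point (with replacement — components may collide); half the population
additionally displaces each component by a random vector with length uniform
in [0, 2 × minimum pairwise feature-point distance]. Rotations are uniform
draws from the library.

Per generation, 90% of children come from crossover: two parents are chosen
by independent size-2 tournaments (drawn without replacement); the child
copies the fitter parent, then each gene independently crosses over to the
other parent's value with probability 0.8, and every crossed-over gene is
mutated with the generation's mutation rate (linear 0.2 → 0.01 across
generations). The per-gene reading of the 0.8 probability, and mutation
following only crossed-over genes, are deliberate interpretations of the
operator description; they keep crossover and mutation coupled the way the
operator intends. Translation mutations add a vector with length uniform in
[0, minimum pairwise feature-point distance]; rotation mutations redraw the
index uniformly. The remaining 10% of children are diversity children: the
current fittest genotype with two random component gene-pairs swapped
(translation and rotation together), then every gene mutated at a constant
0.1. Children and parents are merged and the best N of 2N survive, ties
broken in favour of parents and then insertion order — fully deterministic,
and the best fitness trace is monotone by construction.

Degenerate cases: with a single feature point the minimum pairwise distance
is undefined and the mutation range falls back to the map resolution; with a
single component the diversity swap degenerates to a mutation-only copy.

Every run is reproducible from (config seed, run seed); the quaternion
library depends only on the config seed so all runs of an ensemble share
it. Per-generation records (best, mean, SD of population fitness) are kept
raw; min-max normalization for plotting is presentation-only.

## Assessment

- **TS**: component correct iff |COM_pred − COM_native| ≤ rgyr(native),
  boundary inclusive (fixed for determinism).
- **CPS**: translation = COM displacement; rotation = angle of the optimal
  least-squares (Kabsch) rotation between centred coordinate sets. APS is
  the plain average of CPS over components.
- **RMSD**: per-component Cα RMSD *in the map frame* — no re-superposition,
  because rigid components are conformationally identical and superposing
  would erase exactly the placement error being measured. For identical
  components (detected by identical Cα residue sequences, overridable), the
  correspondence minimizing the average RMSD is found by exhaustive
  permutation for groups of ≤ 6 and by optimal linear assignment above
  (exact, since the objective decomposes per pair). The RMSD-derived
  correspondence is resolved first and then applied consistently to TS and
  CPS, so relabelling identical chains cannot depress the other metrics.

## Synthetic fixtures

Toy components are compact self-avoiding pseudo-Cα walks (3.8 Å steps,
≥ 4 Å non-consecutive separation, centroid-biased for globularity) with
backbone N/C/O and Cβ synthesized at ideal offsets, so the clash grid sees
realistic occupancy. Default assemblies have three components of distinct
sizes (35–65 residues — distinct sizes give the goodness-of-fit term
leverage to assign components to density lobes), centroid separations
≥ 28 Å, a verified nearly clash-free native (PS < 0.05), and a 10 Å map on
3.5 Å voxels with a 10 Å margin. The fixtures emulate assembly geometry —
sizes, packing, blur — not real fold statistics, sidechain chemistry, or
experimental-map artifacts (noise, missing density, B-factor variation);
passing recovery tests therefore demonstrates the sampler and scores work
as designed, not performance on experimental data.

## Problem sizes used in tests and the acceptance script

The recovery experiment runs one ensemble of 5 GA runs at population 40 and
30 generations on the three-component 10 Å fixture, seeded on native
centroids — a deliberately scaled-down analogue of the full operating point
(20 runs × 160 × 100) that preserves every mechanism while completing in
about a minute. Under these conditions the highest-scoring model reliably
recovers the native topology (TS = 1); individual runs occasionally
converge to a wrong component assignment, which is expected GA behaviour at
reduced population size, so the per-run success criterion is ≥ 4 of 5 runs
rather than all of them. Statistical operator checks (tournament-selection
frequencies, mutation-index uniformity) use 10,000 draws with 4σ binomial
envelopes; quaternion-uniformity checks use thousands of rotation pairs
against the analytic SO(3) angle density (1 − cos θ)/π, whose mean
(π/2 + 2/π rad ≈ 126.48°) is the reference for the mean pairwise angle.

## Known limitations

- No symmetry restraints, flexibility, or partial fitting.
- Feature-point quality bounds achievable accuracy; elongated or tightly
  packed components can defeat VQ, and then the GA inherits the bias.
- The clash penalty is voxel-based and element-agnostic: it penalizes
  volume interpenetration, not atomic physics.
- MI uses fixed 20-bin equal-width histograms; very small grids populate
  the joint table sparsely and the score becomes noisy.
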