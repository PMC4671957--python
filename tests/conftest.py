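import numpy as np
import pytest

import emgafit as eg
from emgafit.ga import FitnessBreakdown, GAConfig, GAContext, Genotype
from emgafit.structio import QuaternionSet


@pytest.fixture(scope="session")
def toy_assembly() -> eg.FixtureAssembly:
    """Three-component toy assembly with a 10 Å simulated map."""
    return eg.make_assembly(eg.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def small_quats() -> QuaternionSet:
    return eg.generate_quaternion_set(64, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def cheap_context(n_components: int = 3, quats: QuaternionSet | None = None,
                  order_invariant: bool = True) -> GAContext:
    """A GAContext with an analytic fitness for operator-level GA tests.

    Fitness rewards translations close to the origin; with
    ``order_invariant`` it depends only on the multiset of genes, so a
    diversity swap is fitness-neutral.
    """
    quats = quats or eg.generate_quaternion_set(16, seed=0)

    def evaluate(g: Genotype) -> FitnessBreakdown:
        mi = -float(np.sum(g.translations ** 2)) / g.n
        return FitnessBreakdown(mi=mi, ps=0.0, n=g.n)

    points = eg.PointSet(np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                                   [0.0, 12.0, 0.0]]))
    return GAContext(
        components=[None] * n_components,  # operators never touch components
        quats=quats,
        points=points,
        map_center=np.zeros(3),
        mutation_range=5.0,
        evaluate=evaluate,
    )


def random_genotype(n: int, quats: QuaternionSet, rng: np.random.Generator) -> Genotype:
    return Genotype(rng.normal(scale=8.0, size=(n, 3)),
                    rng.integers(0, quats.size, size=n))
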