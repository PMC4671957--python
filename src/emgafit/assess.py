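"""Accuracy of a predicted assembly against a native reference.

Three complementary metrics:

* Topology Score (TS) — the fraction of components whose predicted centre of
  mass falls inside a sphere centred on the native centre of mass with radius
  equal to the native component's radius of gyration.
* Component / Assembly Placement Score (CPS / APS) — the translation (Å) and
  rotation angle (°) needed to superpose each predicted component onto its
  native counterpart; APS averages the CPS over components.
* Cα RMSD — per-component RMSD in the common map frame (no re-superposition:
  components are rigid, so superposing would erase exactly the placement
  error being measured), averaged over components, minimized over
  correspondences within groups of identical components.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .structio import AssemblyModel, Component

__all__ = [
    "PlacementScore",
    "AssessmentReport",
    "identical_groups",
    "topology_score",
    "component_placement_score",
    "assembly_placement_score",
    "assembly_rmsd",
    "assess",
]


@dataclasses.dataclass(frozen=True)
class PlacementScore:
    """Translation (Å) and rotation angle (degrees, in [0, 180])."""

    translation: float
    rotation: float

    def __post_init__(self) -> None:
        if self.translation < 0 or not (0.0 <= self.rotation <= 180.0 + 1e-9):
            raise ValueError("invalid placement score")


@dataclasses.dataclass
class AssessmentReport:
    ts: float
    aps: PlacementScore
    per_component_cps: list[PlacementScore]
    rmsd: float
    correspondence: list[int]  # correspondence[i] = native index matched to pred i


def identical_groups(components: Sequence[Component]) -> list[list[int]]:
    """Partition component indices into groups with identical Cα sequences."""
    groups: dict[tuple, list[int]] = {}
    for i, c in enumerate(components):
        key = (len(c.calpha_coords), c.sequence)
        groups.setdefault(key, []).append(i)
    return list(groups.values())


def _placed(model: AssemblyModel | Sequence[Component]) -> list[Component]:
    return model.placed() if isinstance(model, AssemblyModel) else list(model)


def topology_score(
    pred: AssemblyModel | Sequence[Component],
    native: AssemblyModel | Sequence[Component],
    correspondence: Sequence[int] | None = None,
) -> float:
    """Fraction of components placed correctly.

    Component ``i`` counts as correct iff its predicted centre of mass lies
    within (inclusive) the native component's radius of gyration of the
    native centre of mass.
    """
    p = _placed(pred)
    n = _placed(native)
    if len(p) != len(n):
        raise ValueError("component counts differ")
    if correspondence is None:
        correspondence = range(len(p))
    correct = 0
    for i, j in enumerate(correspondence):
        if np.linalg.norm(p[i].com - n[j].com) <= n[j].rgyr:
            correct += 1
    return correct / len(p)


def component_placement_score(pred_c: Component, native_c: Component) -> PlacementScore:
    """Translation and rotation needed to superpose predicted onto native.

    Translation is the centre-of-mass displacement; rotation is the angle of
    the optimal least-squares (Kabsch) rotation aligning the centred
    predicted coordinates onto the centred native coordinates.
    """
    if len(pred_c.coords) != len(native_c.coords):
        raise ValueError("atom counts differ between predicted and native component")
    translation = float(np.linalg.norm(pred_c.com - native_c.com))
    a = pred_c.coords - pred_c.com
    b = native_c.coords - native_c.com
    rot, _ = Rotation.align_vectors(b, a)
    angle = float(np.degrees(rot.magnitude()))
    return PlacementScore(translation, min(angle, 180.0))


def assembly_placement_score(per_component: Sequence[PlacementScore]) -> PlacementScore:
    """APS: arithmetic mean of the component translations and rotations."""
    if len(per_component) == 0:
        raise ValueError("need at least one component placement score")
    return PlacementScore(
        float(np.mean([c.translation for c in per_component])),
        float(np.mean([c.rotation for c in per_component])),
    )


def _ca_rmsd(pred_c: Component, native_c: Component) -> float:
    a = pred_c.calpha_coords
    b = native_c.calpha_coords
    if a.shape != b.shape:
        raise ValueError(
            f"Cα count mismatch: {a.shape[0]} vs {b.shape[0]} "
            f"({pred_c.id!r} vs {native_c.id!r})"
        )
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


_EXHAUSTIVE_LIMIT = 6  # brute-force permutations up to this group size


def assembly_rmsd(
    pred: AssemblyModel | Sequence[Component],
    native: AssemblyModel | Sequence[Component],
    groups: Sequence[Sequence[int]] | None = None,
) -> tuple[float, list[int]]:
    """Average per-component Cα RMSD in the map frame, with the
    correspondence within each identical-component group chosen to minimize
    it.  Returns (RMSD, correspondence) where correspondence[i] is the native
    index assigned to predicted component i.

    Groups of ≤ 6 identical components are matched by exhaustive permutation;
    larger groups by optimal linear assignment on the pairwise RMSD matrix
    (exact for this objective, which is a sum of per-pair terms).
    """
    p = _placed(pred)
    nat = _placed(native)
    if len(p) != len(nat):
        raise ValueError("component counts differ")
    if groups is None:
        groups = identical_groups(nat)
    correspondence = list(range(len(p)))
    total = 0.0
    for group in groups:
        group = list(group)
        if len(group) == 1:
            total += _ca_rmsd(p[group[0]], nat[group[0]])
            continue
        mat = np.array([[_ca_rmsd(p[i], nat[j]) for j in group] for i in group])
        if len(group) <= _EXHAUSTIVE_LIMIT:
            best_perm, best_cost = None, np.inf
            for perm in itertools.permutations(range(len(group))):
                cost = sum(mat[r, perm[r]] for r in range(len(group)))
                if cost < best_cost:
                    best_cost, best_perm = cost, perm
            rows = range(len(group))
            cols = best_perm
        else:
            rows, cols = linear_sum_assignment(mat)
            best_cost = mat[rows, cols].sum()
        for r, c in zip(rows, cols):
            correspondence[group[r]] = group[c]
        total += float(best_cost)
    return total / len(p), correspondence


def assess(
    pred: AssemblyModel | Sequence[Component],
    native: AssemblyModel | Sequence[Component],
    groups: Sequence[Sequence[int]] | None = None,
) -> AssessmentReport:
    """Full report: the RMSD-minimizing correspondence is resolved first and
    then applied consistently to TS and CPS."""
    p = _placed(pred)
    nat = _placed(native)
    rmsd, corr = assembly_rmsd(p, nat, groups)
    ts = topology_score(p, nat, corr)
    cps = [component_placement_score(p[i], nat[j]) for i, j in enumerate(corr)]
    aps = assembly_placement_score(cps)
    return AssessmentReport(ts=ts, aps=aps, per_component_cps=cps, rmsd=rmsd,
                            correspondence=corr)
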