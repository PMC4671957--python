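"""Atomic structures as rigid bodies: PDB I/O, rigid transforms, rotation libraries.

A :class:`Component` is one rigid body of an assembly (typically one polymer
chain).  Candidate assembly configurations move components around by
:class:`RigidTransform`; rotations are always applied about the component
centroid so that the rotational and translational degrees of freedom stay
decoupled.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Component",
    "RigidTransform",
    "QuaternionSet",
    "AssemblyModel",
    "read_components",
    "write_assembly_pdb",
    "apply_transform",
    "generate_quaternion_set",
]

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "CB"})


@dataclasses.dataclass
class Component:
    """One rigid body: parallel per-atom arrays plus derived geometry.

    ``coords`` holds all heavy-atom positions in Å.  ``atom_names``,
    ``res_ids`` and ``res_names`` are parallel to it.  Hydrogens, HETATM
    records and alternate locations are dropped on read.
    """

    id: str
    atom_names: Sequence[str]
    res_ids: np.ndarray
    res_names: Sequence[str]
    elements: Sequence[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.atom_names) != len(self.coords):
            raise ValueError("atom_names and coords length mismatch")

    # -- derived geometry ---------------------------------------------------

    @property
    def calpha_mask(self) -> np.ndarray:
        return np.asarray([n == "CA" for n in self.atom_names], dtype=bool)

    @property
    def calpha_coords(self) -> np.ndarray:
        """Ordered Cα coordinates (falls back to all atoms for non-protein chains)."""
        mask = self.calpha_mask
        if not mask.any():
            return self.coords
        return self.coords[mask]

    @property
    def backbone_cb_mask(self) -> np.ndarray:
        mask = np.asarray([n in _BACKBONE_NAMES for n in self.atom_names], dtype=bool)
        if not mask.any():
            # generic (non-protein) chain: every heavy atom counts as backbone
            mask = np.ones(len(self.coords), dtype=bool)
        return mask

    @property
    def backbone_cb_coords(self) -> np.ndarray:
        """Coordinates of backbone (N, CA, C, O) and Cβ atoms."""
        return self.coords[self.backbone_cb_mask]

    @property
    def com(self) -> np.ndarray:
        """Unweighted centroid of all atoms in Å."""
        return self.coords.mean(axis=0)

    @property
    def rgyr(self) -> float:
        """Radius of gyration about the centroid, Å (unweighted)."""
        d2 = ((self.coords - self.com) ** 2).sum(axis=1)
        return float(np.sqrt(d2.mean()))

    @property
    def sequence(self) -> tuple[str, ...]:
        """Residue-name sequence at Cα positions; used to detect identical chains."""
        mask = self.calpha_mask
        if not mask.any():
            return tuple(self.res_names)
        return tuple(rn for rn, m in zip(self.res_names, mask) if m)

    def with_coords(self, coords: np.ndarray) -> "Component":
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float))


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Rotation (unit quaternion, scalar-first ``(w, x, y, z)``) + translation (Å).

    The rotation acts about the component centroid; the translation then
    shifts the centroid.
    """

    rotation: tuple[float, float, float, float]
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        q = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("rotation quaternion must have unit norm")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls((1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0))

    @classmethod
    def from_rotation(cls, rot: Rotation, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        x, y, z, w = rot.as_quat()
        return cls((w, x, y, z), tuple(float(v) for v in translation))

    def as_rotation(self) -> Rotation:
        w, x, y, z = self.rotation
        return Rotation.from_quat([x, y, z, w])

    def inverse_about_centroid(self) -> "RigidTransform":
        """Inverse for the rotate-about-centroid-then-translate convention."""
        inv = self.as_rotation().inv()
        t = -np.asarray(self.translation, dtype=float)
        return RigidTransform.from_rotation(inv, tuple(t))


@dataclasses.dataclass(frozen=True)
class QuaternionSet:
    """An indexed library of unit quaternions approximately uniform on SO(3)."""

    quaternions: np.ndarray  # (n, 4) scalar-first

    @property
    def size(self) -> int:
        return len(self.quaternions)

    def rotation(self, index: int) -> Rotation:
        w, x, y, z = self.quaternions[index]
        return Rotation.from_quat([x, y, z, w])

    def rotations(self) -> Rotation:
        q = self.quaternions
        return Rotation.from_quat(np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))


@dataclasses.dataclass
class AssemblyModel:
    """Components plus the rigid transforms placing them; the unit that is scored."""

    components: list[Component]
    transforms: list[RigidTransform]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.transforms):
            raise ValueError("one transform per component required")

    @property
    def n(self) -> int:
        return len(self.components)

    def placed(self) -> list[Component]:
        return [apply_transform(c, t) for c, t in zip(self.components, self.transforms)]

    @classmethod
    def from_placed(cls, components: Iterable[Component]) -> "AssemblyModel":
        comps = list(components)
        return cls(comps, [RigidTransform.identity()] * len(comps))


def _chain_to_component(chain: gemmi.Chain, label: str) -> Component:
    names, res_ids, res_names, elements, xyz = [], [], [], [], []
    for res_idx, res in enumerate(chain):
        seen: set[str] = set()
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            if atom.name in seen:  # altloc duplicate
                continue
            seen.add(atom.name)
            names.append(atom.name)
            res_ids.append(res_idx)
            res_names.append(res.name)
            elements.append(atom.element.name)
            xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not xyz:
        raise ValueError(f"chain {label!r} has no heavy atoms")
    comp = Component(label, names, np.asarray(res_ids), res_names, elements, np.asarray(xyz))
    return comp


def read_components(
    path_or_paths: str | Path | Sequence[str | Path],
    split_mode: str = "per-chain",
) -> list[Component]:
    """Read assembly components from PDB file(s).

    Parameters
    ----------
    path_or_paths
        One file or a sequence of files (ATOM records; first MODEL only).
    split_mode
        ``"per-chain"``: one component per polymer chain; ``"per-file"``:
        all chains of a file merged into one component.

    Components are ordered by file order, then chain ID.  Protein chains must
    contain at least one Cα atom; chains without any CA atom are treated as
    generic rigid bodies (all heavy atoms used as the clash set).
    """
    if split_mode not in ("per-chain", "per-file"):
        raise ValueError(f"unknown split_mode {split_mode!r}")
    if isinstance(path_or_paths, (str, Path)):
        paths = [Path(path_or_paths)]
    else:
        paths = [Path(p) for p in path_or_paths]

    components: list[Component] = []
    for path in paths:
        if not path.exists():
            raise FileNotFoundError(f"cannot read structure file: {path}")
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as exc:
            raise IOError(f"failed to parse {path}: {exc}") from exc
        st.setup_entities()
        if len(st) == 0:
            raise ValueError(f"{path}: no models found")
        model = st[0]
        chains = sorted(model, key=lambda ch: ch.name)
        if split_mode == "per-chain":
            for chain in chains:
                comp = _chain_to_component(chain, chain.name)
                components.append(comp)
        else:
            merged: Component | None = None
            parts = [_chain_to_component(ch, ch.name) for ch in chains]
            if not parts:
                raise ValueError(f"{path}: no chains found")
            names = [n for p in parts for n in p.atom_names]
            res_off, res_ids, res_names, elements = 0, [], [], []
            coords = []
            for p in parts:
                res_ids.extend((p.res_ids + res_off).tolist())
                res_off += int(p.res_ids.max()) + 1 if len(p.res_ids) else 0
                res_names.extend(p.res_names)
                elements.extend(p.elements)
                coords.append(p.coords)
            merged = Component(path.stem, names, np.asarray(res_ids), res_names,
                               elements, np.vstack(coords))
            components.append(merged)
    return components


def write_assembly_pdb(components: Sequence[Component], path: str | Path) -> None:
    """Write placed components as one PDB file, one chain per component."""
    st = gemmi.Structure()
    st.name = "assembly"
    model = gemmi.Model("1")
    used: set[str] = set()
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
    for comp in components:
        cid = comp.id if comp.id and comp.id not in used else next(
            ch for ch in alphabet if ch not in used)
        used.add(cid)
        chain = gemmi.Chain(cid[:1] if len(cid) > 1 else cid)
        cur_res_id = None
        res = None
        for name, rid, rname, elem, xyz in zip(
            comp.atom_names, comp.res_ids, comp.res_names, comp.elements, comp.coords
        ):
            if rid != cur_res_id:
                res = gemmi.Residue()
                res.name = rname
                res.seqid = gemmi.SeqId(int(rid) + 1, " ")
                chain.add_residue(res)
                cur_res_id = rid
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*map(float, xyz))
            chain[-1].add_atom(atom)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def apply_transform(c: Component, t: RigidTransform) -> Component:
    """Rotate ``c`` about its centroid by ``t.rotation``, then translate.

    The centroid of the result is ``c.com + t.translation``; the radius of
    gyration is preserved (rigid motion).
    """
    com = c.com
    rot = t.as_rotation()
    new_coords = rot.apply(c.coords - com) + com + np.asarray(t.translation, dtype=float)
    return c.with_coords(new_coords)


def generate_quaternion_set(n: int = 5000, seed: int = 0) -> QuaternionSet:
    """Sample ``n`` quaternions uniformly on SO(3), reproducibly for a seed.

    The default library size of 5000 discretizes orientation space finely
    enough that the rotation gene behaves as a near-continuous variable.
    """
    if n < 1:
        raise ValueError("quaternion set size must be >= 1")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n, rng=rng)
    q_xyzw = np.atleast_2d(rots.as_quat())
    q = np.column_stack([q_xyzw[:, 3], q_xyzw[:, 0], q_xyzw[:, 1], q_xyzw[:, 2]])
    return QuaternionSet(q)
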