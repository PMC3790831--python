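"""Molecular structures, atomic solvation parameters and rigid transforms.

The docking engine works on a deliberately small structure model: heavy
atoms with coordinates, van der Waals radii and a per-atom atomic
solvation parameter (ASP).  ASP values relate buried solvent-accessible
area to solvation free energy and are negative by convention, so that the
product of two ASP values in the correlation score rewards surface
burial.  PDB input goes through :mod:`gemmi`; only the first model is
read, hydrogens, waters and HETATM records are dropped, and alternate
locations other than '' / 'A' are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ParseError, SoftDockError, TypingError

#: residue identifier: (chain id, residue number, insertion code)
ResidueId = tuple[str, int, str]

_DATA = resources.files("softdock") / "data"


# ---------------------------------------------------------------------------
# atoms and structures


@dataclass(frozen=True)
class Atom:
    """A heavy atom with coordinates, radius and optional ASP value."""

    serial: int
    name: str
    element: str
    resname: str
    residue_id: ResidueId
    coord: tuple[float, float, float]
    vdw_radius: float
    asp: float | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coord):
            raise SoftDockError(f"atom {self.serial} has non-finite coordinates")
        if self.vdw_radius <= 0:
            raise SoftDockError(f"atom {self.serial} has non-positive radius")
        if self.asp is not None and self.asp >= 0:
            raise SoftDockError(
                f"atom {self.serial}: ASP value must be negative, got {self.asp}"
            )


class Structure:
    """An ordered collection of atoms grouped into residues and chains."""

    def __init__(self, atoms: Sequence[Atom], id: str = "") -> None:
        atoms = list(atoms)
        if not atoms:
            raise SoftDockError("structure must contain at least one atom")
        seen: set[tuple] = set()
        for a in atoms:
            key = (*a.residue_id, a.name)
            if key in seen:
                raise SoftDockError(f"duplicate atom {key} in structure {id!r}")
            seen.add(key)
        self.atoms: list[Atom] = atoms
        self.id = id

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<Structure {self.id!r}: {len(self)} atoms, chains {sorted(self.chains)}>"

    # -- array views ---------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def asp_values(self) -> np.ndarray:
        vals = [a.asp for a in self.atoms]
        if any(v is None for v in vals):
            raise SoftDockError(
                f"structure {self.id!r} has atoms without assigned ASP values"
            )
        return np.array(vals, dtype=float)

    @property
    def chains(self) -> set[str]:
        return {a.residue_id[0] for a in self.atoms}

    def residues(self) -> list[ResidueId]:
        """Residue ids in order of first appearance."""
        out: list[ResidueId] = []
        seen: set[ResidueId] = set()
        for a in self.atoms:
            if a.residue_id not in seen:
                seen.add(a.residue_id)
                out.append(a.residue_id)
        return out

    def residue_names(self) -> dict[ResidueId, str]:
        return {a.residue_id: a.resname for a in self.atoms}

    def atoms_by_residue(self) -> dict[ResidueId, list[int]]:
        out: dict[ResidueId, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_id, []).append(i)
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise SoftDockError("coordinate array shape mismatch")
        atoms = [
            replace(a, coord=tuple(c)) for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, id=self.id)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def select_atoms(self, names: Iterable[str]) -> "Structure":
        names = set(names)
        return Structure([a for a in self.atoms if a.name in names], id=self.id)

    def select_chains(self, chains: Iterable[str]) -> "Structure":
        chains = set(chains)
        atoms = [a for a in self.atoms if a.residue_id[0] in chains]
        if not atoms:
            raise SoftDockError(f"no atoms in chains {sorted(chains)}")
        return Structure(atoms, id=self.id)


def merge(a: Structure, b: Structure, id: str = "") -> Structure:
    """Concatenate two structures (e.g. receptor + posed ligand)."""
    return Structure(a.atoms + b.atoms, id=id or f"{a.id}+{b.id}")


# ---------------------------------------------------------------------------
# ASP parameter tables


class ASPTable:
    """Atom-type -> ASP value mapping plus van der Waals radii.

    The default typing rule keys on the element class {C, N, O, S,
    other}.  All ASP values must be strictly negative.  The bundled
    default magnitudes are placeholders chosen for testing, not a
    published solvation parameter set; substitute your own table via
    :meth:`from_yaml` for production scoring.
    """

    def __init__(
        self, asp: Mapping[str, float], vdw: Mapping[str, float]
    ) -> None:
        for key, val in asp.items():
            if val >= 0:
                raise SoftDockError(
                    f"ASP value for type {key!r} must be negative, got {val}"
                )
        if "other" not in vdw:
            raise SoftDockError("radius table must provide an 'other' fallback")
        self.asp = dict(asp)
        self.vdw = dict(vdw)

    def type_of(self, element: str) -> str:
        """Atom-type key for an element; raises TypingError if untypable."""
        el = element.upper()
        if el in self.asp:
            return el
        if "other" in self.asp:
            return "other"
        raise TypingError(f"element {el!r} has no ASP type and no 'other' fallback")

    def asp_of(self, element: str) -> float:
        return self.asp[self.type_of(element)]

    def radius_of(self, element: str) -> float:
        el = element.upper()
        return self.vdw.get(el, self.vdw["other"])

    @classmethod
    def from_yaml(cls, path) -> "ASPTable":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        try:
            return cls(cfg["asp"], cfg["vdw"])
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed ASP table config {path}: {exc}") from exc

    @classmethod
    def default(cls) -> "ASPTable":
        cfg = yaml.safe_load((_DATA / "asp_default.yaml").read_text())
        return cls(cfg["asp"], cfg["vdw"])


def assign_asp(s: Structure, table: ASPTable | None = None) -> Structure:
    """Return a copy of *s* with per-atom ASP values from *table*.

    Idempotent: reassigning with the same table yields the same values.
    """
    table = table or ASPTable.default()
    atoms = []
    for a in s.atoms:
        try:
            value = table.asp_of(a.element)
        except TypingError as exc:
            raise TypingError(
                f"atom {a.serial} ({a.name} {a.residue_id}): {exc}"
            ) from exc
        atoms.append(replace(a, asp=value))
    return Structure(atoms, id=s.id)


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(path, id: str | None = None, table: ASPTable | None = None) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    Keeps heavy atoms of ATOM records with altloc '' or 'A'; drops
    hydrogens, deuteriums, waters and HETATM records.  Radii are taken
    from *table* (default table if None); ASP values are left unassigned.
    """
    table = table or ASPTable.default()
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in PDB file {path}")
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            if res.het_flag != "A":  # skip HETATM (incl. waters)
                continue
            for at in res:
                el = at.element.name
                if el in ("H", "D"):
                    continue
                if at.altloc not in ("\0", "", "A"):
                    continue
                serial += 1
                icode = res.seqid.icode.strip()
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=el,
                        resname=res.name,
                        residue_id=(chain.name, res.seqid.num, icode),
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        vdw_radius=table.radius_of(el),
                    )
                )
    if not atoms:
        raise ParseError(f"no ATOM records found in {path}")
    return Structure(atoms, id=id if id is not None else st.name or str(path))


def write_pdb(s: Structure, path) -> None:
    """Write *s* as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = s.id or "softdock"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, tuple] = {}
    for a in s.atoms:
        chain_id, resnum, icode = a.residue_id
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        chain = chains[chain_id]
        if current.get(chain_id) != (resnum, icode):
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            res.het_flag = "A"
            chain.add_residue(res)
            current[chain_id] = (resnum, icode)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coord)
        at.occ = 1.0
        at.b_iso = 0.0
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    s: Structure, probe: float = 1.4, n_sphere_points: int = 960
) -> tuple[np.ndarray, dict[ResidueId, float]]:
    """Shrake-Rupley SASA.

    Returns ``(per_atom, per_residue)`` areas in squared angstroms.  Each
    atom is expanded by the probe radius; test points on its expanded
    sphere count as accessible when outside every neighbour's expanded
    sphere.  Deterministic for a fixed ``n_sphere_points``.
    """
    coords = s.coords
    radii = s.radii + probe
    pts = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(len(s))
    max_r = radii.max()
    for i in range(len(s)):
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        sphere = coords[i] + radii[i] * pts
        if neigh:
            d2 = np.sum(
                (sphere[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=-1
            )
            buried = (d2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_sphere_points
        per_atom[i] = 4.0 * math.pi * radii[i] ** 2 * n_acc / n_sphere_points
    per_res: dict[ResidueId, float] = {}
    for a, area in zip(s.atoms, per_atom):
        per_res[a.residue_id] = per_res.get(a.residue_id, 0.0) + float(area)
    return per_atom, per_res


def load_reference_areas() -> dict[str, float]:
    """Maximal per-residue solvent accessibilities (theoretical Gly-X-Gly)."""
    return dict(yaml.safe_load((_DATA / "residue_max_asa.yaml").read_text()))


def surface_residues(
    s: Structure,
    threshold: float = 0.10,
    reference_areas: Mapping[str, float] | None = None,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> set[ResidueId]:
    """Residues with relative solvent accessibility strictly above *threshold*.

    Relative accessibility is the residue SASA divided by a per-residue-type
    reference maximum.  A residue sitting exactly at the threshold is
    excluded ("more than" is read strictly).
    """
    refs = dict(reference_areas) if reference_areas is not None else load_reference_areas()
    names = s.residue_names()
    _, per_res = compute_sasa(s, probe=probe, n_sphere_points=n_sphere_points)
    out: set[ResidueId] = set()
    for rid, area in per_res.items():
        resname = names[rid]
        if resname not in refs:
            raise SoftDockError(
                f"no reference accessibility for residue type {resname!r}"
            )
        if area / refs[resname] > threshold:
            out.add(rid)
    return out


# ---------------------------------------------------------------------------
# rigid transforms


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise SoftDockError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise SoftDockError("rotation matrix is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation(
        cls, rot: Rotation, center: np.ndarray | None = None
    ) -> "RigidTransform":
        """Rotation about *center* (origin if None)."""
        R = rot.as_matrix()
        if center is None:
            return cls(R, np.zeros(3))
        c = np.asarray(center, dtype=float)
        return cls(R, c - R @ c)

    def as_quaternion(self) -> np.ndarray:
        """Scalar-first unit quaternion (w, x, y, z) with w >= 0."""
        q = Rotation.from_matrix(self.rotation).as_quat()  # x,y,z,w
        q = np.array([q[3], q[0], q[1], q[2]])
        return q if q[0] >= 0 else -q

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform 'self after other'."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))


def apply_transform(s: Structure, x: RigidTransform) -> Structure:
    """Apply a rigid transform to every atom of *s*."""
    return s.with_coords(x.apply(s.coords))
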