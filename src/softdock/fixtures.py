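"""Deterministic synthetic toy complexes for docking and evaluation tests.

A toy complex is a pair of complementary rigid pseudo-proteins with one
carbon pseudo-atom per residue: the receptor is a solid quasi-spherical
blob with a concave pocket carved out of its surface, and the ligand is
a compact knob seated in that pocket in the (known) native pose.  The
construction keeps exhaustive direct-scan score oracles tractable while
still producing buried core cells on a 1 angstrom grid, so the overlap
penalty is active exactly as for real proteins.

Residue labels follow the standard docking evaluation definitions:
*true interface* residues are computed with the same surface (>10%
relative accessibility) and distance (<5 A) rules used for real
complexes, which makes the fixtures self-consistent with the evaluation
module by construction.

What these fixtures do not emulate: side-chain chemistry, heterogeneous
atom types, backbone connectivity, and conformational change on
binding.  Their role is to make the engine's contracts (score
complementarity, restraint behaviour, evaluation geometry) testable
without any downloaded structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SoftDockError
from .evaluation import interface_residues
from .grid import core_overlap_cells, project
from .srm import DEFAULT_ALPHA, KeyResidueSet
from .structure import (
    ASPTable,
    Atom,
    ResidueId,
    RigidTransform,
    Structure,
    assign_asp,
    surface_residues,
)

_PSEUDO_RADIUS = 1.7  # carbon vdW, matches the default table
_PROBE = 1.4
#: reference accessibility of an isolated pseudo-residue: free-sphere area
PSEUDO_REFERENCE_AREAS = {
    "UNK": 4.0 * math.pi * (_PSEUDO_RADIUS + _PROBE) ** 2
}
_LATTICE = 1.9  # pseudo-atom packing distance, A (solid blob at r_vdw 1.7)
_CONTACT_GAP = 3.5  # closest receptor-ligand center distance in native pose
_JITTER = 0.1  # per-coordinate seed jitter, A


def _lattice_points(extent: int = 7) -> np.ndarray:
    """Cubic lattice points sorted by distance from the origin (stable)."""
    r = np.arange(-extent, extent + 1)
    pts = np.array(np.meshgrid(r, r, r, indexing="ij")).reshape(3, -1).T * _LATTICE
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.linalg.norm(pts, axis=1)))
    return pts[order]


#: knob footprint: an L with strongly unequal arms (7 and 3 columns,
#: ~13 vs ~6 A), asymmetric at a scale the ~3.5 A carve dilation cannot
#: blur; no in-plane lattice rotation or flip maps it onto itself
_KNOB_FOOTPRINT = [(i, 0) for i in range(7)] + [(0, j) for j in range(1, 4)]


def _grow_cluster(rng: np.random.Generator, n: int) -> np.ndarray:
    """Asymmetric knob: a terraced L-prism with seeded jagged heights.

    Asymmetry matters: a symmetric knob admits rotated placements that
    fit the carved socket equally well, making the native pose
    ill-defined for ranking tests.  Three features rule out every
    non-identity lattice orientation *by hard clash*, not merely by
    contact loss: the unequal-armed L footprint (no in-plane rotation
    maps it onto itself), the two-level stepped bottom (the outer long
    arm sits two cells lower than the corner block, so any flip rams an
    arm into the terraced socket floor), and the seeded jagged top
    versus structured bottom (no upside-down fit).
    """
    if n < 21:
        raise SoftDockError("ligand cluster needs at least 21 residues")
    cols = list(_KNOB_FOOTPRINT)
    # outer long arm two cells lower than the corner block + short arm
    bottom = {c: (0 if c[0] >= 3 else 2) for c in cols}
    heights = {c: 2 for c in cols}
    heights[(3, 0)] = 3  # bridges the terrace step
    while sum(heights.values()) < n:
        open_cols = [c for c in cols if heights[c] < 5]
        if not open_cols:
            raise SoftDockError(f"knob footprint too small for {n} residues")
        heights[open_cols[int(rng.integers(len(open_cols)))]] += 1
    cells = [
        (x, y, z)
        for (x, y) in cols
        for z in range(bottom[(x, y)], bottom[(x, y)] + heights[(x, y)])
    ]
    coords = np.array(sorted(cells), dtype=float) * _LATTICE
    return coords - coords.mean(axis=0)


def _make_structure(
    coords: np.ndarray, chain: str, id: str, table: ASPTable
) -> Structure:
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element="C",
            resname="UNK",
            residue_id=(chain, i + 1, ""),
            coord=tuple(c),
            vdw_radius=table.radius_of("C"),
        )
        for i, c in enumerate(coords)
    ]
    return assign_asp(Structure(atoms, id=id), table)


@dataclass
class ToyComplex:
    """A synthetic complementary complex with known native pose."""

    receptor: Structure
    ligand: Structure  # already placed in the native pose
    native_transform: RigidTransform  # identity: ligand is built bound
    true_interface_r: set[ResidueId]
    true_interface_l: set[ResidueId]
    surface_r: set[ResidueId]
    surface_l: set[ResidueId]
    seed: int
    reference_areas: dict[str, float]


def make_toy_complex(
    seed: int,
    n_res_receptor: int = 420,
    n_res_ligand: int = 22,
    pocket_depth: float = 3.5,
) -> ToyComplex:
    """Build a socket-and-knob toy complex; deterministic per seed.

    The ligand is an asymmetric terraced L-knob of ``n_res_ligand``
    pseudo-atoms seated ``pocket_depth`` angstroms below the receptor's
    nominal surface radius.  The receptor consists of a snug crater
    wall traced around the knob (at the contact gap) plus a solid
    quasi-spherical blob of lattice points around the origin, using
    ``n_res_receptor`` sites in total — a concave socket that only the
    native knob orientation fits.  Both sides receive a small seeded
    jitter.  Construction invariants (zero core-core overlap at a 1 A
    grid; at least 10 receptor interface residues and 10 surface
    non-interface residues, so the standard 10-residue key-residue
    protocols always have material to sample) are verified; if the
    seeded jitter leaves an invariant unmet the jitter is re-derived
    deterministically, and persistent violations raise instead of
    returning a bad fixture.
    """
    if n_res_receptor < 8 or n_res_ligand < 8:
        raise SoftDockError("toy complexes need at least 8 residues per side")
    if pocket_depth <= 0:
        raise SoftDockError(f"pocket_depth must be positive, got {pocket_depth}")
    last_err = None
    for attempt in range(8):
        try:
            return _build_toy(seed, attempt, n_res_receptor, n_res_ligand, pocket_depth)
        except _RetryConstruction as exc:
            last_err = exc
    raise SoftDockError(
        f"toy complex seed {seed}: construction failed after 8 attempts ({last_err})"
    )


class _RetryConstruction(Exception):
    """Internal: seeded jitter produced a fixture violating an invariant."""


def _build_toy(
    seed: int,
    attempt: int,
    n_res_receptor: int,
    n_res_ligand: int,
    pocket_depth: float,
) -> ToyComplex:
    rng = np.random.default_rng((seed + 100_003 * attempt) % 2**31)
    table = ASPTable.default()
    pts = _lattice_points()

    lig_local = _grow_cluster(rng, n_res_ligand)
    half_height = -float(lig_local[:, 2].min())

    if len(pts) < 4 * n_res_receptor:
        raise SoftDockError("lattice extent too small for requested receptor size")
    r_rec = float(np.linalg.norm(pts[n_res_receptor - 1]))
    if pocket_depth >= r_rec:
        raise SoftDockError(
            f"pocket_depth {pocket_depth} exceeds receptor radius {r_rec:.1f}"
        )
    # seat the knob so its lowest atoms sit pocket_depth below the
    # receptor's nominal surface radius
    center_lig = np.array([0.0, 0.0, r_rec - pocket_depth + half_height])

    # carve the pocket: receptor avoids the ligand blob plus a contact gap
    lig_world = lig_local + center_lig
    d_to_lig = np.min(
        np.linalg.norm(pts[:, None, :] - lig_world[None, :, :], axis=-1),
        axis=1,
    )
    allowed = pts[d_to_lig >= _CONTACT_GAP]
    d_allowed = d_to_lig[d_to_lig >= _CONTACT_GAP]
    # crater wall: a snug shell of receptor sites around the knob, up to
    # its top layer, so the socket encloses the knob laterally whatever
    # the blob radius is; the lateral band is two layers thick so that
    # rotated (mis-fitting) knob placements clash into wall material
    # instead of draping over a thin rim
    z_top = lig_world[:, 2].max()
    z_bottom = lig_world[:, 2].min()
    below_top = allowed[:, 2] <= z_top
    wall_mask = (d_allowed <= _CONTACT_GAP + _LATTICE) & below_top
    lateral = (
        (d_allowed <= _CONTACT_GAP + 2.2 * _LATTICE)
        & below_top
        & (allowed[:, 2] >= z_bottom - 0.5 * _LATTICE)
    )
    wall_mask |= lateral
    wall = allowed[wall_mask]
    if len(wall) >= n_res_receptor:
        raise SoftDockError(
            f"n_res_receptor={n_res_receptor} too small: the pocket wall "
            f"alone needs {len(wall)} residues"
        )
    blob = allowed[~wall_mask]
    rec_coords = np.vstack([wall, blob[: n_res_receptor - len(wall)]])

    rec_coords = rec_coords + rng.uniform(-_JITTER, _JITTER, rec_coords.shape)
    lig_coords = (
        lig_local + center_lig + rng.uniform(-_JITTER, _JITTER, lig_local.shape)
    )

    receptor = _make_structure(rec_coords, "A", f"toy-receptor-{seed}", table)
    ligand = _make_structure(lig_coords, "B", f"toy-ligand-{seed}", table)

    refs = dict(PSEUDO_REFERENCE_AREAS)
    iface_r, iface_l = interface_residues(receptor, ligand, reference_areas=refs)
    surf_r = surface_residues(receptor, reference_areas=refs)
    surf_l = surface_residues(ligand, reference_areas=refs)
    if not iface_l or len(iface_r) < 10 or len(surf_r - iface_r) < 10:
        raise _RetryConstruction(
            f"interface material too thin ({len(iface_r)} receptor interface, "
            f"{len(surf_r - iface_r)} surface non-interface, "
            f"{len(iface_l)} ligand interface residues)"
        )
    # native pose must be clash-free at the docking grid resolution
    g_r = project(receptor, spacing=1.0)
    g_l = project(ligand, spacing=1.0)
    n_overlap = core_overlap_cells(g_r, g_l)
    if n_overlap > 0:
        raise _RetryConstruction(f"{n_overlap} core-core overlap cells in native pose")
    return ToyComplex(
        receptor=receptor,
        ligand=ligand,
        native_transform=RigidTransform.identity(),
        true_interface_r=iface_r,
        true_interface_l=iface_l,
        surface_r=surf_r,
        surface_l=surf_l,
        seed=seed,
        reference_areas=refs,
    )


def make_key_sets(
    t: ToyComplex,
    mode: str,
    n: int = 10,
    seed: int = 0,
    molecule: str = "receptor",
    alpha: float = DEFAULT_ALPHA,
) -> KeyResidueSet:
    """Sample a correct or wrong key-residue set from a toy complex.

    ``correct`` samples uniformly from the true interface of the chosen
    molecule; ``wrong`` samples from surface residues that are *not*
    interface residues, mirroring the wrong-information protocol of
    randomly picked surface non-interface residues.  Deterministic per
    seed; raises when fewer than *n* residues qualify.
    """
    if mode not in ("correct", "wrong"):
        raise SoftDockError(f"mode must be 'correct' or 'wrong', got {mode!r}")
    if molecule not in ("receptor", "ligand"):
        raise SoftDockError(f"molecule must be 'receptor' or 'ligand', got {molecule!r}")
    iface = t.true_interface_r if molecule == "receptor" else t.true_interface_l
    surf = t.surface_r if molecule == "receptor" else t.surface_l
    pool = sorted(iface) if mode == "correct" else sorted(surf - iface)
    if len(pool) < n:
        raise SoftDockError(
            f"cannot sample {n} {mode} residues from {molecule}: "
            f"only {len(pool)} qualify"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return KeyResidueSet(
        frozenset(pool[i] for i in chosen), alpha=alpha, label=mode
    )


def perturb_unbound(s: Structure, amplitude: float, seed: int = 0) -> Structure:
    """Jitter coordinates to emulate an unbound conformation.

    Adds independent uniform noise in [-amplitude, amplitude] per
    coordinate, so the unbound-bound RMSD lies in (0, 2 * amplitude]
    for positive amplitude.  Deterministic per seed.
    """
    if amplitude < 0:
        raise SoftDockError("amplitude must be non-negative")
    if amplitude == 0:
        return s
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-amplitude, amplitude, (len(s), 3))
    return s.with_coords(s.coords + noise)
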