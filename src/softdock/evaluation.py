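"""CAPRI-style evaluation of docking predictions.

Implements the standard sampling-stage bookkeeping: ligand RMSD after
receptor superposition (LRMSD), CAPRI quality classes, per-complex hit
statistics over a retained top-N list, interface/surface residue
definitions, binding-site prediction accuracy, unbound-bound RMSD and
relative interface area, plus benchmark-level summaries.

Boundary conventions: a hit is LRMSD <= cutoff (inclusive, default
10 A); an interface residue is a *surface* residue with minimum
inter-molecular atom distance strictly below 5 A; a surface residue has
relative accessibility strictly above 10%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import SoftDockError
from .structure import (
    ResidueId,
    RigidTransform,
    Structure,
    compute_sasa,
    merge,
    surface_residues,
)


# ---------------------------------------------------------------------------
# superposition and LRMSD


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of P onto Q (Kabsch).

    Returns the rigid transform minimizing RMSD(R P + t, Q) and that
    minimal RMSD.  Reflections are never returned, so a mirror image of
    a chiral point set keeps a positive RMSD.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SoftDockError(f"coordinate sets must both be (n, 3); got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise SoftDockError("superposition requires at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2:
        raise SoftDockError("degenerate (collinear) coordinate set")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    xform = RigidTransform(R, qc - R @ pc)
    rmsd = float(np.sqrt(np.mean(np.sum((xform.apply(P) - Q) ** 2, axis=1))))
    return xform, rmsd


def _matched_coords(
    a: Structure, b: Structure, names: set[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms shared by a and b, keyed by (residue_id, name)."""
    bmap = {
        (atom.residue_id, atom.name): atom.coord
        for atom in b.atoms
        if names is None or atom.name in names
    }
    pa, pb = [], []
    for atom in a.atoms:
        if names is not None and atom.name not in names:
            continue
        key = (atom.residue_id, atom.name)
        if key in bmap:
            pa.append(atom.coord)
            pb.append(bmap[key])
    return np.array(pa, dtype=float), np.array(pb, dtype=float)


def lrmsd(
    native_receptor: Structure,
    native_ligand: Structure,
    predicted_receptor: Structure,
    predicted_ligand: Structure,
    atom_selection: str = "heavy",
) -> float:
    """Ligand RMSD after superposing predicted onto native receptor.

    The receptors are superposed on CA atoms (all heavy atoms if no CA
    in common), the resulting transform is applied to the predicted
    ligand, and the RMSD over corresponding ligand atoms is returned.
    ``atom_selection`` is ``"heavy"`` (default) or ``"CA"`` for the
    ligand atom set.  Invariant under any global rigid motion of the
    predicted complex.
    """
    pr, nr = _matched_coords(predicted_receptor, native_receptor, {"CA"})
    if len(pr) < 3:
        pr, nr = _matched_coords(predicted_receptor, native_receptor, None)
    if len(pr) < 3:
        raise SoftDockError("too few corresponding receptor atoms to superpose")
    xform, _ = kabsch_superpose(pr, nr)
    names = {"CA"} if atom_selection == "CA" else None
    pl, nl = _matched_coords(predicted_ligand, native_ligand, names)
    if len(pl) == 0:
        raise SoftDockError("no corresponding ligand atoms")
    moved = xform.apply(pl)
    return float(np.sqrt(np.mean(np.sum((moved - nl) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# CAPRI classes and hit statistics


class CapriClass(enum.Enum):
    HIGH = "high"
    MEDIUM = "medium"
    ACCEPTABLE = "acceptable"
    INCORRECT = "incorrect"


def capri_class(l: float) -> CapriClass:
    """CAPRI quality class from LRMSD, inclusive boundaries.

    <= 2.5 A high, <= 5 A medium, <= 10 A acceptable, else incorrect.
    """
    if l < 0:
        raise SoftDockError(f"LRMSD must be non-negative, got {l}")
    if l <= 2.5:
        return CapriClass.HIGH
    if l <= 5.0:
        return CapriClass.MEDIUM
    if l <= 10.0:
        return CapriClass.ACCEPTABLE
    return CapriClass.INCORRECT


@dataclass
class ComplexEval:
    """Per-complex hit bookkeeping over a ranked prediction list.

    ``first_rank`` is the smallest rank whose LRMSD is within the
    cutoff, ``best_rmsd`` the minimal LRMSD among hits and
    ``best_rank`` the rank attaining it.  When there are no hits the
    optional fields are None (rendered as "-" in tables).
    """

    complex_id: str
    hit_count: int
    first_rank: int | None
    first_rmsd: float | None
    best_rank: int | None
    best_rmsd: float | None
    top_n: int = 2000
    cutoff: float = 10.0

    def __post_init__(self) -> None:
        absent = [self.first_rank, self.first_rmsd, self.best_rank, self.best_rmsd]
        if (self.hit_count == 0) != all(v is None for v in absent):
            raise SoftDockError(
                "hit_count == 0 must coincide with absent rank/rmsd fields"
            )

    def as_row(self) -> dict[str, str]:
        fmt = lambda v, p: "-" if v is None else (f"{v:.{p}f}" if p else str(v))
        return {
            "complex": self.complex_id,
            "HitCount": str(self.hit_count),
            "FirstRMSD": fmt(self.first_rmsd, 2),
            "FirstRank": fmt(self.first_rank, 0),
            "BestRMSD": fmt(self.best_rmsd, 2),
            "BestRank": fmt(self.best_rank, 0),
        }


def hit_stats(
    lrmsds: Sequence[float],
    top_n: int = 2000,
    cutoff: float = 10.0,
    complex_id: str = "",
) -> ComplexEval:
    """Hit statistics from LRMSDs listed in rank order (rank = index + 1).

    Only the first ``top_n`` entries are considered; a hit is
    LRMSD <= cutoff.
    """
    considered = list(lrmsds[:top_n])
    hits = [(i + 1, r) for i, r in enumerate(considered) if r <= cutoff]
    if not hits:
        return ComplexEval(complex_id, 0, None, None, None, None, top_n, cutoff)
    first_rank, first_rmsd = hits[0]
    best_rank, best_rmsd = min(hits, key=lambda h: (h[1], h[0]))
    return ComplexEval(
        complex_id,
        len(hits),
        first_rank,
        float(first_rmsd),
        best_rank,
        float(best_rmsd),
        top_n,
        cutoff,
    )


# ---------------------------------------------------------------------------
# interface and surface definitions


def interface_residues(
    receptor: Structure,
    ligand: Structure,
    cutoff: float = 5.0,
    surface_threshold: float = 0.10,
    reference_areas: Mapping[str, float] | None = None,
) -> tuple[set[ResidueId], set[ResidueId]]:
    """Interface residues of a bound complex, per molecule.

    A residue qualifies iff it is a surface residue of its monomer
    (relative accessibility > ``surface_threshold``) and the minimum
    distance from its atoms to the partner's atoms is strictly below
    ``cutoff``.
    """
    out = []
    for mol, partner in ((receptor, ligand), (ligand, receptor)):
        surf = surface_residues(
            mol, threshold=surface_threshold, reference_areas=reference_areas
        )
        tree = cKDTree(partner.coords)
        dmin: dict[ResidueId, float] = {}
        dists, _ = tree.query(mol.coords)
        for atom, d in zip(mol.atoms, dists):
            rid = atom.residue_id
            dmin[rid] = min(dmin.get(rid, np.inf), float(d))
        out.append({rid for rid in surf if dmin.get(rid, np.inf) < cutoff})
    return out[0], out[1]


def prediction_accuracy(
    predicted: Iterable[ResidueId], true_interface: Iterable[ResidueId]
) -> float | None:
    """Fraction of predicted residues that are true interface residues.

    Returns None for an empty prediction (rendered "-" in tables).
    """
    predicted = set(predicted)
    if not predicted:
        return None
    return len(predicted & set(true_interface)) / len(predicted)


def ub_rmsd(unbound: Structure, bound: Structure) -> float:
    """CA RMSD between unbound and bound forms after superposition.

    Residues are matched by (chain, residue number, insertion code);
    unmatched residues are dropped.  Requires >= 3 common CA atoms.
    """
    pu, pb = _matched_coords(unbound, bound, {"CA"})
    if len(pu) < 3:
        raise SoftDockError(
            f"only {len(pu)} corresponding CA atoms between "
            f"{unbound.id!r} and {bound.id!r}; need >= 3"
        )
    _, rmsd = kabsch_superpose(pu, pb)
    return rmsd


def relative_interface_area(
    receptor: Structure,
    ligand: Structure,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Buried interface area divided by total complex area.

    The interface area is half the total buried area,
    (SASA_R + SASA_L - SASA_complex) / 2, since burial is shared by the
    two surfaces.
    """
    area = lambda s: compute_sasa(s, probe=probe, n_sphere_points=n_sphere_points)[0].sum()
    a_r = area(receptor)
    a_l = area(ligand)
    a_c = area(merge(receptor, ligand))
    if a_c <= 0:
        raise SoftDockError("complex has non-positive surface area")
    buried = max(0.0, float(a_r + a_l - a_c))
    return 0.5 * buried / float(a_c)


# ---------------------------------------------------------------------------
# benchmark summaries


@dataclass(frozen=True)
class BenchmarkSummary:
    n_success: int
    total_hits: int
    mean_hits: float | None  # total hits / successful complexes, 1 decimal

    @classmethod
    def from_counts(cls, n_success: int, total_hits: int) -> "BenchmarkSummary":
        mean = round(total_hits / n_success, 1) if n_success else None
        return cls(n_success, total_hits, mean)


def benchmark_summary(
    evals: Iterable[ComplexEval | int],
) -> BenchmarkSummary:
    """Aggregate per-complex hit counts.

    Accepts ComplexEval objects or plain hit counts.  A complex is a
    success when it has at least one hit; the mean hit count is taken
    over successful complexes only and reported to one decimal.
    """
    counts = [e.hit_count if isinstance(e, ComplexEval) else int(e) for e in evals]
    n_success = sum(1 for c in counts if c > 0)
    return BenchmarkSummary.from_counts(n_success, sum(counts))
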