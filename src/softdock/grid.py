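"""Two-channel grid projection and the direct correlation score.

A structure is projected onto a regular cubic lattice (1 angstrom
default).  Cells whose center lies within the van der Waals radius of
any atom are *occupied*; the two score channels are built from them:

* **core** — every occupied cell.  Core-core coincidence between
  receptor and ligand costs a flat penalty ``rho`` per cell pair, so any
  interpenetration of the two molecules is punished.
* **surface** — the one-cell solvent-side skin: unoccupied cells with at
  least one occupied cell among their 26 neighbours.  Each surface cell
  carries the sum of the ASP values of the nearby atoms (those whose vdW
  sphere dilated by one cell diagonal covers the cell center); since ASP
  values are negative, products of receptor and ligand surface cells are
  positive and reward close surface-to-surface contact — the grid
  rendering of burying solvent-accessible area on binding.

The correlation score of a relative integer shift ``s`` is

    score(s) = sum_x surf_R(x) * surf_L(x - s)  -  rho * sum_x core_R(x) * core_L(x - s)

and larger is better.  Grid origins are snapped to multiples of the
spacing so that grids of independently projected molecules share one
global lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SoftDockError
from .structure import Structure

DEFAULT_RHO = 20.0


@dataclass
class DockGrid:
    """Two-channel lattice representation of one molecule."""

    spacing: float
    origin: np.ndarray  # world coordinates of cell (0,0,0) center
    surface: np.ndarray  # float field, <= 0 (summed ASP on the solvent skin)
    core: np.ndarray  # uint8 field in {0,1} (occupied cells)
    rho: float = DEFAULT_RHO

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise SoftDockError(f"grid spacing must be positive, got {self.spacing}")
        if self.rho <= 0:
            raise SoftDockError(f"overlap penalty rho must be positive, got {self.rho}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.surface.shape != self.core.shape:
            raise SoftDockError("channel shape mismatch")
        if np.any(self.surface > 0):
            raise SoftDockError("surface channel must be non-positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.surface.shape

    @property
    def occupancy(self) -> np.ndarray:
        """Boolean field of all occupied cells (the core channel)."""
        return self.core > 0

    def n_core(self) -> int:
        return int(self.core.sum())


def project(
    s: Structure,
    spacing: float = 1.0,
    pad: int = 2,
    rho: float = DEFAULT_RHO,
) -> DockGrid:
    """Project *s* onto a lattice, producing surface and core channels.

    The grid covers the bounding box of the atoms (including their vdW
    extent and the one-cell solvent skin) plus *pad* cells on every
    side.  Requires ASP values to be assigned.  Deterministic;
    translating all atoms by exactly one spacing yields identical
    channel arrays with a shifted origin.
    """
    if spacing <= 0:
        raise SoftDockError(f"grid spacing must be positive, got {spacing}")
    if pad < 1:
        raise SoftDockError("pad must be >= 1 (the solvent skin needs one cell)")
    coords = s.coords
    radii = s.radii
    asp = s.asp_values
    skin = spacing * np.sqrt(3.0)  # one cell diagonal
    lo = (coords - radii[:, None]).min(axis=0)
    hi = (coords + radii[:, None]).max(axis=0)
    # snap origin to the global lattice (multiples of spacing)
    origin = (np.floor(lo / spacing) - pad) * spacing
    dims = np.ceil((hi - origin) / spacing).astype(int) + pad + 1
    occ = np.zeros(tuple(dims), dtype=bool)
    asp_field = np.zeros(tuple(dims), dtype=float)

    for xyz, r, a in zip(coords, radii, asp):
        # local window of cells inside the dilated sphere r + skin
        ilo = np.floor((xyz - r - skin - origin) / spacing).astype(int)
        ihi = np.ceil((xyz + r + skin - origin) / spacing).astype(int)
        ilo = np.maximum(ilo, 0)
        ihi = np.minimum(ihi, dims - 1)
        ax = [np.arange(ilo[k], ihi[k] + 1) for k in range(3)]
        centers = [origin[k] + ax[k] * spacing for k in range(3)]
        d2 = (
            (centers[0][:, None, None] - xyz[0]) ** 2
            + (centers[1][None, :, None] - xyz[1]) ** 2
            + (centers[2][None, None, :] - xyz[2]) ** 2
        )
        sl = tuple(slice(ilo[k], ihi[k] + 1) for k in range(3))
        occ[sl] |= d2 <= r * r
        asp_field[sl] += np.where(d2 <= (r + skin) ** 2, a, 0.0)

    # solvent-side skin: unoccupied cells 26-adjacent to the occupancy
    dilated = ndimage.binary_dilation(
        occ, structure=np.ones((3, 3, 3), dtype=bool)
    )
    surface = np.where(dilated & ~occ, asp_field, 0.0)
    return DockGrid(
        spacing=spacing,
        origin=origin,
        surface=surface,
        core=occ.astype(np.uint8),
        rho=rho,
    )


def grid_score_direct(
    receptor: DockGrid, ligand: DockGrid, shift: tuple[int, int, int]
) -> float:
    """Correlation score of one integer relative shift, by direct summation.

    Receptor cell index ``x`` is paired with ligand cell index
    ``x - shift``.  Shifts placing the grids out of overlap score 0.
    """
    if abs(receptor.spacing - ligand.spacing) > 1e-12:
        raise SoftDockError(
            f"grid spacing mismatch: {receptor.spacing} vs {ligand.spacing}"
        )
    shift = tuple(int(v) for v in shift)
    nr = receptor.dims
    nl = ligand.dims
    rs, ls = [], []
    for k in range(3):
        r0 = max(0, shift[k])
        r1 = min(nr[k], nl[k] + shift[k])
        if r1 <= r0:
            return 0.0
        rs.append(slice(r0, r1))
        ls.append(slice(r0 - shift[k], r1 - shift[k]))
    rs, ls = tuple(rs), tuple(ls)
    surf = float(np.sum(receptor.surface[rs] * ligand.surface[ls]))
    core = float(np.sum(receptor.core[rs].astype(float) * ligand.core[ls]))
    return surf - receptor.rho * core


def _world_shift(receptor: DockGrid, ligand: DockGrid) -> tuple[int, int, int]:
    if abs(receptor.spacing - ligand.spacing) > 1e-12:
        raise SoftDockError("grid spacing mismatch")
    rel = (ligand.origin - receptor.origin) / receptor.spacing
    shift = np.rint(rel).astype(int)
    if not np.allclose(rel, shift, atol=1e-6):
        raise SoftDockError("grid origins are not on a common lattice")
    return tuple(int(v) for v in shift)


def pose_score(receptor: DockGrid, ligand: DockGrid) -> float:
    """Score two grids in their own world frames (lattice-aligned origins)."""
    return grid_score_direct(receptor, ligand, _world_shift(receptor, ligand))


def core_overlap_cells(receptor: DockGrid, ligand: DockGrid) -> int:
    """Number of coincident core-core cells of two grids in world frame."""
    shift = _world_shift(receptor, ligand)
    nr, nl = receptor.dims, ligand.dims
    rs, ls = [], []
    for k in range(3):
        r0 = max(0, shift[k])
        r1 = min(nr[k], nl[k] + shift[k])
        if r1 <= r0:
            return 0
        rs.append(slice(r0, r1))
        ls.append(slice(r0 - shift[k], r1 - shift[k]))
    return int(
        np.sum(receptor.core[tuple(rs)].astype(int) * ligand.core[tuple(ls)])
    )
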