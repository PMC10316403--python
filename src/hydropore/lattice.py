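"""Periodic square-lattice geometry: slit pore, neighbours, distances, hydration shell.

The simulation box is an ``L x L`` periodic square partition of the monolayer.
Each cell is occupied by exactly one species:

* ``WATER`` -- a coarse-grained water molecule,
* ``WALL``  -- an immobile hydrophobic cell; one full row of them realises the
  slit pore (under periodic boundaries a single row bounds the pore on both
  sides),
* ``RESIDUE`` -- a bead of the hydrophobic homopolymer.

Coordinates are 0-based ``(x, y)`` with the wall on row ``y = wall_row``
(default 0); the pore interior is rows ``1 .. L-1``.  All functions in this
module are plain NumPy and support any ``L >= 2``; they double as the
brute-force oracles for the fast incremental bookkeeping in
:mod:`hydropore.kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WATER = np.int8(0)
WALL = np.int8(1)
RESIDUE = np.int8(2)

#: maximum lattice separation that the van der Waals cutoff can ever require:
#: 6 r0 at nearest-neighbour spacing l = (v/v0)^(1/3) >= 1.
MAX_PAIR_DISTANCE = 6


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the periodic monolayer and its slit pore.

    Parameters
    ----------
    L : int
        Side length in cells (the box holds ``L**2`` cells).
    wall_row : int or None
        Row index of the fixed hydrophobic wall cells.  ``None`` removes the
        wall entirely (the "free chain" geometry used for comparison runs).
    """

    L: int = 40
    wall_row: int | None = 0

    def __post_init__(self) -> None:
        if self.L < 8:
            raise ValueError(f"L must be >= 8, got {self.L}")
        if self.wall_row is not None and not 0 <= self.wall_row < self.L:
            raise ValueError(f"wall_row {self.wall_row} outside grid of side {self.L}")

    @property
    def n_cells(self) -> int:
        return self.L * self.L

    @property
    def periodic(self) -> bool:
        return True


def empty_occupancy(spec: GridSpec) -> np.ndarray:
    """All-water occupancy with the wall row (if any) filled in."""
    occ = np.full((spec.L, spec.L), WATER, dtype=np.int8)
    if spec.wall_row is not None:
        occ[:, spec.wall_row] = WALL
    return occ


def build_slit_pore(spec: GridSpec, chain: np.ndarray | None = None) -> np.ndarray:
    """Occupancy grid for the slit pore, optionally with a chain placed in it.

    ``chain`` is an ``(N_R, 2)`` integer array of ``(x, y)`` cell coordinates
    forming a self-avoiding walk.  Raises ``ValueError`` naming the offending
    cell if the chain overlaps the wall or itself, or is not a lattice SAW.
    """
    occ = empty_occupancy(spec)
    if chain is None or len(chain) == 0:
        return occ
    chain = np.asarray(chain, dtype=np.int64)
    if spec.wall_row is not None and len(chain) > spec.L - 2:
        # pore height L-1 must exceed the chain's maximum extension
        raise ValueError(
            f"chain of {len(chain)} residues does not fit in a pore of height {spec.L - 1}"
        )
    validate_chain(chain, spec)
    for x, y in chain:
        if occ[x, y] == WALL:
            raise ValueError(f"chain cell ({x}, {y}) lies on the wall row")
        if occ[x, y] == RESIDUE:
            raise ValueError(f"chain overlaps itself at cell ({x}, {y})")
        occ[x, y] = RESIDUE
    return occ


def validate_chain(chain: np.ndarray, spec: GridSpec) -> None:
    """Check SAW validity: unit bonds under periodicity, all cells distinct."""
    chain = np.asarray(chain)
    L = spec.L
    if chain.ndim != 2 or chain.shape[1] != 2:
        raise ValueError("chain must be an (N_R, 2) coordinate array")
    if np.any(chain < 0) or np.any(chain >= L):
        raise ValueError("chain coordinates outside the grid")
    cells = {tuple(c) for c in chain.tolist()}
    if len(cells) != len(chain):
        raise ValueError("chain is not self-avoiding (duplicate cell)")
    for a, b in zip(chain[:-1], chain[1:]):
        dx = min((a[0] - b[0]) % L, (b[0] - a[0]) % L)
        dy = min((a[1] - b[1]) % L, (b[1] - a[1]) % L)
        if dx + dy != 1:
            raise ValueError(f"chain bond {tuple(a)} -> {tuple(b)} is not a unit lattice bond")


def occupancy_counts(occ: np.ndarray) -> dict[str, int]:
    """Species counts: N_W (water), wall cells, N_R (residues)."""
    return {
        "N_W": int(np.count_nonzero(occ == WATER)),
        "N_wall": int(np.count_nonzero(occ == WALL)),
        "N_R": int(np.count_nonzero(occ == RESIDUE)),
    }


def minimum_image_distance(a, b, spec: GridSpec) -> float:
    """Euclidean lattice distance between cells under the minimum-image convention."""
    L = spec.L
    dx = abs(int(a[0]) - int(b[0])) % L
    dy = abs(int(a[1]) - int(b[1])) % L
    dx = min(dx, L - dx)
    dy = min(dy, L - dy)
    return float(np.hypot(dx, dy))


def water_pair_distance_counts(occ: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Table of unordered water-water pair counts indexed by squared lattice distance.

    Entry ``t[d2]`` is the number of unordered water pairs at squared
    minimum-image distance ``d2``, for ``d2 = 0 .. MAX_PAIR_DISTANCE**2``.
    The table is exact (integer bookkeeping, no floating-point keys) and covers
    every pair the 6 r0 van der Waals cutoff can ever reach, since the
    nearest-neighbour spacing is at least r0.
    """
    L = spec.L
    xs, ys = np.nonzero(occ == WATER)
    dx = np.abs(xs[:, None] - xs[None, :])
    dy = np.abs(ys[:, None] - ys[None, :])
    dx = np.minimum(dx, L - dx)
    dy = np.minimum(dy, L - dy)
    d2 = dx * dx + dy * dy
    iu = np.triu_indices(len(xs), k=1)
    d2 = d2[iu]
    d2 = d2[d2 <= MAX_PAIR_DISTANCE**2]
    return np.bincount(d2, minlength=MAX_PAIR_DISTANCE**2 + 1).astype(np.int64)


def hydration_shell(occ: np.ndarray) -> np.ndarray:
    """Boolean mask of hydration-shell water.

    A water cell belongs to the shell iff at least one of its four lattice
    neighbours (von Neumann neighbourhood, matching the hydrogen-bond
    adjacency) is a residue or a wall cell.
    """
    solute = occ != WATER
    near = (
        np.roll(solute, 1, axis=0)
        | np.roll(solute, -1, axis=0)
        | np.roll(solute, 1, axis=1)
        | np.roll(solute, -1, axis=1)
    )
    return (occ == WATER) & near
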