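"""Self-avoiding-walk homopolymer: contact points and chain move generators.

The chain is an ordered list of ``N_R`` lattice cells with unit bonds under
periodic boundaries; all residues are hydrophobic and interact with water and
with each other by excluded volume only.  The degree-of-folding observable is
the number of contact points ``N_CP``: unordered residue pairs on
nearest-neighbour cells that are not adjacent along the chain.

Four move generators act on the chain: corner (kink) flips including terminal
rotations, crankshaft rotations of U-shaped segments, pivots of the shorter
arm, and unit translations of the whole chain (optionally biased toward the
top wall).  Proposals are generated by the same jitted routines the Monte
Carlo engine uses, so there is a single implementation of the move mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .lattice import WALL, GridSpec, validate_chain

MOVE_KINDS = ("corner_flip", "crankshaft", "pivot", "translation")


@dataclass
class MoveProposal:
    """Outcome of a chain move generator.

    ``valid`` is False when the local geometry admits no move of the requested
    kind or the target cells are blocked; invalid proposals count as rejected
    attempts.  ``moved`` holds residue indices, ``new_xy`` their proposed
    coordinates, ``vacated`` the cells left behind (to be refilled by water).
    """

    kind: str
    valid: bool
    moved: np.ndarray
    new_xy: np.ndarray
    vacated: np.ndarray

    @staticmethod
    def invalid(kind: str) -> "MoveProposal":
        e = np.empty((0, 2), dtype=np.int64)
        return MoveProposal(kind, False, np.empty(0, dtype=np.int64), e, e)


def count_contact_points(chain: np.ndarray, spec: GridSpec) -> int:
    """Number of unordered NN residue pairs with chain separation >= 2."""
    chain = np.asarray(chain, dtype=np.int64)
    validate_chain(chain, spec)
    L = spec.L
    resmap = np.full((L, L), -1, dtype=np.int16)
    for i, (x, y) in enumerate(chain):
        resmap[x, y] = i
    return int(kernels.count_contacts(chain, resmap, L))


def max_contact_points(n_residues: int) -> int:
    """Upper bound on N_CP for a chain of ``n_residues`` cells.

    The densest packing of n cells on the square lattice has
    ``2n - ceil(2 sqrt(n))`` internal adjacencies (the most-square compact
    rectangle attains it); subtracting the ``n - 1`` chain bonds leaves the
    contact bound.  For n = 36 (the 6x6 block) this gives 25.
    """
    if n_residues < 2:
        return 0
    adjacencies = 2 * n_residues - int(np.ceil(2.0 * np.sqrt(n_residues)))
    return adjacencies - (n_residues - 1)


def _finalize(kind, chain, mov_idx, new_xy, nmov, occ, resmap) -> MoveProposal:
    if nmov == 0:
        return MoveProposal.invalid(kind)
    moved = mov_idx[:nmov].copy()
    newc = new_xy[:nmov].copy()
    if occ is not None:
        flag = np.zeros(len(chain), dtype=np.bool_)
        if not kernels.proposal_valid(occ, resmap, moved, newc, nmov, flag):
            return MoveProposal.invalid(kind)
    new_set = {tuple(c) for c in newc.tolist()}
    vac = np.array(
        [chain[i] for i in moved if tuple(chain[i]) not in new_set], dtype=np.int64
    ).reshape(-1, 2)
    return MoveProposal(kind, True, moved, newc, vac)


def _occ_resmap(chain, spec, occ):
    if occ is None:
        return None, None
    resmap = np.full((spec.L, spec.L), -1, dtype=np.int16)
    for i, (x, y) in enumerate(np.asarray(chain)):
        resmap[x, y] = i
    return occ, resmap


def propose_corner_flip(chain, index, rng, spec: GridSpec, occ=None) -> MoveProposal:
    """Kink flip at ``index``; terminal residues rotate about their neighbour."""
    chain = np.ascontiguousarray(chain, dtype=np.int64)
    mov = np.empty(len(chain), dtype=np.int64)
    new = np.empty((len(chain), 2), dtype=np.int64)
    choice = int(rng.integers(3))
    nmov = kernels.propose_corner_flip(chain, spec.L, index, choice, mov, new)
    occ, resmap = _occ_resmap(chain, spec, occ)
    return _finalize("corner_flip", chain, mov, new, nmov, occ, resmap)


def propose_crankshaft(chain, index, rng, spec: GridSpec, occ=None) -> MoveProposal:
    """180-degree rotation of the interior of the U-shaped segment index..index+3."""
    chain = np.ascontiguousarray(chain, dtype=np.int64)
    mov = np.empty(len(chain), dtype=np.int64)
    new = np.empty((len(chain), 2), dtype=np.int64)
    nmov = kernels.propose_crankshaft(chain, spec.L, index, mov, new)
    occ, resmap = _occ_resmap(chain, spec, occ)
    return _finalize("crankshaft", chain, mov, new, nmov, occ, resmap)


def propose_pivot(chain, index, rng, spec: GridSpec, occ=None, rotation=None) -> MoveProposal:
    """Rigid rotation of the shorter arm about residue ``index``.

    The rotation (90/180/270 degrees) is drawn uniformly unless given.
    """
    chain = np.ascontiguousarray(chain, dtype=np.int64)
    mov = np.empty(len(chain), dtype=np.int64)
    new = np.empty((len(chain), 2), dtype=np.int64)
    rot = int(rng.integers(1, 4)) if rotation is None else int(rotation)
    nmov = kernels.propose_pivot(chain, spec.L, index, rot, mov, new)
    occ, resmap = _occ_resmap(chain, spec, occ)
    return _finalize("pivot", chain, mov, new, nmov, occ, resmap)


def propose_translation(chain, bias, rng, spec: GridSpec, occ=None) -> MoveProposal:
    """Unit translation of the whole chain.

    With ``bias`` on, the vertical component is drawn only toward the top
    wall (+y) and the -y direction is never proposed; horizontal moves remain
    unbiased.  With bias off all four directions are uniform.
    """
    chain = np.ascontiguousarray(chain, dtype=np.int64)
    mov = np.empty(len(chain), dtype=np.int64)
    new = np.empty((len(chain), 2), dtype=np.int64)
    if bias:
        d = (0, 1, 2)[int(rng.integers(3))]
    else:
        d = int(rng.integers(4))
    nmov = kernels.propose_translation(chain, spec.L, d, mov, new)
    occ, resmap = _occ_resmap(chain, spec, occ)
    return _finalize("translation", chain, mov, new, nmov, occ, resmap)


def apply_proposal(chain: np.ndarray, prop: MoveProposal) -> np.ndarray:
    """Return the chain with an (assumed valid) proposal applied."""
    if not prop.valid:
        raise ValueError("cannot apply an invalid proposal")
    out = np.asarray(chain, dtype=np.int64).copy()
    out[prop.moved] = prop.new_xy
    return out


def wall_overlap(prop: MoveProposal, occ: np.ndarray) -> bool:
    return any(occ[x, y] == WALL for x, y in prop.new_xy)
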