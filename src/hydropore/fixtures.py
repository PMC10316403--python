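"""Deterministic test conformations and snapshots.

``rod``       -- straight 36-mer at mid-pore height (N_CP = 0);
``hairpin``   -- two antiparallel strands joined by a turn;
``snake6x6``  -- boustrophedon filling a 6x6 block, the maximally compact
                 36-mer (N_CP = 25);
``wall_only`` -- slit pore with no chain.
"""

from __future__ import annotations

import numpy as np

from .engine import rod_chain
from .lattice import GridSpec, build_slit_pore

FIXTURE_NAMES = ("rod", "hairpin", "snake6x6", "wall_only")


def fixture_chain(name: str, n_residues: int = 36, spec: GridSpec | None = None) -> np.ndarray | None:
    spec = spec or GridSpec()
    L = spec.L
    if name == "wall_only":
        return None
    if name == "rod":
        return rod_chain(n_residues, spec)
    if name == "hairpin":
        half = n_residues // 2
        x0 = (L - half) // 2
        y0 = L // 2
        down = [[(x0 + i) % L, y0] for i in range(half)]
        back = [[(x0 + half - 1 - i) % L, y0 + 1] for i in range(n_residues - half)]
        return np.array(down + back, dtype=np.int64)
    if name == "snake6x6":
        side = int(round(np.sqrt(n_residues)))
        if side * side != n_residues:
            raise ValueError("snake fixture needs a square residue count")
        x0 = (L - side) // 2
        y0 = L // 2 - side // 2
        cells = []
        for row in range(side):
            xs = range(side) if row % 2 == 0 else range(side - 1, -1, -1)
            cells.extend([(x0 + x) % L, y0 + row] for x in xs)
        return np.array(cells, dtype=np.int64)
    raise ValueError(f"unknown fixture {name!r}")


def make_fixture(name: str, spec: GridSpec | None = None, n_residues: int = 36):
    """Occupancy grid and chain for a named fixture.

    Returns ``(occ, chain)`` with ``chain = None`` for ``wall_only``.
    """
    spec = spec or GridSpec()
    chain = fixture_chain(name, n_residues, spec)
    occ = build_slit_pore(spec, chain)
    return occ, chain
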