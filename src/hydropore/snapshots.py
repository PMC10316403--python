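"""Plain-text snapshot format for lattice configurations.

Layout (all lines LF-terminated)::

    L <int>
    wall_row <int or none>
    v_rel <float>            # optional, defaults to 1.0
    chain <x0>,<y0> <x1>,<y1> ...   # optional, ordered residue coordinates
    <L lines of L characters>       # W water, X wall, R residue, row y printed
                                    # top-down (y = L-1 first), column x left-right

The character grid is redundant with the chain line (residue cells must
match); both are written so snapshots are human-readable and self-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import RESIDUE, WALL, WATER, GridSpec, validate_chain

_CHARS = {int(WATER): "W", int(WALL): "X", int(RESIDUE): "R"}
_LABELS = {v: k for k, v in _CHARS.items()}


@dataclass
class Snapshot:
    spec: GridSpec
    occ: np.ndarray
    chain: np.ndarray | None = None
    v_rel: float = 1.0


def dumps(snap: Snapshot) -> str:
    L = snap.spec.L
    lines = [f"L {L}"]
    wr = snap.spec.wall_row
    lines.append(f"wall_row {'none' if wr is None else wr}")
    lines.append(f"v_rel {snap.v_rel!r}")
    if snap.chain is not None and len(snap.chain):
        coords = " ".join(f"{x},{y}" for x, y in np.asarray(snap.chain))
        lines.append(f"chain {coords}")
    for y in range(L - 1, -1, -1):
        lines.append("".join(_CHARS[int(snap.occ[x, y])] for x in range(L)))
    return "\n".join(lines) + "\n"


def loads(text: str) -> Snapshot:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header: dict[str, str] = {}
    grid_lines: list[str] = []
    for ln in lines:
        parts = ln.split(None, 1)
        if parts[0] in ("L", "wall_row", "v_rel", "chain") and not grid_lines:
            header[parts[0]] = parts[1] if len(parts) > 1 else ""
        else:
            grid_lines.append(ln.strip())
    if "L" not in header:
        raise ValueError("snapshot missing 'L' header")
    L = int(header["L"])
    wr_raw = header.get("wall_row", "none")
    wall_row = None if wr_raw == "none" else int(wr_raw)
    spec = GridSpec(L=L, wall_row=wall_row)
    v_rel = float(header.get("v_rel", "1.0"))
    if len(grid_lines) != L:
        raise ValueError(f"expected {L} grid rows, found {len(grid_lines)}")
    occ = np.empty((L, L), dtype=np.int8)
    for i, ln in enumerate(grid_lines):
        y = L - 1 - i
        if len(ln) != L:
            raise ValueError(f"grid row {i} has length {len(ln)}, expected {L}")
        for x, ch in enumerate(ln):
            if ch not in _LABELS:
                raise ValueError(f"unknown cell character {ch!r}")
            occ[x, y] = _LABELS[ch]
    chain = None
    if "chain" in header:
        chain = np.array(
            [[int(v) for v in tok.split(",")] for tok in header["chain"].split()],
            dtype=np.int64,
        )
        validate_chain(chain, spec)
        for x, y in chain:
            if occ[x, y] != RESIDUE:
                raise ValueError(f"chain cell ({x}, {y}) not marked R in the grid")
        if int((occ == RESIDUE).sum()) != len(chain):
            raise ValueError("grid residue count does not match the chain")
    return Snapshot(spec=spec, occ=occ, chain=chain, v_rel=v_rel)


def save(snap: Snapshot, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps(snap))


def load(path) -> Snapshot:
    with open(path) as fh:
        return loads(fh.read())
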