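"""Numba kernels: incremental Metropolis bookkeeping for the NPT lattice model.

The pure-NumPy routines in :mod:`hydropore.lattice` and
:mod:`hydropore.energetics` recompute every observable from scratch and act as
the oracles; the kernels here maintain the same quantities incrementally so a
full Monte Carlo step (one attempt per chain residue, one per bonding-index
slot, one volume attempt) costs far less than a recomputation.

State layout (all arrays owned by :class:`hydropore.engine.SystemState`):

* ``occ``      int8  (L, L)    cell species (0 water, 1 wall, 2 residue)
* ``sigma``    int8  (L, L, 4) bonding indices per direction (+x, -x, +y, -y)
* ``shell``    uint8 (L, L)    hydration-shell mask
* ``resmap``   int16 (L, L)    residue index at cell, or -1
* ``chain``    int64 (N_R, 2)  ordered residue coordinates
* ``pair_cnt`` int64 (37,)     water-water pair counts by squared distance
* ``cnt``      int64 (3,)      [sigma matches, shell sigma matches, cooperative pairs]
* ``volbox``   float64 (1,)    global cell volume v/v0
* ``ubox``     float64 (1,)    cached van der Waals energy

``cnt`` stores *matches* (facing-index agreements), independent of the volume
switch; the hydrogen-bond counts are ``N_HB = n * cnt[0]`` and
``N_HB_phi = n * cnt[1]`` with ``n = 1`` iff ``v/v0 < 2``.

The incremental pair-distance update assumes ``L >= 13`` so that every
displacement within the cutoff reaches a distinct periodic image; the generic
O(N^2) builder below has no such restriction.

Randomness: all kernels draw from numba's thread-local ``np.random`` state,
seeded once per run (or per wrapped single attempt) via :func:`seed_rng`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WATER = 0
WALL = 1
RESIDUE = 2

MAXD2 = 36

DIRX = np.array([1, -1, 0, 0], dtype=np.int64)
DIRY = np.array([0, 0, 1, -1], dtype=np.int64)
OPP = np.array([1, 0, 3, 2], dtype=np.int64)

# displacement offsets with 1 <= dx^2 + dy^2 <= 36 (full circle)
_ox, _oy = np.meshgrid(np.arange(-6, 7), np.arange(-6, 7), indexing="ij")
_mask = (_ox**2 + _oy**2 >= 1) & (_ox**2 + _oy**2 <= MAXD2)
OFFX = _ox[_mask].astype(np.int64)
OFFY = _oy[_mask].astype(np.int64)
OFFD2 = (OFFX**2 + OFFY**2).astype(np.int64)
del _ox, _oy, _mask

# parameter-vector indices
P_J = 0
P_JSIG = 1
P_DJPHI = 2
P_VHB = 3
P_K1 = 4
P_Q = 5
P_EPS = 6
P_CUT = 7
P_T = 8
P_P = 9
P_DV = 10
P_BIAS = 11
P_VOLMOVES = 12
NPAR = 13

MOVE_CORNER = 0
MOVE_CRANK = 1
MOVE_PIVOT = 2
MOVE_TRANS = 3


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _pbc(i, L):
    """Periodic wrap for i in (-L, 2L); cheaper than hardware modulo."""
    if i >= L:
        return i - L
    if i < 0:
        return i + L
    return i


@njit(cache=True)
def pair_u(r, eps_rel, cutoff):
    """12-6 pair potential in units of 4 eps (r in units of r0); truncated at cutoff."""
    if r >= cutoff:
        return 0.0
    x6 = (1.0 / r) ** 6
    return 4.0 * eps_rel * (x6 * x6 - x6)


@njit(cache=True)
def vdw_from_table(pair_cnt, v_rel, eps_rel, cutoff):
    ell = v_rel ** (1.0 / 3.0)
    u = 0.0
    for d2 in range(1, MAXD2 + 1):
        c = pair_cnt[d2]
        if c > 0:
            u += c * pair_u(ell * np.sqrt(d2), eps_rel, cutoff)
    return u


@njit(cache=True)
def build_pair_table(occ):
    """Generic O(N^2) water-pair distance table (any L >= 2, minimum image)."""
    L = occ.shape[0]
    pair_cnt = np.zeros(MAXD2 + 1, dtype=np.int64)
    half = L // 2
    for x1 in range(L):
        for y1 in range(L):
            if occ[x1, y1] != WATER:
                continue
            i1 = x1 * L + y1
            for x2 in range(L):
                for y2 in range(L):
                    if occ[x2, y2] != WATER:
                        continue
                    if x2 * L + y2 <= i1:
                        continue
                    dx = abs(x1 - x2)
                    if dx > half:
                        dx = L - dx
                    dy = abs(y1 - y2)
                    if dy > half:
                        dy = L - dy
                    d2 = dx * dx + dy * dy
                    if d2 <= MAXD2:
                        pair_cnt[d2] += 1
    return pair_cnt


@njit(cache=True)
def recompute_shell(occ, shell):
    L = occ.shape[0]
    for x in range(L):
        for y in range(L):
            if occ[x, y] != WATER:
                shell[x, y] = 0
                continue
            s = 0
            for d in range(4):
                nx = (x + DIRX[d]) % L
                ny = (y + DIRY[d]) % L
                if occ[nx, ny] != WATER:
                    s = 1
                    break
            shell[x, y] = s


@njit(cache=True)
def recompute_counters(occ, sigma, shell):
    """Full recount of [matches, shell matches, cooperative pairs]."""
    L = occ.shape[0]
    m = 0
    mphi = 0
    nsig = 0
    for x in range(L):
        for y in range(L):
            if occ[x, y] != WATER:
                continue
            for d in (0, 2):  # +x and +y faces: each face pair counted once
                nx = (x + DIRX[d]) % L
                ny = (y + DIRY[d]) % L
                if occ[nx, ny] == WATER and sigma[x, y, d] == sigma[nx, ny, OPP[d]]:
                    m += 1
                    if shell[x, y] and shell[nx, ny]:
                        mphi += 1
            for a in range(4):
                for b in range(a + 1, 4):
                    if sigma[x, y, a] == sigma[x, y, b]:
                        nsig += 1
    return m, mphi, nsig


@njit(cache=True)
def total_volume_red(n_cells, v_rel, n_hb, n_hb_phi, p_star, vhb, k1):
    return n_cells * v_rel + vhb * n_hb - k1 * p_star * vhb * n_hb_phi


@njit(cache=True)
def enthalpy_red(u_vdw, n_hb, n_hb_phi, n_sigma, v_tot, par):
    return (
        u_vdw
        - par[P_J] * n_hb
        - par[P_JSIG] * n_sigma
        - par[P_DJPHI] * n_hb_phi
        + par[P_P] * v_tot
    )


@njit(cache=True)
def count_contacts(chain, resmap, L):
    """Contact points: NN residue pairs nonadjacent along the chain (each once)."""
    ncp = 0
    for i in range(chain.shape[0]):
        x = chain[i, 0]
        y = chain[i, 1]
        for d in (0, 2):
            nx = (x + DIRX[d]) % L
            ny = (y + DIRY[d]) % L
            j = resmap[nx, ny]
            if j >= 0:
                dij = j - i
                if dij < 0:
                    dij = -dij
                if dij >= 2:
                    ncp += 1
    return ncp


@njit(cache=True)
def metropolis(dh, t_star):
    if dh <= 0.0:
        return True
    return np.random.random() < np.exp(-dh / t_star)


# ---------------------------------------------------------------------------
# bonding-index (sigma) attempt
# ---------------------------------------------------------------------------


@njit(cache=True)
def build_sigma_acc(par):
    """Acceptance-probability table for single-index flips.

    The enthalpy change of one flip is a function of the three integer
    deltas only (facing matches, shell facing matches, same-molecule
    matches), so Metropolis factors can be tabulated once per chunk:
    ``pacc[n, dmatch+1, dphi+1, dsig+3]`` with ``n`` the volume bonding
    switch (0: bonds broken, 1: bonding allowed).
    """
    pacc = np.empty((2, 3, 3, 7), dtype=np.float64)
    p_star = par[P_P]
    vhb = par[P_VHB]
    t_star = par[P_T]
    for n in range(2):
        for dm in range(-1, 2):
            for dp in range(-1, 2):
                for ds in range(-3, 4):
                    dv = vhb * n * dm - par[P_K1] * p_star * vhb * n * dp
                    dh = (
                        -par[P_J] * n * dm
                        - par[P_DJPHI] * n * dp
                        - par[P_JSIG] * ds
                        + p_star * dv
                    )
                    pacc[n, dm + 1, dp + 1, ds + 3] = (
                        1.0 if dh <= 0.0 else np.exp(-dh / t_star)
                    )
    return pacc


@njit(cache=True)
def attempt_sigma(occ, sigma, shell, cnt, volbox, par):
    """One sigma-slot attempt at a uniformly random non-residue slot.

    Wall-cell slots are scheduled but inert (walls form no hydrogen bonds).
    Returns 1 on acceptance, 0 otherwise (no-ops count as rejected).
    """
    pacc = build_sigma_acc(par)
    q = int(par[P_Q])
    return attempt_sigma_fast(occ, sigma, shell, cnt, volbox, pacc, q)


@njit(cache=True)
def attempt_sigma_fast(occ, sigma, shell, cnt, volbox, pacc, q):
    """Hot-path sigma attempt: slot, direction and new value from one draw;
    Metropolis factor from the precomputed ``pacc`` table (see
    :func:`build_sigma_acc`).  Physics identical to :func:`attempt_sigma_at`.
    """
    L = occ.shape[0]
    q4 = 4 * q
    m = L * L * q4
    while True:
        r = int(np.random.random() * m)
        cell = r // q4
        x = cell // L
        y = cell - x * L
        if occ[x, y] != RESIDUE:
            break
    if occ[x, y] == WALL:
        return 0
    rem = r - cell * q4
    d = rem // q
    s_new = rem - d * q
    s_old = sigma[x, y, d]
    nx = _pbc(x + DIRX[d], L)
    ny = _pbc(y + DIRY[d], L)
    dmatch = 0
    dphi = 0
    if occ[nx, ny] == WATER:
        facing = sigma[nx, ny, OPP[d]]
        dmatch = (1 if s_new == facing else 0) - (1 if s_old == facing else 0)
        if shell[x, y] and shell[nx, ny]:
            dphi = dmatch
    dsig = 0
    for dd in range(4):
        if dd == d:
            continue
        if s_new == sigma[x, y, dd]:
            dsig += 1
        if s_old == sigma[x, y, dd]:
            dsig -= 1
    n = 1 if volbox[0] < 2.0 else 0
    p = pacc[n, dmatch + 1, dphi + 1, dsig + 3]
    if p >= 1.0 or np.random.random() < p:
        sigma[x, y, d] = s_new
        cnt[0] += dmatch
        cnt[1] += dphi
        cnt[2] += dsig
        return 1
    return 0


@njit(cache=True)
def attempt_sigma_at(occ, sigma, shell, cnt, volbox, par, x, y, d):
    if occ[x, y] == WALL:
        return 0
    L = occ.shape[0]
    q = int(par[P_Q])
    s_old = sigma[x, y, d]
    s_new = np.random.randint(0, q)
    nx = (x + DIRX[d]) % L
    ny = (y + DIRY[d]) % L
    dmatch = 0
    dphi = 0
    if occ[nx, ny] == WATER:
        facing = sigma[nx, ny, OPP[d]]
        dmatch = (1 if s_new == facing else 0) - (1 if s_old == facing else 0)
        if shell[x, y] and shell[nx, ny]:
            dphi = dmatch
    dsig = 0
    for dd in range(4):
        if dd == d:
            continue
        if s_new == sigma[x, y, dd]:
            dsig += 1
        if s_old == sigma[x, y, dd]:
            dsig -= 1
    n = 1 if volbox[0] < 2.0 else 0
    p_star = par[P_P]
    vhb = par[P_VHB]
    dv = vhb * n * dmatch - par[P_K1] * p_star * vhb * n * dphi
    dh = (
        -par[P_J] * n * dmatch
        - par[P_DJPHI] * n * dphi
        - par[P_JSIG] * dsig
        + p_star * dv
    )
    if metropolis(dh, par[P_T]):
        sigma[x, y, d] = s_new
        cnt[0] += dmatch
        cnt[1] += dphi
        cnt[2] += dsig
        return 1
    return 0


# ---------------------------------------------------------------------------
# volume attempt
# ---------------------------------------------------------------------------


@njit(cache=True)
def attempt_volume(pair_cnt, cnt, volbox, ubox, par, n_cells):
    """One global volume attempt: v' uniform in [v - dv, v + dv], v' >= v0."""
    v = volbox[0]
    vp = v + (2.0 * np.random.random() - 1.0) * par[P_DV]
    if vp < 1.0:
        return 0
    eps = par[P_EPS]
    cut = par[P_CUT]
    n_old = 1 if v < 2.0 else 0
    n_new = 1 if vp < 2.0 else 0
    u_old = ubox[0]
    u_new = vdw_from_table(pair_cnt, vp, eps, cut)
    p_star = par[P_P]
    vhb = par[P_VHB]
    k1 = par[P_K1]
    hb_o = n_old * cnt[0]
    hb_n = n_new * cnt[0]
    phi_o = n_old * cnt[1]
    phi_n = n_new * cnt[1]
    v_o = total_volume_red(n_cells, v, hb_o, phi_o, p_star, vhb, k1)
    v_n = total_volume_red(n_cells, vp, hb_n, phi_n, p_star, vhb, k1)
    dh = (
        (u_new - u_old)
        - par[P_J] * (hb_n - hb_o)
        - par[P_DJPHI] * (phi_n - phi_o)
        + p_star * (v_n - v_o)
    )
    if metropolis(dh, par[P_T]):
        volbox[0] = vp
        ubox[0] = u_new
        return 1
    return 0


# ---------------------------------------------------------------------------
# chain move proposals
# ---------------------------------------------------------------------------


@njit(cache=True)
def _wrap_delta(d, L):
    half = L // 2
    if d > half:
        d -= L
    elif d < -half:
        d += L
    return d


@njit(cache=True)
def propose_corner_flip(chain, L, r, end_choice, mov_idx, new_xy):
    """Kink flip at residue r; terminal residues rotate about their neighbour.

    ``end_choice`` in {0,1,2} selects among the three alternative end
    positions (the proposal distribution is symmetric).  Returns the number of
    moved residues (0 if the geometry admits no flip).
    """
    nr = chain.shape[0]
    if r == 0 or r == nr - 1:
        piv = 1 if r == 0 else nr - 2
        px = chain[piv, 0]
        py = chain[piv, 1]
        k = 0
        for d in range(4):
            tx = (px + DIRX[d]) % L
            ty = (py + DIRY[d]) % L
            if tx == chain[r, 0] and ty == chain[r, 1]:
                continue
            if k == end_choice:
                mov_idx[0] = r
                new_xy[0, 0] = tx
                new_xy[0, 1] = ty
                return 1
            k += 1
        return 0
    b1x = _wrap_delta(chain[r, 0] - chain[r - 1, 0], L)
    b1y = _wrap_delta(chain[r, 1] - chain[r - 1, 1], L)
    b2x = _wrap_delta(chain[r + 1, 0] - chain[r, 0], L)
    b2y = _wrap_delta(chain[r + 1, 1] - chain[r, 1], L)
    if b1x * b2x + b1y * b2y != 0:
        return 0  # straight segment: no corner
    mov_idx[0] = r
    new_xy[0, 0] = (chain[r - 1, 0] + b2x) % L
    new_xy[0, 1] = (chain[r - 1, 1] + b2y) % L
    return 1


@njit(cache=True)
def propose_crankshaft(chain, L, r, mov_idx, new_xy):
    """180-degree rotation of the two interior beads of a U-shaped segment r..r+3."""
    nr = chain.shape[0]
    if r < 0 or r > nr - 4:
        return 0
    b3x = _wrap_delta(chain[r + 3, 0] - chain[r, 0], L)
    b3y = _wrap_delta(chain[r + 3, 1] - chain[r, 1], L)
    if abs(b3x) + abs(b3y) != 1:
        return 0  # end beads not adjacent: not a U
    ax = _wrap_delta(chain[r + 1, 0] - chain[r, 0], L)
    ay = _wrap_delta(chain[r + 1, 1] - chain[r, 1], L)
    if ax * b3x + ay * b3y != 0:
        return 0  # first bond parallel to the axis: rotation is the identity
    mov_idx[0] = r + 1
    mov_idx[1] = r + 2
    new_xy[0, 0] = (chain[r, 0] - ax) % L
    new_xy[0, 1] = (chain[r, 1] - ay) % L
    new_xy[1, 0] = (chain[r + 3, 0] - ax) % L
    new_xy[1, 1] = (chain[r + 3, 1] - ay) % L
    return 2


@njit(cache=True)
def propose_pivot(chain, L, r, rot, mov_idx, new_xy):
    """Rigid rotation (rot in {1,2,3} quarter turns) of the shorter arm about residue r.

    Ties are broken toward the tail.  Displacements from the pivot are
    accumulated bond by bond, so the move is well defined under periodic
    wrapping.
    """
    nr = chain.shape[0]
    tail_len = nr - 1 - r
    head_len = r
    if tail_len == 0 and head_len == 0:
        return 0
    use_tail = tail_len <= head_len if tail_len > 0 else False
    if head_len == 0:
        use_tail = True
    px = chain[r, 0]
    py = chain[r, 1]
    nmov = 0
    relx = 0
    rely = 0
    if use_tail:
        for i in range(r + 1, nr):
            relx += _wrap_delta(chain[i, 0] - chain[i - 1, 0], L)
            rely += _wrap_delta(chain[i, 1] - chain[i - 1, 1], L)
            rx, ry = _rotate(relx, rely, rot)
            mov_idx[nmov] = i
            new_xy[nmov, 0] = (px + rx) % L
            new_xy[nmov, 1] = (py + ry) % L
            nmov += 1
    else:
        for i in range(r - 1, -1, -1):
            relx += _wrap_delta(chain[i, 0] - chain[i + 1, 0], L)
            rely += _wrap_delta(chain[i, 1] - chain[i + 1, 1], L)
            rx, ry = _rotate(relx, rely, rot)
            mov_idx[nmov] = i
            new_xy[nmov, 0] = (px + rx) % L
            new_xy[nmov, 1] = (py + ry) % L
            nmov += 1
    return nmov


@njit(cache=True)
def _rotate(dx, dy, rot):
    if rot == 1:  # 90 degrees
        return -dy, dx
    if rot == 2:  # 180 degrees
        return -dx, -dy
    return dy, -dx  # 270 degrees


@njit(cache=True)
def propose_translation(chain, L, d, mov_idx, new_xy):
    """Unit translation of the whole chain along lattice direction d."""
    nr = chain.shape[0]
    for i in range(nr):
        mov_idx[i] = i
        new_xy[i, 0] = (chain[i, 0] + DIRX[d]) % L
        new_xy[i, 1] = (chain[i, 1] + DIRY[d]) % L
    return nr


@njit(cache=True)
def proposal_valid(occ, resmap, mov_idx, new_xy, nmov, moved_flag):
    """Excluded-volume check: targets must be water or cells vacated by the move."""
    nr = moved_flag.shape[0]
    for i in range(nr):
        moved_flag[i] = False
    for k in range(nmov):
        moved_flag[mov_idx[k]] = True
    ok = True
    for k in range(nmov):
        o = occ[new_xy[k, 0], new_xy[k, 1]]
        if o == WALL:
            ok = False
            break
        if o == RESIDUE:
            j = resmap[new_xy[k, 0], new_xy[k, 1]]
            if not moved_flag[j]:
                ok = False
                break
    return ok


# ---------------------------------------------------------------------------
# chain attempt with incremental bookkeeping
# ---------------------------------------------------------------------------


@njit(cache=True)
def make_chain_scratch(nr):
    """Preallocated work arrays for :func:`attempt_chain` (one per run loop,
    reused across attempts to keep the hot path allocation-free)."""
    return (
        np.empty(nr, dtype=np.int64),            # mov_idx
        np.empty((nr, 2), dtype=np.int64),       # new_xy
        np.zeros(nr, dtype=np.bool_),            # moved_flag
        np.empty((nr, 2), dtype=np.int64),       # acq
        np.empty((nr, 2), dtype=np.int64),       # vac
        np.empty((nr, 2), dtype=np.int64),       # old_xy
        np.empty(2 * nr, dtype=np.int8),         # ch_occ
        np.empty((2 * nr, 4), dtype=np.int8),    # ch_sig
        np.empty((10 * nr, 2), dtype=np.int64),  # wlist
        np.empty(10 * nr, dtype=np.uint8),       # shell_save
        np.empty(MAXD2 + 1, dtype=np.int64),     # pair_save
        np.empty(3, dtype=np.int64),             # cnt_save
    )


@njit(cache=True)
def _pairs_of_four(s0, s1, s2, s3):
    n = 0
    if s0 == s1:
        n += 1
    if s0 == s2:
        n += 1
    if s0 == s3:
        n += 1
    if s1 == s2:
        n += 1
    if s1 == s3:
        n += 1
    if s2 == s3:
        n += 1
    return n


@njit(cache=True)
def _scan_region(occ, sigma, shell, cnt, wlist, nw, stampB, sid, sign):
    """Subtract (sign=-1) or add (sign=+1) all counter contributions of pairs
    and cells touching the affected region ``wlist[:nw]``."""
    L = occ.shape[0]
    for k in range(nw):
        x = wlist[k, 0]
        y = wlist[k, 1]
        stampB[x, y] = sid
        if occ[x, y] != WATER:
            continue
        for d in range(4):
            nx = _pbc(x + DIRX[d], L)
            ny = _pbc(y + DIRY[d], L)
            if stampB[nx, ny] == sid:
                continue  # pair already handled from the other endpoint
            if occ[nx, ny] == WATER and sigma[x, y, d] == sigma[nx, ny, OPP[d]]:
                cnt[0] += sign
                if shell[x, y] and shell[nx, ny]:
                    cnt[1] += sign
        cnt[2] += sign * _pairs_of_four(
            sigma[x, y, 0], sigma[x, y, 1], sigma[x, y, 2], sigma[x, y, 3]
        )


@njit(cache=True)
def attempt_chain(
    occ,
    sigma,
    shell,
    resmap,
    chain,
    pair_cnt,
    cnt,
    volbox,
    ubox,
    par,
    wts,
    stampA,
    stampB,
    stampc,
    scr,
):
    """One chain-residue move attempt (kind drawn from the move-mix weights).

    After an accepted move the cells left by the residues become water with
    uniformly random bonding indices; on rejection the state is restored
    bit for bit.  ``scr`` is the work-array bundle from
    :func:`make_chain_scratch`.  Returns (move_kind, accepted).
    """
    L = occ.shape[0]
    nr = chain.shape[0]
    (mov_idx, new_xy, moved_flag, acq, vac, old_xy, ch_occ, ch_sig,
     wlist, shell_save, pair_save, cnt_save) = scr
    u = np.random.random()
    if u < wts[0]:
        kind = MOVE_CORNER
        r = np.random.randint(0, nr)
        c = np.random.randint(0, 3)
        nmov = propose_corner_flip(chain, L, r, c, mov_idx, new_xy)
    elif u < wts[1]:
        kind = MOVE_CRANK
        nmov = 0
        if nr >= 4:
            r = np.random.randint(0, nr - 3)
            nmov = propose_crankshaft(chain, L, r, mov_idx, new_xy)
    elif u < wts[2]:
        kind = MOVE_PIVOT
        r = np.random.randint(0, nr)
        rot = 1 + np.random.randint(0, 3)
        nmov = propose_pivot(chain, L, r, rot, mov_idx, new_xy)
    else:
        kind = MOVE_TRANS
        if par[P_BIAS] != 0.0:
            # vertical proposals only toward the top wall (+y); +-x unbiased
            j = np.random.randint(0, 3)
            d = 0 if j == 0 else (1 if j == 1 else 2)
        else:
            d = np.random.randint(0, 4)
        nmov = propose_translation(chain, L, d, mov_idx, new_xy)
    if nmov == 0:
        return kind, 0
    if not proposal_valid(occ, resmap, mov_idx, new_xy, nmov, moved_flag):
        return kind, 0

    q = int(par[P_Q])
    # --- changed cells: acquired (water -> residue) and vacated (residue -> water)
    nacq = 0
    nvac = 0
    for k in range(nmov):
        if occ[new_xy[k, 0], new_xy[k, 1]] == WATER:
            acq[nacq, 0] = new_xy[k, 0]
            acq[nacq, 1] = new_xy[k, 1]
            nacq += 1
    for k in range(nmov):
        ox = chain[mov_idx[k], 0]
        oy = chain[mov_idx[k], 1]
        hit = False
        for k2 in range(nmov):
            if new_xy[k2, 0] == ox and new_xy[k2, 1] == oy:
                hit = True
                break
        if not hit:
            vac[nvac, 0] = ox
            vac[nvac, 1] = oy
            nvac += 1
    nch = nacq + nvac

    # --- affected region W = changed cells + their neighbours
    sidA = stampc[0] + 1
    stampc[0] = sidA
    nw = 0
    for k in range(nch):
        cx = acq[k, 0] if k < nacq else vac[k - nacq, 0]
        cy = acq[k, 1] if k < nacq else vac[k - nacq, 1]
        for dd in range(5):
            if dd == 4:
                nx2, ny2 = cx, cy
            else:
                nx2 = _pbc(cx + DIRX[dd], L)
                ny2 = _pbc(cy + DIRY[dd], L)
            if stampA[nx2, ny2] != sidA:
                stampA[nx2, ny2] = sidA
                wlist[nw, 0] = nx2
                wlist[nw, 1] = ny2
                nw += 1

    # --- save undo information
    pair_save[:] = pair_cnt
    cnt_save[:] = cnt
    for k in range(nmov):
        old_xy[k, 0] = chain[mov_idx[k], 0]
        old_xy[k, 1] = chain[mov_idx[k], 1]
    for k in range(nch):
        cx = acq[k, 0] if k < nacq else vac[k - nacq, 0]
        cy = acq[k, 1] if k < nacq else vac[k - nacq, 1]
        ch_occ[k] = occ[cx, cy]
        for dd in range(4):
            ch_sig[k, dd] = sigma[cx, cy, dd]
    for k in range(nw):
        shell_save[k] = shell[wlist[k, 0], wlist[k, 1]]

    # --- remove old contributions over W
    sid = stampc[0] + 1
    stampc[0] = sid
    _scan_region(occ, sigma, shell, cnt, wlist, nw, stampB, sid, -1)

    # --- apply: pair table and occupancy (sequential, each pair once)
    for k in range(nacq):
        ax = acq[k, 0]
        ay = acq[k, 1]
        for o in range(OFFX.shape[0]):
            nx2 = _pbc(ax + OFFX[o], L)
            ny2 = _pbc(ay + OFFY[o], L)
            if occ[nx2, ny2] == WATER:
                pair_cnt[OFFD2[o]] -= 1
        occ[ax, ay] = RESIDUE
    for k in range(nvac):
        vx = vac[k, 0]
        vy = vac[k, 1]
        for o in range(OFFX.shape[0]):
            nx2 = _pbc(vx + OFFX[o], L)
            ny2 = _pbc(vy + OFFY[o], L)
            if occ[nx2, ny2] == WATER:
                pair_cnt[OFFD2[o]] += 1
        occ[vx, vy] = WATER
        for dd in range(4):
            sigma[vx, vy, dd] = np.random.randint(0, q)
    # chain coordinates and residue map
    for k in range(nmov):
        resmap[old_xy[k, 0], old_xy[k, 1]] = -1
    for k in range(nmov):
        resmap[new_xy[k, 0], new_xy[k, 1]] = mov_idx[k]
        chain[mov_idx[k], 0] = new_xy[k, 0]
        chain[mov_idx[k], 1] = new_xy[k, 1]
    # shell over W
    for k in range(nw):
        x = wlist[k, 0]
        y = wlist[k, 1]
        s = 0
        if occ[x, y] == WATER:
            for dd in range(4):
                if occ[_pbc(x + DIRX[dd], L), _pbc(y + DIRY[dd], L)] != WATER:
                    s = 1
                    break
        shell[x, y] = s

    # --- re-add contributions over W
    sid = stampc[0] + 1
    stampc[0] = sid
    _scan_region(occ, sigma, shell, cnt, wlist, nw, stampB, sid, 1)

    # --- enthalpy change and Metropolis
    v = volbox[0]
    n = 1 if v < 2.0 else 0
    u_new = vdw_from_table(pair_cnt, v, par[P_EPS], par[P_CUT])
    du = u_new - ubox[0]
    dmatch = cnt[0] - cnt_save[0]
    dphi = cnt[1] - cnt_save[1]
    dsig = cnt[2] - cnt_save[2]
    p_star = par[P_P]
    vhb = par[P_VHB]
    dvtot = vhb * n * dmatch - par[P_K1] * p_star * vhb * n * dphi
    dh = (
        du
        - par[P_J] * n * dmatch
        - par[P_DJPHI] * n * dphi
        - par[P_JSIG] * dsig
        + p_star * dvtot
    )
    if metropolis(dh, par[P_T]):
        ubox[0] = u_new
        return kind, 1

    # --- reject: restore everything
    pair_cnt[:] = pair_save
    cnt[:] = cnt_save
    for k in range(nmov):
        resmap[new_xy[k, 0], new_xy[k, 1]] = -1
    for k in range(nmov):
        resmap[old_xy[k, 0], old_xy[k, 1]] = mov_idx[k]
        chain[mov_idx[k], 0] = old_xy[k, 0]
        chain[mov_idx[k], 1] = old_xy[k, 1]
    for k in range(nch):
        cx = acq[k, 0] if k < nacq else vac[k - nacq, 0]
        cy = acq[k, 1] if k < nacq else vac[k - nacq, 1]
        occ[cx, cy] = ch_occ[k]
        for dd in range(4):
            sigma[cx, cy, dd] = ch_sig[k, dd]
    for k in range(nw):
        shell[wlist[k, 0], wlist[k, 1]] = shell_save[k]
    return kind, 0


# ---------------------------------------------------------------------------
# full MC step and run loop
# ---------------------------------------------------------------------------


@njit(cache=True)
def mc_step(
    occ,
    sigma,
    shell,
    resmap,
    chain,
    pair_cnt,
    cnt,
    volbox,
    ubox,
    par,
    wts,
    stampA,
    stampB,
    stampc,
    acc,
    pacc,
    scr,
):
    """One MC step: a random sequence of one attempt per degree of freedom.

    Schedules exactly N_R chain attempts, 4*(L^2 - N_R) sigma-slot attempts
    (wall slots inert) and, if enabled, one volume attempt, in random order.
    ``acc`` accumulates [sigma, corner, crank, pivot, trans, volume] attempt
    and acceptance counts (attempts at even, acceptances at odd indices).
    ``pacc`` is the flip-acceptance table from :func:`build_sigma_acc`;
    ``scr`` the scratch bundle from :func:`make_chain_scratch`.
    """
    L = occ.shape[0]
    q = int(par[P_Q])
    nr = chain.shape[0]
    n_cells = L * L
    nsig = 4 * (n_cells - nr)
    nvol = 1 if par[P_VOLMOVES] != 0.0 else 0
    nspec = nr + nvol
    ntot = nsig + nspec

    spos = np.empty(nspec, dtype=np.int64)
    stype = np.empty(nspec, dtype=np.int8)
    for i in range(nr):
        stype[i] = 1
    if nvol:
        stype[nspec - 1] = 2
    # shuffle types, then draw distinct slot positions and sort them
    for i in range(nspec - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        t = stype[i]
        stype[i] = stype[j]
        stype[j] = t
    for i in range(nspec):
        while True:
            p = np.random.randint(0, ntot)
            dup = False
            for k in range(i):
                if spos[k] == p:
                    dup = True
                    break
            if not dup:
                break
        # insertion into sorted order
        k = i
        while k > 0 and spos[k - 1] > p:
            spos[k] = spos[k - 1]
            stype[k], stype[k - 1] = stype[k - 1], stype[k]
            k -= 1
        spos[k] = p

    k = 0
    for t in range(ntot):
        if k < nspec and t == spos[k]:
            if stype[k] == 1:
                kind, ok = attempt_chain(
                    occ, sigma, shell, resmap, chain, pair_cnt, cnt, volbox, ubox,
                    par, wts, stampA, stampB, stampc, scr,
                )
                acc[2 + 2 * kind] += 1
                acc[3 + 2 * kind] += ok
            else:
                ok = attempt_volume(pair_cnt, cnt, volbox, ubox, par, n_cells)
                acc[10] += 1
                acc[11] += ok
            k += 1
        else:
            ok = attempt_sigma_fast(occ, sigma, shell, cnt, volbox, pacc, q)
            acc[0] += 1
            acc[1] += ok


@njit(cache=True)
def run_mc(
    occ,
    sigma,
    shell,
    resmap,
    chain,
    pair_cnt,
    cnt,
    volbox,
    ubox,
    par,
    wts,
    step_start,
    step_end,
    n_equil,
    sample_every,
    seed,
    out,
    nsamp0,
    acc,
):
    """Steps ``step_start+1 .. step_end`` of a run; samples every
    ``sample_every`` steps once past ``n_equil`` (global step counter).

    ``out`` is a preallocated (n_samples, 11) float64 buffer receiving
    [step, v_rel, N_HB, N_HB_phi, N_sigma, U_vdw, V_tot, H, N_CP, com_height,
    wall_contacts] from row ``nsamp0`` on.  Returns the updated sample count.
    """
    np.random.seed(seed)
    L = occ.shape[0]
    n_cells = L * L
    stampA = np.zeros((L, L), dtype=np.int64)
    stampB = np.zeros((L, L), dtype=np.int64)
    stampc = np.zeros(1, dtype=np.int64)
    pacc = build_sigma_acc(par)
    scr = make_chain_scratch(chain.shape[0])
    nsamp = nsamp0
    for step in range(step_start + 1, step_end + 1):
        mc_step(
            occ, sigma, shell, resmap, chain, pair_cnt, cnt, volbox, ubox,
            par, wts, stampA, stampB, stampc, acc, pacc, scr,
        )
        if step > n_equil and (step - n_equil) % sample_every == 0:
            if nsamp < out.shape[0]:
                v = volbox[0]
                n = 1 if v < 2.0 else 0
                n_hb = n * cnt[0]
                n_phi = n * cnt[1]
                u = vdw_from_table(pair_cnt, v, par[P_EPS], par[P_CUT])
                vtot = total_volume_red(
                    n_cells, v, n_hb, n_phi, par[P_P], par[P_VHB], par[P_K1]
                )
                h = enthalpy_red(u, n_hb, n_phi, cnt[2], vtot, par)
                nr = chain.shape[0]
                ncp = 0.0
                com = 0.0
                wc = 0.0
                if nr > 0:
                    ncp = float(count_contacts(chain, resmap, L))
                    s = 0.0
                    for i in range(nr):
                        s += chain[i, 1]
                    com = s / nr
                    for i in range(nr):
                        touch = 0
                        for dd in range(4):
                            if (
                                occ[(chain[i, 0] + DIRX[dd]) % L,
                                    (chain[i, 1] + DIRY[dd]) % L] == WALL
                            ):
                                touch = 1
                                break
                        wc += touch
                out[nsamp, 0] = step
                out[nsamp, 1] = v
                out[nsamp, 2] = n_hb
                out[nsamp, 3] = n_phi
                out[nsamp, 4] = cnt[2]
                out[nsamp, 5] = u
                out[nsamp, 6] = vtot
                out[nsamp, 7] = h
                out[nsamp, 8] = ncp
                out[nsamp, 9] = com
                out[nsamp, 10] = wc
                nsamp += 1
    return nsamp


# ---------------------------------------------------------------------------
# cluster equilibration of the bonding indices
# ---------------------------------------------------------------------------


@njit(cache=True)
def cluster_sweep(occ, sigma, shell, cnt, volbox, par, n_clusters):
    """Wolff-style cluster relabelling of the bonding indices (equilibration aid).

    At fixed volume and chain, the enthalpy restricted to the bonding indices
    is a Potts model: same-molecule index pairs couple with J_sigma; facing
    cross-molecule pairs couple with K = J + dJphi*phi - P*vHB + k1*P^2*vHB*phi
    (zero when the volume switch forbids bonding), where phi marks pairs with
    both partners in the hydration shell.  Bonds are laid with probability
    1 - exp(-K/T) between equal-valued variables (only for K > 0); the grown
    cluster is relabelled to a uniformly random state.  Counters are
    recomputed by the caller.
    """
    L = occ.shape[0]
    q = int(par[P_Q])
    t_star = par[P_T]
    n = 1 if volbox[0] < 2.0 else 0
    p_star = par[P_P]
    vhb = par[P_VHB]
    p_sig = 1.0 - np.exp(-par[P_JSIG] / t_star) if par[P_JSIG] > 0 else 0.0
    k_bulk = (par[P_J] - p_star * vhb) * n
    k_shell = (par[P_J] + par[P_DJPHI] - p_star * vhb + par[P_K1] * p_star * p_star * vhb) * n
    p_bulk = 1.0 - np.exp(-k_bulk / t_star) if k_bulk > 0 else 0.0
    p_shell = 1.0 - np.exp(-k_shell / t_star) if k_shell > 0 else 0.0

    nvar = L * L * 4
    stack = np.empty(nvar, dtype=np.int64)
    member = np.empty(nvar, dtype=np.int64)
    visited = np.zeros(nvar, dtype=np.int64)
    tag = 0
    for _ in range(n_clusters):
        while True:
            x = np.random.randint(0, L)
            y = np.random.randint(0, L)
            if occ[x, y] == WATER:
                break
        d0 = np.random.randint(0, 4)
        tag += 1
        s0 = sigma[x, y, d0]
        root = (x * L + y) * 4 + d0
        stack[0] = root
        visited[root] = tag
        nstack = 1
        nmem = 0
        while nstack > 0:
            nstack -= 1
            vid = stack[nstack]
            member[nmem] = vid
            nmem += 1
            cx = vid // (4 * L)
            cy = (vid // 4) % L
            cd = vid % 4
            # same-molecule partners
            for dd in range(4):
                if dd == cd:
                    continue
                wid = (cx * L + cy) * 4 + dd
                if visited[wid] != tag and sigma[cx, cy, dd] == s0:
                    if p_sig > 0.0 and np.random.random() < p_sig:
                        visited[wid] = tag
                        stack[nstack] = wid
                        nstack += 1
            # facing partner
            nx = (cx + DIRX[cd]) % L
            ny = (cy + DIRY[cd]) % L
            if occ[nx, ny] == WATER:
                wid = (nx * L + ny) * 4 + OPP[cd]
                if visited[wid] != tag and sigma[nx, ny, OPP[cd]] == s0:
                    pb = p_shell if (shell[cx, cy] and shell[nx, ny]) else p_bulk
                    if pb > 0.0 and np.random.random() < pb:
                        visited[wid] = tag
                        stack[nstack] = wid
                        nstack += 1
        s_new = np.random.randint(0, q)
        for k in range(nmem):
            vid = member[k]
            sigma[vid // (4 * L), (vid // 4) % L, vid % 4] = s_new
    m, mphi, nsig = recompute_counters(occ, sigma, shell)
    cnt[0] = m
    cnt[1] = mphi
    cnt[2] = nsig
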