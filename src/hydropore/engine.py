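"""Constant-(N, P, T) Metropolis engine.

One Monte Carlo step performs, in random order, one move attempt per degree
of freedom: ``N_R`` chain attempts (kind drawn from the move mix),
``4 (L^2 - N_R)`` bonding-index slot attempts (slots on wall cells are
scheduled but inert, reproducing the conventional degree-of-freedom count
while walls form no hydrogen bonds), and one global volume attempt.  Chain
moves refill vacated cells with water carrying uniformly random bonding
indices.  All randomness flows from a single master seed.

The heavy lifting happens in :mod:`hydropore.kernels`; this module owns the
state container, run scheduling, and thin single-operation wrappers used by
the tests and by the public API.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels
from .energetics import (
    EnergyBreakdown,
    ModelParams,
    ThermoState,
    VolumeState,
    full_breakdown,
)
from .lattice import (
    WATER,
    GridSpec,
    build_slit_pore,
    hydration_shell,
    water_pair_distance_counts,
)

log = logging.getLogger(__name__)

#: reduced temperature below which the bonding network falls out of
#: equilibrium within practical schedules (glassy regime)
GLASSY_T = 0.05

TRAJECTORY_COLUMNS = (
    "step",
    "v_rel",
    "N_HB",
    "N_HB_phi",
    "N_sigma",
    "U_vdw",
    "V_tot",
    "H",
    "N_CP",
    "com_height",
    "wall_contacts",
)

MOVE_NAMES = ("sigma", "corner_flip", "crankshaft", "pivot", "translation", "volume")


@dataclass
class RunConfig:
    """Schedule and state-point settings of one Monte Carlo run."""

    T_star: float = 0.3
    P_star: float = 0.0
    n_steps: int = 1_000_000
    n_equil: int = 10_000
    sample_every: int = 100
    seed: int = 0
    bias: bool = True
    delta_v: float = 0.05
    cluster_equil: bool = False
    cluster_sweeps: int = 20
    move_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    L: int = 40
    n_residues: int = 36
    wall: bool = True
    volume_moves: bool = True
    initial: str = "random"
    v_init: float = 1.0
    log_every: int = 10_000

    def __post_init__(self) -> None:
        if self.T_star <= 0:
            raise ValueError("T_star must be positive")
        if not self.n_steps > self.n_equil >= 0:
            raise ValueError("need n_steps > n_equil >= 0")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.delta_v <= 0:
            raise ValueError("delta_v must be positive")
        if len(self.move_weights) != 4 or min(self.move_weights) < 0 or sum(self.move_weights) <= 0:
            raise ValueError("move_weights must be 4 non-negative numbers")

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(self.T_star, self.P_star)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(L=self.L, wall_row=0 if self.wall else None)

    def n_samples(self) -> int:
        return (self.n_steps - self.n_equil) // self.sample_every


def sigma_slots_per_step(L: int, n_residues: int) -> int:
    """Number of bonding-index slot attempts scheduled per MC step: 4 (L^2 - N_R)."""
    return 4 * (L * L - n_residues)


@dataclass
class SystemState:
    """The full Monte Carlo microstate plus cached extensive bookkeeping."""

    spec: GridSpec
    params: ModelParams
    thermo: ThermoState
    occ: np.ndarray
    sigma: np.ndarray
    shell: np.ndarray
    resmap: np.ndarray
    chain: np.ndarray
    pair_cnt: np.ndarray
    cnt: np.ndarray
    volbox: np.ndarray
    ubox: np.ndarray
    _stampA: np.ndarray = field(repr=False, default=None)
    _stampB: np.ndarray = field(repr=False, default=None)
    _stampc: np.ndarray = field(repr=False, default=None)

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(
        cls,
        spec: GridSpec,
        chain: np.ndarray | None,
        params: ModelParams,
        thermo: ThermoState,
        rng: np.random.Generator,
        v_rel: float = 1.0,
    ) -> "SystemState":
        chain = (
            np.empty((0, 2), dtype=np.int64)
            if chain is None
            else np.ascontiguousarray(chain, dtype=np.int64)
        )
        if len(chain) > 0 and spec.L < 13:
            raise ValueError("chain runs require L >= 13 (incremental pair bookkeeping)")
        occ = build_slit_pore(spec, chain if len(chain) else None)
        L = spec.L
        sigma = rng.integers(0, params.q, size=(L, L, 4), dtype=np.int8)
        shell = hydration_shell(occ).astype(np.uint8)
        resmap = np.full((L, L), -1, dtype=np.int16)
        for i, (x, y) in enumerate(chain):
            resmap[x, y] = i
        pair_cnt = water_pair_distance_counts(occ, spec)
        cnt = np.zeros(3, dtype=np.int64)
        m, mphi, nsig = kernels.recompute_counters(occ, sigma, shell)
        cnt[:] = (m, mphi, nsig)
        volbox = np.array([v_rel], dtype=np.float64)
        ubox = np.array(
            [kernels.vdw_from_table(pair_cnt, v_rel, params.eps_rel, params.cutoff_rel)]
        )
        return cls(
            spec=spec, params=params, thermo=thermo,
            occ=occ, sigma=sigma, shell=shell, resmap=resmap, chain=chain,
            pair_cnt=pair_cnt, cnt=cnt, volbox=volbox, ubox=ubox,
            _stampA=np.zeros((L, L), dtype=np.int64),
            _stampB=np.zeros((L, L), dtype=np.int64),
            _stampc=np.zeros(1, dtype=np.int64),
        )

    # -- derived quantities -------------------------------------------------

    @property
    def v_rel(self) -> float:
        return float(self.volbox[0])

    @property
    def volume_state(self) -> VolumeState:
        return VolumeState(self.v_rel)

    @property
    def n(self) -> int:
        return 1 if self.v_rel < 2.0 else 0

    @property
    def N_HB(self) -> int:
        return self.n * int(self.cnt[0])

    @property
    def N_HB_phi(self) -> int:
        return self.n * int(self.cnt[1])

    @property
    def N_sigma(self) -> int:
        return int(self.cnt[2])

    def params_array(self, *, T_star=None, P_star=None, delta_v=0.05,
                     bias=False, volume_moves=True) -> np.ndarray:
        p = self.params
        t = self.thermo
        par = np.zeros(kernels.NPAR, dtype=np.float64)
        par[kernels.P_J] = p.J_rel
        par[kernels.P_JSIG] = p.Jsigma_rel
        par[kernels.P_DJPHI] = p.dJphi_abs
        par[kernels.P_VHB] = p.vHB_rel
        par[kernels.P_K1] = p.k1_rel
        par[kernels.P_Q] = p.q
        par[kernels.P_EPS] = p.eps_rel
        par[kernels.P_CUT] = p.cutoff_rel
        par[kernels.P_T] = t.T_star if T_star is None else T_star
        par[kernels.P_P] = t.P_star if P_star is None else P_star
        par[kernels.P_DV] = delta_v
        par[kernels.P_BIAS] = 1.0 if bias else 0.0
        par[kernels.P_VOLMOVES] = 1.0 if volume_moves else 0.0
        return par

    def breakdown(self) -> EnergyBreakdown:
        """Enthalpy components from the cached incremental counters."""
        from .energetics import enthalpy, total_volume

        u = float(
            kernels.vdw_from_table(
                self.pair_cnt, self.v_rel, self.params.eps_rel, self.params.cutoff_rel
            )
        )
        vtot = total_volume(
            self.spec.n_cells, self.volume_state, self.N_HB, self.N_HB_phi,
            self.thermo, self.params,
        )
        h = enthalpy(u, self.N_HB, self.N_HB_phi, self.N_sigma, vtot, self.thermo, self.params)
        return EnergyBreakdown(u, self.N_HB, self.N_HB_phi, self.N_sigma, vtot, h)

    def recompute(self) -> EnergyBreakdown:
        """Full from-scratch recomputation (the oracle path, pure NumPy)."""
        shell = hydration_shell(self.occ)
        pc = water_pair_distance_counts(self.occ, self.spec)
        return full_breakdown(
            self.occ, self.sigma, shell.astype(np.uint8), pc,
            self.volume_state, self.thermo, self.params,
        )

    def consistency_errors(self) -> list[str]:
        """Compare cached bookkeeping against full recomputation (debug aid)."""
        errs = []
        ref = self.recompute()
        got = self.breakdown()
        for name in ("N_HB", "N_HB_phi", "N_sigma"):
            if getattr(ref, name) != getattr(got, name):
                errs.append(f"{name}: cached {getattr(got, name)} != full {getattr(ref, name)}")
        for name in ("U_vdw", "V_tot", "H"):
            if abs(getattr(ref, name) - getattr(got, name)) > 1e-8:
                errs.append(f"{name}: cached {getattr(got, name)} != full {getattr(ref, name)}")
        shell = hydration_shell(self.occ).astype(np.uint8)
        if not np.array_equal(shell, self.shell):
            errs.append("shell mask inconsistent")
        pc = water_pair_distance_counts(self.occ, self.spec)
        if not np.array_equal(pc, self.pair_cnt):
            errs.append("pair distance table inconsistent")
        return errs


# ---------------------------------------------------------------------------
# initial conformations
# ---------------------------------------------------------------------------


def rod_chain(n_residues: int, spec: GridSpec, y: int | None = None) -> np.ndarray:
    """Straight horizontal rod at mid-pore height."""
    L = spec.L
    if y is None:
        y = L // 2
    x0 = (L - n_residues) // 2 if n_residues <= L else 0
    if n_residues > L:
        raise ValueError("rod longer than the box")
    return np.array([[(x0 + i) % L, y] for i in range(n_residues)], dtype=np.int64)


def random_saw(n_residues: int, spec: GridSpec, rng: np.random.Generator,
               max_restarts: int = 10_000) -> np.ndarray:
    """Random self-avoiding walk grown inside the pore (restart on dead ends)."""
    L = spec.L
    wall = spec.wall_row
    for _ in range(max_restarts):
        x = int(rng.integers(L))
        y = int(rng.integers(1, L)) if wall is not None else int(rng.integers(L))
        cells = [(x, y)]
        used = {(x, y)}
        ok = True
        for _ in range(n_residues - 1):
            dirs = rng.permutation(4)
            for d in dirs:
                nx = (x + kernels.DIRX[d]) % L
                ny = (y + kernels.DIRY[d]) % L
                if (nx, ny) in used or (wall is not None and ny == wall):
                    continue
                x, y = int(nx), int(ny)
                break
            else:
                ok = False
                break
            cells.append((x, y))
            used.add((x, y))
        if ok:
            return np.array(cells, dtype=np.int64)
    raise RuntimeError("failed to grow a random self-avoiding walk")


# ---------------------------------------------------------------------------
# single-operation wrappers (thin layers over the kernels)
# ---------------------------------------------------------------------------


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def metropolis_accept(delta_H: float, T_star: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-delta_H / T*))."""
    if T_star <= 0:
        raise ValueError("T_star must be positive")
    if delta_H <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_H / T_star))


def sigma_update(state: SystemState, cell, direction: int, rng: np.random.Generator) -> bool:
    """Metropolis resampling of one bonding index; errors on non-water cells."""
    x, y = int(cell[0]), int(cell[1])
    if state.occ[x, y] != WATER:
        raise ValueError(f"cell ({x}, {y}) holds no water molecule")
    kernels.seed_rng(_seed_from(rng))
    par = state.params_array()
    return bool(
        kernels.attempt_sigma_at(
            state.occ, state.sigma, state.shell, state.cnt, state.volbox, par, x, y, direction
        )
    )


def chain_move(state: SystemState, rng: np.random.Generator, bias: bool = False) -> bool:
    """One chain move attempt with water backfill; state untouched on rejection."""
    kernels.seed_rng(_seed_from(rng))
    par = state.params_array(bias=bias)
    wts = np.array([0.25, 0.5, 0.75, 1.0])
    _, ok = kernels.attempt_chain(
        state.occ, state.sigma, state.shell, state.resmap, state.chain,
        state.pair_cnt, state.cnt, state.volbox, state.ubox, par, wts,
        state._stampA, state._stampB, state._stampc,
        kernels.make_chain_scratch(state.chain.shape[0]),
    )
    return bool(ok)


def volume_move(state: SystemState, rng: np.random.Generator, delta_v: float = 0.05) -> bool:
    """One global volume attempt: v' uniform in [v - delta_v, v + delta_v], v' >= v0."""
    if delta_v <= 0:
        raise ValueError("delta_v must be positive")
    kernels.seed_rng(_seed_from(rng))
    par = state.params_array(delta_v=delta_v)
    return bool(
        kernels.attempt_volume(
            state.pair_cnt, state.cnt, state.volbox, state.ubox, par, state.spec.n_cells
        )
    )


def mc_step(state: SystemState, config: RunConfig, rng: np.random.Generator) -> np.ndarray:
    """One full MC step; returns the per-move attempt/acceptance counters."""
    kernels.seed_rng(_seed_from(rng))
    par = state.params_array(
        T_star=config.T_star, P_star=config.P_star, delta_v=config.delta_v,
        bias=config.bias, volume_moves=config.volume_moves,
    )
    wts = np.cumsum(np.asarray(config.move_weights, dtype=np.float64))
    wts /= wts[-1]
    acc = np.zeros(12, dtype=np.int64)
    kernels.mc_step(
        state.occ, state.sigma, state.shell, state.resmap, state.chain,
        state.pair_cnt, state.cnt, state.volbox, state.ubox, par, wts,
        state._stampA, state._stampB, state._stampc, acc,
        kernels.build_sigma_acc(par),
        kernels.make_chain_scratch(state.chain.shape[0]),
    )
    return acc


def cluster_equilibrate(
    state: SystemState,
    rng: np.random.Generator,
    n_sweeps: int = 10,
    T_star: float | None = None,
    P_star: float | None = None,
) -> None:
    """Cluster relabelling sweeps of the bonding indices (equilibration aid).

    Each sweep grows L^2 clusters.  Production statistics always come from
    Metropolis sweeps; this only shortens the burn-in of the bonded network.
    """
    kernels.seed_rng(_seed_from(rng))
    par = state.params_array(T_star=T_star, P_star=P_star)
    for _ in range(n_sweeps):
        kernels.cluster_sweep(
            state.occ, state.sigma, state.shell, state.cnt, state.volbox, par,
            state.spec.n_cells,
        )


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


def initial_chain(config: RunConfig, rng: np.random.Generator) -> np.ndarray | None:
    from . import fixtures

    if config.n_residues == 0:
        return None
    spec = config.grid
    if config.initial == "rod":
        return rod_chain(config.n_residues, spec)
    if config.initial == "random":
        return random_saw(config.n_residues, spec, rng)
    if config.initial in ("hairpin", "snake6x6"):
        return fixtures.fixture_chain(config.initial, config.n_residues, spec)
    raise ValueError(f"unknown initial conformation {config.initial!r}")


def run_simulation(
    config: RunConfig,
    params: ModelParams | None = None,
    state: SystemState | None = None,
    return_state: bool = False,
):
    """Run the full schedule and return the sampled trajectory.

    The trajectory is a DataFrame with one row per sample (columns
    ``TRAJECTORY_COLUMNS``).  With ``return_state`` the final microstate is
    returned as well.  Identical configs and seeds give identical
    trajectories.
    """
    params = params or ModelParams()
    if config.T_star <= GLASSY_T:
        log.warning(
            "T* = %.3f is at or below the glassy regime (T* <~ %.2f): "
            "equilibration is not guaranteed", config.T_star, GLASSY_T,
        )
    ss = np.random.SeedSequence([int(config.seed) % 2**31, 0xC0FFEE])
    rng = np.random.default_rng(ss)
    if state is None:
        chain0 = initial_chain(config, rng)
        state = SystemState.initialize(
            config.grid, chain0, params, config.thermo, rng, v_rel=config.v_init
        )
    if config.cluster_equil:
        cluster_equilibrate(
            state, rng, n_sweeps=config.cluster_sweeps,
            T_star=config.T_star, P_star=config.P_star,
        )
    par = state.params_array(
        T_star=config.T_star, P_star=config.P_star, delta_v=config.delta_v,
        bias=config.bias, volume_moves=config.volume_moves,
    )
    wts = np.cumsum(np.asarray(config.move_weights, dtype=np.float64))
    wts /= wts[-1]
    out = np.empty((config.n_samples(), 11), dtype=np.float64)
    acc = np.zeros(12, dtype=np.int64)
    nsamp = 0
    step = 0
    chunk = max(1, int(config.log_every))
    while step < config.n_steps:
        end = min(step + chunk, config.n_steps)
        prev = acc.copy()
        nsamp = kernels.run_mc(
            state.occ, state.sigma, state.shell, state.resmap, state.chain,
            state.pair_cnt, state.cnt, state.volbox, state.ubox, par, wts,
            step, end, config.n_equil, config.sample_every,
            _seed_from(rng), out, nsamp, acc,
        )
        if log.isEnabledFor(logging.DEBUG):
            d = acc - prev
            rates = {
                MOVE_NAMES[i]: (d[2 * i + 1] / d[2 * i] if d[2 * i] else float("nan"))
                for i in range(6)
            }
            log.debug("steps %d-%d acceptance %s", step + 1, end, rates)
        step = end
    df = pd.DataFrame(out[:nsamp], columns=list(TRAJECTORY_COLUMNS))
    df["step"] = df["step"].astype(np.int64)
    if return_state:
        return df, state
    return df


def acceptance_rates(acc: np.ndarray) -> dict[str, float]:
    return {
        MOVE_NAMES[i]: (float(acc[2 * i + 1] / acc[2 * i]) if acc[2 * i] else float("nan"))
        for i in range(6)
    }
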