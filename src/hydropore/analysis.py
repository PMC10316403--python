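"""Phase-diagram sweeps, coil/globule classification, stability regions,
spinodal detection, adsorption metrics, and field exports.

The chain is classified as a globule when its average contact count exceeds
half of the compact bound ``N_CP^max`` (25 for the 36-mer), and as a coil
otherwise.  A stability region (SR) collects the state points of the
(T*, P*) plane where the mean contact count exceeds a stated fraction of
``N_CP^max``; SRs at increasing thresholds are nested by construction.  The
liquid-to-gas spinodal of the confined water is detected as a discontinuous
volume increase on heating at fixed pressure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chain import max_contact_points
from .energetics import ModelParams
from .engine import RunConfig, SystemState, run_simulation
from .kernels import DIRX, DIRY, OPP, WATER

DEFAULT_THRESHOLDS = (0.30, 0.40, 0.50)

#: spinodal criteria: HB-off mean volume, or a relative jump in total volume
GAS_V_REL = 2.0
VOLUME_JUMP = 0.50


@dataclass(frozen=True)
class StatePointSummary:
    """Averaged observables of one (T*, P*) state point."""

    T_star: float
    P_star: float
    n_samples: int
    mean_N_CP: float
    se_N_CP: float
    mean_N_HB: float
    se_N_HB: float
    mean_N_HB_phi: float
    se_N_HB_phi: float
    mean_v_rel: float
    se_v_rel: float
    mean_V_tot: float
    se_V_tot: float
    max_N_CP: float
    adsorbed_fraction: float
    gas: bool

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class StabilityRegion:
    """Grid points where the mean contact count exceeds threshold * N_CP^max."""

    threshold: float
    ncp_max: int
    points: frozenset  # of (T_star, P_star)

    def __contains__(self, tp) -> bool:
        return tuple(tp) in self.points

    def __len__(self) -> int:
        return len(self.points)


def classify_conformation(mean_NCP: float, n_residues: int) -> str:
    """'globule' when mean N_CP strictly exceeds 50% of N_CP^max, else 'coil'."""
    return "globule" if mean_NCP > 0.5 * max_contact_points(n_residues) else "coil"


def _batch_se(x: np.ndarray, n_batches: int = 20) -> float:
    """Standard error from batch means (guards against autocorrelation)."""
    n = len(x)
    if n < 2:
        return 0.0
    nb = min(n_batches, n)
    means = np.array([b.mean() for b in np.array_split(x, nb)])
    return float(means.std(ddof=1) / np.sqrt(nb))


def summarize(df: pd.DataFrame, T_star: float, P_star: float, has_wall: bool = True) -> StatePointSummary:
    """Reduce a trajectory to a state-point summary."""
    mean_se = {c: (float(df[c].mean()), _batch_se(df[c].to_numpy())) for c in
               ("N_CP", "N_HB", "N_HB_phi", "v_rel", "V_tot")}
    adsorbed = float((df["wall_contacts"] >= 1).mean()) if has_wall else float("nan")
    return StatePointSummary(
        T_star=T_star, P_star=P_star, n_samples=len(df),
        mean_N_CP=mean_se["N_CP"][0], se_N_CP=mean_se["N_CP"][1],
        mean_N_HB=mean_se["N_HB"][0], se_N_HB=mean_se["N_HB"][1],
        mean_N_HB_phi=mean_se["N_HB_phi"][0], se_N_HB_phi=mean_se["N_HB_phi"][1],
        mean_v_rel=mean_se["v_rel"][0], se_v_rel=mean_se["v_rel"][1],
        mean_V_tot=mean_se["V_tot"][0], se_V_tot=mean_se["V_tot"][1],
        max_N_CP=float(df["N_CP"].max()),
        adsorbed_fraction=adsorbed,
        gas=bool(mean_se["v_rel"][0] > GAS_V_REL),
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-state-point seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed) % 2**31, int(index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def default_grid() -> list[tuple[float, float]]:
    """The standard sweep grid: P* from -0.2 to 0.6 in steps of 0.1;
    T* in steps of 0.025 below 0.2 and 0.05 above (0.05 .. 0.6)."""
    T_low = np.round(np.arange(0.05, 0.2, 0.025), 4)
    T_high = np.round(np.arange(0.2, 0.6001, 0.05), 4)
    T_vals = np.concatenate([T_low, T_high])
    P_vals = np.round(np.arange(-0.2, 0.6001, 0.1), 4)
    return [(float(t), float(p)) for p in P_vals for t in T_vals]


def sweep_phase_diagram(
    grid,
    template: RunConfig,
    params: ModelParams | None = None,
    progress: bool = False,
) -> list[StatePointSummary]:
    """One summary per (T*, P*) grid point.

    Each point runs with an independent seed derived deterministically from
    the template's master seed and the grid index, so results do not depend
    on evaluation order.
    """
    if len(grid) == 0:
        raise ValueError("empty state-point grid")
    summaries = []
    for idx, point in enumerate(grid):
        T, P = (point.T_star, point.P_star) if hasattr(point, "T_star") else point
        cfg = replace(template, T_star=float(T), P_star=float(P),
                      seed=derive_seed(template.seed, idx))
        df = run_simulation(cfg, params=params)
        summaries.append(summarize(df, float(T), float(P), has_wall=cfg.wall))
        if progress:
            print(f"[{idx + 1}/{len(grid)}] T*={T:.3f} P*={P:.2f} "
                  f"<N_CP>={summaries[-1].mean_N_CP:.2f} <v>={summaries[-1].mean_v_rel:.3f}")
    return summaries


def stability_regions(
    summaries,
    thresholds=DEFAULT_THRESHOLDS,
    n_residues: int = 36,
) -> dict[float, StabilityRegion]:
    """Stability regions at each threshold fraction of N_CP^max (nested)."""
    ncp_max = max_contact_points(n_residues)
    regions = {}
    for thr in sorted(thresholds):
        pts = frozenset(
            (s.T_star, s.P_star) for s in summaries if s.mean_N_CP > thr * ncp_max
        )
        regions[thr] = StabilityRegion(threshold=thr, ncp_max=ncp_max, points=pts)
    return regions


def detect_spinodal(summaries, criterion: str = "either") -> float | None:
    """Lowest T* at which the confined liquid destabilizes to gas at fixed P*.

    ``summaries`` must share one pressure; they are sorted by temperature.
    The gas criterion is a mean cell volume beyond the HB-breaking value
    (v/v0 > 2) or a relative jump in the mean total volume between adjacent
    temperatures exceeding 50% (``criterion``: 'volume', 'jump' or 'either').
    Returns None when the liquid survives the whole scan.
    """
    if criterion not in ("volume", "jump", "either"):
        raise ValueError(f"unknown spinodal criterion {criterion!r}")
    ss = sorted(summaries, key=lambda s: s.T_star)
    if len({round(s.P_star, 6) for s in ss}) > 1:
        raise ValueError("spinodal detection expects summaries at a single pressure")
    prev = None
    for s in ss:
        if criterion in ("volume", "either") and s.mean_v_rel > GAS_V_REL:
            return s.T_star
        if (
            criterion in ("jump", "either")
            and prev is not None
            and prev.mean_V_tot > 0
            and (s.mean_V_tot - prev.mean_V_tot) / prev.mean_V_tot > VOLUME_JUMP
        ):
            return s.T_star
        prev = s
    return None


def adsorption_metrics(df: pd.DataFrame, has_wall: bool = True) -> dict[str, float]:
    """Adsorbed fraction, mean wall-contact count, mean centre-of-mass height.

    A sample is adsorbed iff at least one residue is lattice-adjacent to a
    wall cell.  Raises if the geometry has no walls.
    """
    if not has_wall:
        raise ValueError("adsorption metrics require a slit pore with walls")
    return {
        "adsorbed_fraction": float((df["wall_contacts"] >= 1).mean()),
        "mean_wall_contacts": float(df["wall_contacts"].mean()),
        "mean_com_height": float(df["com_height"].mean()),
    }


def export_fields(state: SystemState):
    """Per-cell bonded-edge counts and the tagged HB edge list of one snapshot.

    Returns ``(counts, edges)``: ``counts`` is an (L, L) int array of how many
    of each water cell's four faces carry an HB (0 everywhere once the volume
    switch breaks bonding); ``edges`` is a DataFrame with columns
    x1, y1, x2, y2, kind ('shell' when both partners are hydration-shell
    water, else 'bulk').  Dense HB-free regions in this export correspond to
    the high-density regions of the rendered water field.
    """
    L = state.spec.L
    occ, sigma, shell = state.occ, state.sigma, state.shell
    counts = np.zeros((L, L), dtype=np.int64)
    rows = []
    if state.n:
        for x in range(L):
            for y in range(L):
                if occ[x, y] != WATER:
                    continue
                for d in (0, 2):
                    nx = (x + int(DIRX[d])) % L
                    ny = (y + int(DIRY[d])) % L
                    if occ[nx, ny] == WATER and sigma[x, y, d] == sigma[nx, ny, OPP[d]]:
                        counts[x, y] += 1
                        counts[nx, ny] += 1
                        kind = "shell" if (shell[x, y] and shell[nx, ny]) else "bulk"
                        rows.append((x, y, nx, ny, kind))
    edges = pd.DataFrame(rows, columns=["x1", "y1", "x2", "y2", "kind"])
    return counts, edges
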