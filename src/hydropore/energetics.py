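"""Water energetics on the compressible monolayer: van der Waals term,
hydrogen-bond counting with q-state bonding indices, cooperativity, volume
and enthalpy.

Model summary
-------------
Every cell shares a single global geometric volume ``v >= v0`` (``v0`` is the
van der Waals volume of one water molecule), so the nearest-neighbour spacing
is ``l = r0 (v/v0)^(1/3)`` with ``r0 = v0^(1/3)``.  Water-water pairs interact
through a truncated 12-6 van der Waals curve with well depth ``eps``
(hard core below ``r0``, zero beyond ``6 r0``).

Each water molecule carries four q-state bonding indices (default ``q = 6``,
encoding the 30-degree angular tolerance of a hydrogen bond: only 1/q of the
relative orientations bond).  A hydrogen bond (HB) forms on a
nearest-neighbour water pair when the two facing indices match and the global
volume still permits bonding (``v/v0 < 2``, i.e. O-O distance below
``r_max = r0 * 2^(1/3) = 3.65 A``).  Each HB adds a volume ``v_HB`` (default
``v0/2``).  A many-body cooperative term rewards equal pairs of bonding
indices on the same molecule (coupling ``J_sigma``), driving the open
four-coordinated network at low temperature.

Water in the hydration shell of a hydrophobic solute (chain residues or the
pore wall) forms stronger HBs (extra coupling ``dJ_phi = 0.83 J``) of reduced
volume: each shell HB contributes ``v_HB (1 - k1 P)`` instead of ``v_HB``,
modelling the larger compressibility of hydrophobic hydration water.

All energies are expressed in units of ``4 eps``, volumes in units of ``v0``,
with reduced temperature ``T* = kB T / 4 eps`` and pressure
``P* = P v0 / 4 eps``.

Everything here is straightforward NumPy and serves as the full-recomputation
oracle against which the incremental bookkeeping of the Monte Carlo kernels is
verified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import MAX_PAIR_DISTANCE, WATER

#: bonding-index direction order: +x, -x, +y, -y; OPPOSITE[d] faces d.
DIR_DX = (1, -1, 0, 0)
DIR_DY = (0, 0, 1, -1)
OPPOSITE = (1, 0, 3, 2)


@dataclass(frozen=True)
class ModelParams:
    """Couplings and geometric constants, in reduced units.

    Attributes
    ----------
    J_rel : float
        Two-body HB coupling in units of 4 eps.
    Jsigma_rel : float
        Cooperative (many-body) coupling in units of 4 eps.
    vHB_rel : float
        Volume added per HB, in units of v0.
    dJphi_rel : float
        Hydration-shell HB bonus as a fraction of J.
    k1_rel : float
        Shell-HB compressibility factor (k1 = v0/4eps, i.e. 1 in reduced units).
    q : int
        Number of bonding states per index.
    eps_rel : float
        van der Waals well depth in units of 4 eps (0.25 by definition).
    r0_rel, cutoff_rel : float
        Hard-core distance and cutoff, in units of r0.
    eps_kJmol : float
        Physical well depth, used only for unit conversion.
    """

    J_rel: float = 0.3
    Jsigma_rel: float = 0.05
    vHB_rel: float = 0.5
    dJphi_rel: float = 0.83
    k1_rel: float = 1.0
    q: int = 6
    eps_rel: float = 0.25
    r0_rel: float = 1.0
    cutoff_rel: float = 6.0
    eps_kJmol: float = 5.8

    def __post_init__(self) -> None:
        if min(self.J_rel, self.Jsigma_rel, self.dJphi_rel, self.vHB_rel) < 0:
            raise ValueError("couplings and volumes must be non-negative")
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.cutoff_rel <= self.r0_rel:
            raise ValueError("cutoff must exceed the hard-core distance")

    @property
    def dJphi_abs(self) -> float:
        """Shell HB bonus in units of 4 eps (dJphi_rel * J_rel)."""
        return self.dJphi_rel * self.J_rel


@dataclass(frozen=True)
class ThermoState:
    """Reduced temperature and pressure of the NPT ensemble."""

    T_star: float
    P_star: float = 0.0

    def __post_init__(self) -> None:
        if self.T_star <= 0:
            raise ValueError("T_star must be positive")


@dataclass(frozen=True)
class VolumeState:
    """The single global cell volume and its derived quantities."""

    v_rel: float = 1.0

    def __post_init__(self) -> None:
        if self.v_rel < 1.0:
            raise ValueError("v/v0 must be >= 1 (hard core)")

    @property
    def n(self) -> int:
        """HB permission switch theta(v0/v - 1/2): bonds break beyond v/v0 = 2."""
        return hb_permitted(self)

    @property
    def l_rel(self) -> float:
        """Nearest-neighbour spacing in units of r0."""
        return self.v_rel ** (1.0 / 3.0)


@dataclass
class EnergyBreakdown:
    """All extensive pieces of the enthalpy of one microstate (reduced units)."""

    U_vdw: float
    N_HB: int
    N_HB_phi: int
    N_sigma: int
    V_tot: float
    H: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def hb_permitted(vol: VolumeState) -> int:
    """1 while the cell volume still allows bonding (v/v0 < 2), else 0.

    The boundary v/v0 = 2 (O-O distance exactly r_max) is taken as non-bonding:
    the Heaviside convention is a measure-zero choice and is fixed here once.
    """
    return 1 if vol.v_rel < 2.0 else 0


def _facing_matches(sigma: np.ndarray, occ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean match masks for the +x and +y face pairings (each pair once)."""
    water = occ == WATER
    # pair (cell, +x face) with (right neighbour, -x face); same for +y
    right = np.roll(water, -1, axis=0)
    up = np.roll(water, -1, axis=1)
    mx = water & right & (sigma[:, :, 0] == np.roll(sigma[:, :, 1], -1, axis=0))
    my = water & up & (sigma[:, :, 2] == np.roll(sigma[:, :, 3], -1, axis=1))
    return mx, my


def count_hbonds(sigma: np.ndarray, occ: np.ndarray, vol: VolumeState) -> int:
    """Total HB count: matched facing indices on NN water pairs, gated by the volume switch."""
    if not hb_permitted(vol):
        return 0
    mx, my = _facing_matches(sigma, occ)
    return int(mx.sum() + my.sum())


def count_shell_hbonds(
    sigma: np.ndarray, shell: np.ndarray, occ: np.ndarray, vol: VolumeState
) -> int:
    """HBs whose two water partners both lie in the hydration shell."""
    if not hb_permitted(vol):
        return 0
    mx, my = _facing_matches(sigma, occ)
    sx = shell & np.roll(shell, -1, axis=0)
    sy = shell & np.roll(shell, -1, axis=1)
    return int((mx & sx).sum() + (my & sy).sum())


def count_cooperative(sigma: np.ndarray, occ: np.ndarray) -> int:
    """Cooperative pair count: equal pairs among each water molecule's four indices."""
    water = occ == WATER
    total = 0
    for a in range(4):
        for b in range(a + 1, 4):
            total += int((water & (sigma[:, :, a] == sigma[:, :, b])).sum())
    return total


def pair_potential(r_rel: np.ndarray | float, params: ModelParams) -> np.ndarray | float:
    """Truncated 12-6 van der Waals curve in units of 4 eps, distance in units of r0.

    Hard core (infinite) below r0; zero at and beyond the cutoff.  With
    ``eps_rel = 0.25`` the well depth is exactly eps.
    """
    r = np.asarray(r_rel, dtype=float)
    out = np.zeros_like(r)
    inside = (r >= params.r0_rel) & (r < params.cutoff_rel)
    x6 = (params.r0_rel / r[inside]) ** 6
    out[inside] = 4.0 * params.eps_rel * (x6 * x6 - x6)
    if np.any(r < params.r0_rel):
        raise ValueError("hard-core violation: pair distance below r0")
    return out if out.ndim else float(out)


def vdw_energy(pair_counts: np.ndarray, vol: VolumeState, params: ModelParams) -> float:
    """van der Waals energy from the water-pair distance table (units of 4 eps)."""
    d2 = np.arange(1, MAX_PAIR_DISTANCE**2 + 1)
    counts = np.asarray(pair_counts[1:], dtype=float)
    r = vol.l_rel * np.sqrt(d2)
    return float(np.sum(counts * pair_potential(r, params)))


def total_volume(
    n_cells: int,
    vol: VolumeState,
    N_HB: int,
    N_HB_phi: int,
    thermo: ThermoState,
    params: ModelParams,
) -> float:
    """Total volume in units of v0.

    All ``n_cells`` cells share the geometric volume v; each HB adds v_HB;
    each hydration-shell HB is corrected by -k1 P v_HB (applied as written at
    every P, including tension, where it enlarges the shell-HB volume).
    """
    return (
        n_cells * vol.v_rel
        + params.vHB_rel * N_HB
        - params.k1_rel * thermo.P_star * params.vHB_rel * N_HB_phi
    )


def enthalpy(
    U_vdw: float,
    N_HB: int,
    N_HB_phi: int,
    N_sigma: int,
    V_tot: float,
    thermo: ThermoState,
    params: ModelParams,
) -> float:
    """Total enthalpy H = U_vdw - J N_HB - Jsigma N_sigma - dJphi N_HB_phi + P V_tot.

    The chain is an excluded-volume homopolymer: its residue-residue and
    residue-water energy couplings are identically zero, so no explicit chain
    term appears (the interface accepts only the hydrophobic sequence).
    """
    return (
        U_vdw
        - params.J_rel * N_HB
        - params.Jsigma_rel * N_sigma
        - params.dJphi_abs * N_HB_phi
        + thermo.P_star * V_tot
    )


def sigma_move_enthalpy_delta(
    dN_HB: int, dN_HB_phi: int, dN_sigma: int, thermo: ThermoState, params: ModelParams
) -> float:
    """Enthalpy change of a bonding-index move from its count deltas.

    Includes the mandatory PV coupling: each HB changes the volume by v_HB and
    each shell HB by an additional -k1 P v_HB; this is the model's mechanism
    for pressure effects on the HB network.
    """
    dV = params.vHB_rel * dN_HB - params.k1_rel * thermo.P_star * params.vHB_rel * dN_HB_phi
    return (
        -params.J_rel * dN_HB
        - params.dJphi_abs * dN_HB_phi
        - params.Jsigma_rel * dN_sigma
        + thermo.P_star * dV
    )


def full_breakdown(
    occ: np.ndarray,
    sigma: np.ndarray,
    shell: np.ndarray,
    pair_counts: np.ndarray,
    vol: VolumeState,
    thermo: ThermoState,
    params: ModelParams,
) -> EnergyBreakdown:
    """Recompute every enthalpy component from scratch for one microstate."""
    N_HB = count_hbonds(sigma, occ, vol)
    N_HB_phi = count_shell_hbonds(sigma, shell, occ, vol)
    N_sigma = count_cooperative(sigma, occ)
    U = vdw_energy(pair_counts, vol, params)
    n_cells = occ.shape[0] * occ.shape[1]
    V = total_volume(n_cells, vol, N_HB, N_HB_phi, thermo, params)
    H = enthalpy(U, N_HB, N_HB_phi, N_sigma, V, thermo, params)
    return EnergyBreakdown(U_vdw=U, N_HB=N_HB, N_HB_phi=N_HB_phi, N_sigma=N_sigma, V_tot=V, H=H)
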