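"""Conversion between reduced and physical units.

The energy unit is 4*eps with eps = 5.8 kJ/mol, the length unit is
r0 = v0^(1/3) = 2.9 A.  Reduced temperature and pressure are
T* = kB T / 4 eps and P* = P v0 / 4 eps.
"""

from __future__ import annotations

EPS_KJ_MOL = 5.8
R0_ANGSTROM = 2.9
KB_KJ_MOL_K = 0.008314462618
AVOGADRO = 6.02214076e23

FOUR_EPS_KJ_MOL = 4.0 * EPS_KJ_MOL
V0_ANGSTROM3 = R0_ANGSTROM**3


def temperature_kelvin(T_star: float) -> float:
    """Physical temperature corresponding to reduced T* = kB T / 4 eps."""
    return T_star * FOUR_EPS_KJ_MOL / KB_KJ_MOL_K


def pressure_pascal(P_star: float) -> float:
    """Physical pressure corresponding to reduced P* = P v0 / 4 eps."""
    four_eps_joule = FOUR_EPS_KJ_MOL * 1e3 / AVOGADRO
    v0_m3 = V0_ANGSTROM3 * 1e-30
    return P_star * four_eps_joule / v0_m3


def hb_breaking_distance_angstrom() -> float:
    """O-O distance r_max beyond which a hydrogen bond is considered broken.

    Solves (r0/r)^3 = 1/2, i.e. r_max = r0 * 2^(1/3) ~= 3.65 A.
    """
    return R0_ANGSTROM * 2.0 ** (1.0 / 3.0)
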