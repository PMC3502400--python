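"""Carrier transport of glucose/lactate and lumped intracellular metabolism.

Transport between interstitium, astrocyte and neuron goes through symmetric
saturable carriers (GLUT for glucose, MCT for lactate), antisymmetric under
swapping source and destination and bounded by T_max.  Inside each cell a
lumped pathway converts glucose to pyruvate (glycolysis, 1 -> 2), LDH
interconverts pyruvate and lactate (astrocytic kinetics favour lactate
export, neuronal kinetics favour lactate oxidation), and the TCA step burns
pyruvate into ATP with a lumped yield, throttled by an ATP cap.  Oxygen is
assumed unlimited.  Both Na+/K+ pumps consume ATP in strict proportion to
their cycle rate.
"""

from __future__ import annotations

from numba import njit

from .params import (
    ModelParams,
    PVGLYA, PKGLYA, PVGLYN, PKGLYN, PLDHFA, PLDHRA, PLDHFN, PLDHRN,
    PVTCAN, PKTCAN, PYATPN, PATPMAXN, PVTCAA, PKTCAA, PYATPA, PATPMAXA,
    PEPSATPN, PEPSATPA,
)

__all__ = ["carrier_flux", "intracellular_metabolism_rhs",
           "atp_consumption_flux"]


@njit(cache=True)
def _mm(c: float, k: float) -> float:
    return c / (c + k) if c > 0.0 else 0.0


@njit(cache=True)
def _carrier(c_src, c_dst, t_max, k_t):
    return t_max * (_mm(c_src, k_t) - _mm(c_dst, k_t))


@njit(cache=True)
def _cell_metabolism(glc, lac, pyr, atp, v_gly, k_gly, ldh_f, ldh_r,
                     v_tca, k_tca, y_atp, atp_max):
    """Derivatives of (Glc, Lac, Pyr, ATP) from internal conversions only.

    The energy-state factor ``cap = 1 - ATP/ATP_max`` throttles glycolysis,
    lactate oxidation and the TCA step alike (a lumped Pasteur-type
    feedback), so carbon consumption tracks demand.
    """
    cap = 1.0 - atp / atp_max
    if cap < 0.0:
        cap = 0.0
    j_gly = v_gly * _mm(glc, k_gly) * cap
    j_ldh = ldh_f * max(pyr, 0.0) - ldh_r * max(lac, 0.0) * cap
    j_tca = v_tca * _mm(pyr, k_tca) * cap
    dglc = -j_gly
    dpyr = 2.0 * j_gly - j_ldh - j_tca
    dlac = j_ldh
    datp = y_atp * j_tca
    return dglc, dlac, dpyr, datp


def carrier_flux(c_src: float, c_dst: float, t_max: float,
                 k_t: float) -> float:
    """Net saturable carrier flux (mM/s), positive from src to dst.

    ``T_max * (S/(S+K_t) - D/(D+K_t))``: antisymmetric under argument
    swap, zero at equal concentrations, and bounded by T_max in magnitude.
    """
    if c_src < 0.0 or c_dst < 0.0:
        raise ValueError("carrier concentrations must be non-negative")
    if t_max <= 0.0 or k_t <= 0.0:
        raise ValueError("T_max and K_t must be positive")
    return _carrier(c_src, c_dst, t_max, k_t)


def intracellular_metabolism_rhs(cell: str, glc: float, lac: float,
                                 pyr: float, atp: float,
                                 params: ModelParams):
    """Derivatives of (Glc, Lac, Pyr, ATP) for ``cell`` in {"neuron",
    "astrocyte"} from the lumped glycolysis/LDH/TCA pathway (no transport,
    no pump cost)."""
    p = params.vector()
    if cell == "neuron":
        return _cell_metabolism(glc, lac, pyr, atp, p[PVGLYN], p[PKGLYN],
                                p[PLDHFN], p[PLDHRN], p[PVTCAN], p[PKTCAN],
                                p[PYATPN], p[PATPMAXN])
    if cell == "astrocyte":
        return _cell_metabolism(glc, lac, pyr, atp, p[PVGLYA], p[PKGLYA],
                                p[PLDHFA], p[PLDHRA], p[PVTCAA], p[PKTCAA],
                                p[PYATPA], p[PATPMAXA])
    raise ValueError(f"unknown cell {cell!r}")


def atp_consumption_flux(pump_cycle_neuron: float, pump_cycle_astro: float,
                         params: ModelParams) -> tuple[float, float]:
    """(dATP_n/dt, dATP_a/dt) consumption terms, both <= 0 (uM/s).

    Strictly proportional to the respective pump cycle rates (1 ATP per
    3 Na+ / 2 K+ cycle); the proportionality constants are lumped yields
    on the effective ATP pools.  The pump's own Michaelis-Menten ATP
    dependence is what prevents the pools from being driven negative.
    """
    p = params.vector()
    return (-p[PEPSATPN] * max(pump_cycle_neuron, 0.0),
            -p[PEPSATPA] * max(pump_cycle_astro, 0.0))
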