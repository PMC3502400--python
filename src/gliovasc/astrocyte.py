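"""Astrocytic transduction: glutamate -> IP3 -> store Ca2+ -> EET.

The astrocyte senses synaptic glutamate through mGluR (saturating Hill
transduction to IP3 production), releases Ca2+ from the endoplasmic
reticulum through IP3-gated channels with Li-Rinzel gating, and converts
supra-threshold cytosolic Ca2+ into the vasodilator EET.  EET removal is
first-order Michaelis-Menten, standing in for all diffusion/degradation.
The same module owns the reversible interstitial K+ buffer and the
Na+-coupled glutamate uptake that loads the astrocytic pump.

A deliberate unit quirk inherited from the printed model: cytosolic Ca_a is
carried on the standard Li-Rinzel numerical scale but labelled mM, so the
printed EET-production threshold of 0.1 mM is used verbatim.  Production is
exactly zero at or below the threshold (hard piecewise-linear switch).
"""

from __future__ import annotations

import math

from numba import njit

from .params import (
    ModelParams, PVIP3, PKGLUIP3, PHILLIP3, PKIP3DEG, PC0, PC1, PV1, PV2,
    PV3, PK3, PD1, PD2, PD3, PD5, PA2, PCATH, PKEET, PVMAXEET, PKMEET,
    PKBF, PKBB, PBMAX, PKABUF, PKBTH, PKBSIG, PKSIPH, PKSIPHTH,
    PVGLUUP, PKGLUUP, PNAPERGLU,
)

__all__ = [
    "ip3_rhs", "store_calcium_rhs", "eet_rhs", "k_buffer_flux",
    "glutamate_uptake_flux",
]


@njit(cache=True)
def _ip3_rhs(glu, ip3, p):
    g = max(glu, 0.0)
    hill = g ** p[PHILLIP3] / (g ** p[PHILLIP3] + p[PKGLUIP3] ** p[PHILLIP3]) \
        if g > 0.0 else 0.0
    return p[PVIP3] * hill - p[PKIP3DEG] * ip3


@njit(cache=True)
def _store_calcium_rhs(ip3, ca, h_er, p):
    """Li-Rinzel ER release / leak / SERCA re-uptake and slow gate."""
    ca = max(ca, 1e-12)
    ca_er = (p[PC0] - ca) / p[PC1]
    m_inf = ip3 / (ip3 + p[PD1])
    n_inf = ca / (ca + p[PD5])
    j_chan = p[PC1] * p[PV1] * (m_inf * n_inf * h_er) ** 3 * (ca_er - ca)
    j_leak = p[PC1] * p[PV2] * (ca_er - ca)
    j_serca = p[PV3] * ca * ca / (ca * ca + p[PK3] * p[PK3])
    dca = j_chan + j_leak - j_serca
    q2 = p[PD2] * (ip3 + p[PD1]) / (ip3 + p[PD3])
    dh = p[PA2] * (q2 * (1.0 - h_er) - ca * h_er)
    return dca, dh


@njit(cache=True)
def _eet_rhs(ca, eet, p):
    prod = p[PKEET] * max(ca - p[PCATH], 0.0)
    deg = p[PVMAXEET] * eet / (p[PKMEET] + eet) if eet > 0.0 else 0.0
    return prod - deg


@njit(cache=True)
def _k_buffer_flux(k_o, k_buf, atp_a, p):
    """Net astrocytic K+ uptake (interstitial mM/s).

    Uptake engages sigmoidally once K_o crosses the elevated-K_o
    threshold, is proportional to free buffer sites and fueled by
    astrocytic ATP (saturable gate); unbinding stays passive, so
    buffered K+ is slowly returned once activity ceases.
    """
    free = (p[PBMAX] - k_buf) / p[PBMAX]
    if free < 0.0:
        free = 0.0
    f_atp = atp_a / (atp_a + p[PKABUF]) if atp_a > 0.0 else 0.0
    x = (k_o - p[PKBTH]) / p[PKBSIG]
    if x > 40.0:
        sig = 1.0
    elif x < -40.0:
        sig = 0.0
    else:
        sig = 1.0 / (1.0 + math.exp(-x))
    return p[PKBF] * f_atp * sig * free - p[PKBB] * k_buf


@njit(cache=True)
def _k_siphon_flux(k_o, p):
    """Perivascular K+ clearance (mM/s): threshold-linear, zero in the
    physiological range, engaging only during pathological elevations."""
    if k_o <= p[PKSIPHTH]:
        return 0.0
    return p[PKSIPH] * (k_o - p[PKSIPHTH])


@njit(cache=True)
def _glu_uptake(glu, p):
    if glu <= 0.0:
        return 0.0
    return p[PVGLUUP] * glu / (glu + p[PKGLUUP])


def ip3_rhs(glu_syn: float, ip3: float, params: ModelParams) -> float:
    """dIP3/dt (uM/s): saturating mGluR production, first-order decay.

    With no synaptic glutamate the derivative is strictly negative for any
    positive IP3 (pure degradation), and zero at IP3 = 0.
    """
    return _ip3_rhs(glu_syn, ip3, params.vector())


def store_calcium_rhs(ip3: float, ca_a: float, h_er: float,
                      params: ModelParams) -> tuple[float, float]:
    """(dCa_a/dt, dh_ER/dt) for the IP3-gated store.

    Sustained IP3 above the oscillation threshold produces limit-cycle
    Ca2+ pulses; the slow inactivation gate h_ER is what delays release
    after an IP3 rise.
    """
    return _store_calcium_rhs(ip3, ca_a, h_er, params.vector())


def eet_rhs(ca_a: float, eet: float, params: ModelParams) -> float:
    """dEET/dt (uM/s): threshold-linear production, Michaelis-Menten removal.

    Production is gain * max(Ca_a - threshold, 0): exactly zero at or
    below the printed 0.1 mM threshold.
    """
    return _eet_rhs(ca_a, eet, params.vector())


def k_buffer_flux(k_o: float, k_buf: float, params: ModelParams,
                  atp_a: float | None = None) -> float:
    """Net interstitial K+ uptake by the astrocytic buffer (mM/s).

    Reversible binding to a finite buffer whose uptake limb is fueled by
    astrocytic ATP (``atp_a`` defaults to the reference 20 uM); the
    flux-zero locus defines the plateau the buffer drives interstitial
    K+ toward after a firing episode.
    """
    if atp_a is None:
        atp_a = params.neuron.ATP_ref
    return _k_buffer_flux(k_o, k_buf, atp_a, params.vector())


def buffer_equilibrium_ko(k_buf: float, params: ModelParams,
                          atp_a: float | None = None) -> float:
    """Interstitial K+ at which the buffer flux vanishes, given occupancy."""
    if atp_a is None:
        atp_a = params.neuron.ATP_ref
    p = params.vector()
    free = max((p[PBMAX] - k_buf) / p[PBMAX], 1e-12)
    f_atp = atp_a / (atp_a + p[PKABUF])
    target = p[PKBB] * k_buf / (p[PKBF] * f_atp * free)
    if not 0.0 < target < 1.0:
        return float("nan")
    return p[PKBTH] + p[PKBSIG] * math.log(target / (1.0 - target))


def glutamate_uptake_flux(glu_syn: float, na_a: float,
                          params: ModelParams) -> tuple[float, float]:
    """(glutamate uptake rate, Na+ co-transport rate), both mM/s.

    Saturable uptake with a fixed Na+:glutamate stoichiometry; the Na+
    load is what drives the astrocytic Na+/K+ pump and hence astrocytic
    ATP consumption.
    """
    if glu_syn < 0.0 or na_a < 0.0:
        raise ValueError("concentrations must be non-negative")
    p = params.vector()
    up = _glu_uptake(glu_syn, p)
    return up, p[PNAPERGLU] * up


def ca_rest_fixed_point(params: ModelParams, ip3: float = 0.0) -> tuple[float, float]:
    """Numerically solve the (Ca_a, h_ER) fixed point at a given IP3."""
    from scipy.optimize import brentq

    p = params.vector()

    def dca_at(ca: float) -> float:
        q2 = p[PD2] * (ip3 + p[PD1]) / (ip3 + p[PD3])
        h = q2 / (q2 + ca)
        dca, _ = _store_calcium_rhs(ip3, ca, h, p)
        return dca

    ca = brentq(dca_at, 1e-6, p[PC0] / (1.0 + p[PC1]) - 1e-6, xtol=1e-12)
    q2 = p[PD2] * (ip3 + p[PD1]) / (ip3 + p[PD3])
    return ca, q2 / (q2 + ca)
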