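"""Single-compartment excitable membrane with ion bookkeeping.

The membrane is Hodgkin-Huxley-like with two essential departures from the
classical model: (i) the Na+ and K+ reversal potentials are recomputed from
the instantaneous intracellular/interstitial concentrations through the
Nernst relation at 37 degC, and (ii) the K+-channel time constant tau_n is
multiplied by a factor ``k_tau`` >= 1, slowing K+ kinetics enough to bring
the firing rate into the gamma band (20-80 Hz).  An ATP-dependent
Na+/K+-ATPase with exact 3:2 stoichiometry couples the membrane to the
metabolic arm of the loop, and the leak is split into Na+- and K+-specific
components so that every charge moved across the membrane appears in the
concentration balance (Kager-style bookkeeping).

All rate functions use millivolts and seconds; HH rate constants, written
per millisecond in the classical parameterisation, are scaled by 1000.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import BODY_TEMP, rt_over_f
from .params import (
    ModelParams, PCM, PGNA, PGK, PGNAL, PGKL, PKTAU, PPMAX, PKAP, PKNAP,
    PKKP, PGAMN, PGAMO, PT,
)

__all__ = [
    "nernst_potential", "pump_currents", "membrane_rhs", "ion_balance_rhs",
    "alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_n", "beta_n",
    "m_inf", "h_inf", "n_inf",
]

_MS = 1000.0  # classical HH rates are per ms; the model runs in seconds


# --- gating kinetics (classical HH parameterisation, rest near -65 mV) ---
@njit(cache=True)
def alpha_m(v: float) -> float:
    x = v + 40.0
    if abs(x) < 1e-7:
        return 1.0
    return 0.1 * x / (1.0 - math.exp(-x / 10.0))


@njit(cache=True)
def beta_m(v: float) -> float:
    return 4.0 * math.exp(-(v + 65.0) / 18.0)


@njit(cache=True)
def alpha_h(v: float) -> float:
    return 0.07 * math.exp(-(v + 65.0) / 20.0)


@njit(cache=True)
def beta_h(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))


@njit(cache=True)
def alpha_n(v: float) -> float:
    x = v + 55.0
    if abs(x) < 1e-7:
        return 0.1
    return 0.01 * x / (1.0 - math.exp(-x / 10.0))


@njit(cache=True)
def beta_n(v: float) -> float:
    return 0.125 * math.exp(-(v + 65.0) / 80.0)


@njit(cache=True)
def m_inf(v: float) -> float:
    a = alpha_m(v)
    return a / (a + beta_m(v))


@njit(cache=True)
def h_inf(v: float) -> float:
    a = alpha_h(v)
    return a / (a + beta_h(v))


@njit(cache=True)
def n_inf(v: float) -> float:
    a = alpha_n(v)
    return a / (a + beta_n(v))


# --- Nernst potential ----------------------------------------------------
@njit(cache=True)
def _nernst(valence: float, c_out: float, c_in: float, temperature: float) -> float:
    return (1000.0 * 8.314462618 * temperature
            / (valence * 96485.33212)) * math.log(c_out / c_in)


def nernst_potential(valence: int, c_out: float, c_in: float,
                     temperature: float = BODY_TEMP, ion: str = "ion") -> float:
    """Equilibrium (reversal) potential of one ionic species, in mV.

    Parameters
    ----------
    valence : int
        Ionic charge number (+1 for Na+/K+); must be non-zero.
    c_out, c_in : float
        Interstitial and intracellular concentrations (mM); must be > 0.
    temperature : float
        Absolute temperature in K.  The model is isothermal at 310.15 K.
    ion : str
        Name used in error messages.

    Returns
    -------
    float
        (R*T)/(z*F) * ln(c_out/c_in) in millivolts.
    """
    if valence == 0:
        raise ValueError("valence must be non-zero")
    if c_out <= 0.0 or c_in <= 0.0:
        raise ValueError(
            f"non-positive concentration for {ion}: "
            f"c_out={c_out} mM, c_in={c_in} mM"
        )
    return _nernst(float(valence), c_out, c_in, temperature)


# --- Na+/K+-ATPase -------------------------------------------------------
@njit(cache=True)
def _pump_cycle_current(atp_n: float, na_i: float, k_o: float,
                        pump_max: float, k_atp: float, k_na: float,
                        k_k: float) -> float:
    """Per-cycle pump current (uA/cm^2): saturable in ATP, Na_i, K_o."""
    if atp_n <= 0.0 or na_i <= 0.0 or k_o <= 0.0:
        return 0.0
    f_atp = 1.0 - math.exp(-atp_n / k_atp)
    n2 = na_i * na_i
    f_na = (n2 / (n2 + k_na * k_na)) ** 3
    f_k = (k_o / (k_o + k_k)) ** 2
    return pump_max * f_atp * f_na * f_k


def pump_currents(atp_n: float, na_i: float, k_o: float,
                  params: ModelParams) -> tuple[float, float]:
    """Na+/K+-ATPase currents with exact 3:2 stoichiometry.

    Returns ``(I_pump_Na, I_pump_K)`` in uA/cm^2: an outward (positive)
    Na+ current of 3 cycle-units and an inward (negative) K+ current of
    2 cycle-units, so ``|I_pump_Na| / |I_pump_K| = 1.5`` at every state.
    Each factor of the cycle rate is saturable: exponential-saturating
    in ATP, a quadratic Michaelis-Menten in K_o after the 2-site binding,
    and a steeper sixth-order Hill term in Na_i (cooperative 3-site
    binding) that lets the pump track activity-driven intracellular Na+
    loads; the currents grow monotonically and approach an ion-limited
    maximum as ATP -> infinity.
    """
    for val, name in ((atp_n, "ATP_n"), (na_i, "Na_i"), (k_o, "K_o")):
        if val < 0.0:
            raise ValueError(f"negative concentration {name}={val}")
    p = params.vector()
    cyc = _pump_cycle_current(atp_n, na_i, k_o, p[PPMAX], p[PKAP],
                              p[PKNAP], p[PKKP])
    return 3.0 * cyc, -2.0 * cyc


# --- membrane equation ---------------------------------------------------
@njit(cache=True)
def _membrane_currents(v, m, h, n, e_na, e_k, p):
    """(I_Na_total, I_K_total) channel+leak currents in uA/cm^2."""
    i_na = (p[PGNA] * m ** 3 * h + p[PGNAL]) * (v - e_na)
    i_k = (p[PGK] * n ** 4 + p[PGKL]) * (v - e_k)
    return i_na, i_k


@njit(cache=True)
def _membrane_rhs(v, m, h, n, na_i, na_o, k_i, k_o, atp_n, i_stim, p):
    """dV/dt, dm/dt, dh/dt, dn/dt with instantaneous Nernst potentials."""
    e_na = _nernst(1.0, na_o, na_i, p[PT])
    e_k = _nernst(1.0, k_o, k_i, p[PT])
    i_na, i_k = _membrane_currents(v, m, h, n, e_na, e_k, p)
    cyc = _pump_cycle_current(atp_n, na_i, k_o, p[PPMAX], p[PKAP],
                              p[PKNAP], p[PKKP])
    i_pump_net = cyc  # +3 out, -2 in
    dv = _MS * (i_stim - i_na - i_k - i_pump_net) / p[PCM]
    dm = _MS * (alpha_m(v) * (1.0 - m) - beta_m(v) * m)
    dh = _MS * (alpha_h(v) * (1.0 - h) - beta_h(v) * h)
    dn = _MS * (alpha_n(v) * (1.0 - n) - beta_n(v) * n) / p[PKTAU]
    return dv, dm, dh, dn


def membrane_rhs(state, i_stim: float, params: ModelParams):
    """Time derivatives of (V_m, m, h, n).

    ``i_stim`` is in mA/cm^2 (the printed stimulus unit); channel currents
    are evaluated against the instantaneous Nernst potentials and dn/dt is
    slowed by the ``k_tau`` factor.  Raises on non-finite state entries,
    naming the offending field.
    """
    vals = {"V_m": state.V_m, "m": state.m, "h": state.h, "n": state.n,
            "Na_i": state.Na_i, "Na_o": state.Na_o,
            "K_i": state.K_i, "K_o": state.K_o, "ATP_n": state.ATP_n}
    for name, v in vals.items():
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite state field {name}={v}")
    if not math.isfinite(i_stim):
        raise FloatingPointError("non-finite stimulation current")
    p = params.vector()
    return _membrane_rhs(state.V_m, state.m, state.h, state.n,
                         state.Na_i, state.Na_o, state.K_i, state.K_o,
                         state.ATP_n, 1000.0 * i_stim, p)


# --- ion bookkeeping -----------------------------------------------------
@njit(cache=True)
def _ion_balance(i_na, i_k, cyc, buffer_flux, gamma_n, gamma_o):
    """Concentration derivatives from membrane currents.

    Currents in uA/cm^2 convert to concentration fluxes through the
    area-to-volume factors gamma (mM per uA/cm^2 per s, Faraday folded in).
    Outward positive current removes cations from the cell.  Interstitial
    K+ additionally loses the astrocytic buffer uptake flux.
    """
    i_pna = 3.0 * cyc
    i_pk = -2.0 * cyc
    dna_i = -gamma_n * (i_na + i_pna)
    dna_o = gamma_o * (i_na + i_pna)
    dk_i = -gamma_n * (i_k + i_pk)
    dk_o = gamma_o * (i_k + i_pk) - buffer_flux
    return dna_i, dna_o, dk_i, dk_o


def ion_balance_rhs(state, channel_currents, pump_currents, buffer_flux,
                    params: ModelParams):
    """Derivatives of (Na_i, Na_o, K_i, K_o) in mM/s.

    ``channel_currents`` and ``pump_currents`` are (Na, K) pairs in
    uA/cm^2 per unit membrane area; ``buffer_flux`` is the astrocytic K+
    uptake in interstitial mM/s.  With pump, channel and buffer as the
    only terms the total amount of each ion over neuron + interstitium
    (+ buffer for K+) is conserved, because gamma_o/gamma_n equals the
    neuron-to-interstitium volume ratio.
    """
    p = params.vector()
    i_na = channel_currents[0]
    i_k = channel_currents[1]
    cyc = pump_currents[0] / 3.0
    return _ion_balance(i_na, i_k, cyc, buffer_flux, p[PGAMN], p[PGAMO])


def reversal_potentials(na_i, na_o, k_i, k_o,
                        temperature: float = BODY_TEMP):
    """(E_Na, E_K) in mV for arrays or scalars."""
    rtf = rt_over_f(temperature)
    return rtf * np.log(np.asarray(na_o) / np.asarray(na_i)), \
        rtf * np.log(np.asarray(k_o) / np.asarray(k_i))
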