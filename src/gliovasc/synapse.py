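"""Spike-driven neuronal Ca2+ and quantal glutamate release.

Action potentials open a fast voltage-gated Ca2+ entry pathway; cytosolic
Ca2+ relaxes back to baseline first-order, so sustained firing builds a
plateau with spike-locked transients riding on it.  Release follows the
quantal scheme of the Lee lineage: a releasable vesicle-pool fraction is
consumed at a Ca2+-cooperative rate and replenished from an implicit
reserve; cleared transmitter taken up by the astrocyte accumulates in a
recycling pool that is returned to the releasable pool quantum-by-quantum
through seeded Bernoulli draws (the probabilistic recycling of the model).

Clearance is zero-order ("constant rate") with a soft clamp at zero so the
synaptic concentration can never be driven negative.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (
    ModelParams, PKCAIN, PVCAH, PVCAS, PTAUCA, PCAREST, PKREL, PKCAREL,
    PGMAX, PKREC, PKCLR, PEPSCLR,
)

__all__ = [
    "neuronal_calcium_rhs", "glutamate_release_flux",
    "glutamate_clearance_flux", "recycle_step",
]


@njit(cache=True)
def _ca_gate(v: float, v_half: float, slope: float) -> float:
    x = (v - v_half) / slope
    if x > 40.0:
        return 1.0
    if x < -40.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True)
def _calcium_rhs(v, ca_n, p):
    entry = p[PKCAIN] * _ca_gate(v, p[PVCAH], p[PVCAS])
    return entry - (ca_n - p[PCAREST]) / p[PTAUCA]


@njit(cache=True)
def _release_hill(ca_n: float, k_half: float) -> float:
    c4 = ca_n ** 4
    return c4 / (c4 + k_half ** 4)


@njit(cache=True)
def _release_flux(ca_n, r_pool, p):
    """Transmitter release rate into the cleft, mM/s."""
    if r_pool <= 0.0 or ca_n <= 0.0:
        return 0.0
    return p[PGMAX] * p[PKREL] * _release_hill(ca_n, p[PKCAREL]) * r_pool


@njit(cache=True)
def _clearance_flux(glu, p):
    """Zero-order clearance with a soft clamp: -> k_clear for Glu >> eps."""
    if glu <= 0.0:
        return 0.0
    return p[PKCLR] * glu / (glu + p[PEPSCLR])


def neuronal_calcium_rhs(v_m: float, ca_n: float,
                         params: ModelParams) -> float:
    """dCa_n/dt (uM/s): voltage-gated entry plus first-order extrusion.

    With V_m clamped at rest the entry gate is closed and Ca_n relaxes
    exponentially to its baseline fixed point.
    """
    return _calcium_rhs(v_m, ca_n, params.vector())


def glutamate_release_flux(ca_n: float, pools, params: ModelParams) -> float:
    """Quantal release rate into the synaptic cleft (mM/s).

    Fourth-order cooperative in Ca_n and proportional to the releasable
    pool fraction, so release shuts off with either empty pools or resting
    calcium.
    """
    return _release_flux(ca_n, pools.R_pool, params.vector())


def glutamate_clearance_flux(glu_syn: float, params: ModelParams) -> float:
    """Constant-rate clearance (mM/s), soft-clamped so Glu_syn >= 0."""
    if glu_syn < 0.0:
        raise ValueError("Glu_syn must be non-negative")
    return _clearance_flux(glu_syn, params.vector())


def recycle_step(r_pool: float, glu_rec: float, rng: np.random.Generator,
                 params: ModelParams) -> tuple[float, float]:
    """One probabilistic recycling event.

    Transmitter held in the astrocytic recycling pool is returned to the
    releasable pool quantum-by-quantum: each of the ``floor(U/q)`` quanta
    is returned with probability ``recycle_prob`` (one binomial draw from
    the seeded generator).  The releasable fraction is capped at 1.

    Returns the updated ``(R_pool, Glu_rec)``.
    """
    s = params.synapse
    if s.recycle_prob <= 0.0 or glu_rec < s.quantum_mM:
        return r_pool, glu_rec
    n_quanta = int(glu_rec / s.quantum_mM)
    k = rng.binomial(n_quanta, s.recycle_prob)
    if k == 0:
        return r_pool, glu_rec
    returned = k * s.quantum_mM
    headroom = (1.0 - r_pool) * s.G_max
    returned = min(returned, max(headroom, 0.0))
    return min(r_pool + returned / s.G_max, 1.0), glu_rec - returned
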