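"""Lumped vessel: EET -> smooth-muscle voltage -> radius -> metabolite flux.

EET hyperpolarizes the smooth muscle through a sigmoidal (Hill) transfer;
the membrane voltage relaxes first-order toward the EET-set target and maps
*linearly* onto lumen radius between the two printed endpoint pairs
(-30 mV, 8 um) and (-75 mV, 30 um).  Radius gates glucose and lactate
delivery by scaling the endothelial transfer coefficient.  The module also
provides the externally-forced vasomotion waveform used when the
astrocyte -> vessel branch is severed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from numba import njit

from .params import (
    ModelParams, PVSMREST, PVSMHYP, PRMIN, PRMAX, PEETMID, PEETHILL,
    PTAUSM, PGLCB, PLACB, PTGV, PKGV, PTLV, PKLV, PBASAL,
)

__all__ = [
    "VasomotionProtocol", "smooth_muscle_rhs", "radius_from_vsm",
    "vessel_metabolite_flux", "forced_radius",
]


@dataclass
class VasomotionProtocol:
    """Square-wave forced vasomotion.

    The vessel is dilated to ``dilated_radius`` for ``dilation_duration``
    seconds once per cycle of ``1/frequency`` seconds, and held at
    ``baseline_radius`` otherwise.  ``phase_offset`` shifts the first
    dilation window.
    """

    frequency: float = 0.2          # Hz
    dilation_duration: float = 0.5  # s per cycle
    dilated_radius: float = 30.0    # um
    baseline_radius: float = 8.0    # um
    phase_offset: float = 4.5       # s until the first dilation window

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.dilation_duration >= 1.0 / self.frequency:
            raise ValueError(
                "dilation window must be shorter than the cycle period"
            )

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


@njit(cache=True)
def _vsm_target(eet, p):
    if eet <= 0.0:
        s = 0.0
    else:
        eh = eet ** p[PEETHILL]
        s = eh / (eh + p[PEETMID] ** p[PEETHILL])
    target = p[PVSMREST] - (p[PVSMREST] - p[PVSMHYP]) * s
    if target < p[PVSMHYP]:
        target = p[PVSMHYP]
    elif target > p[PVSMREST]:
        target = p[PVSMREST]
    return target


@njit(cache=True)
def _smooth_muscle_rhs(eet, v_sm, p):
    return (_vsm_target(eet, p) - v_sm) / p[PTAUSM]


@njit(cache=True)
def _radius_from_vsm(v_sm, p):
    v = v_sm
    if v > p[PVSMREST]:
        v = p[PVSMREST]
    elif v < p[PVSMHYP]:
        v = p[PVSMHYP]
    frac = (p[PVSMREST] - v) / (p[PVSMREST] - p[PVSMHYP])
    return p[PRMIN] + (p[PRMAX] - p[PRMIN]) * frac


@njit(cache=True)
def _forced_radius(t, freq, dur, r_dilated, r_base, offset):
    if t < offset:
        return r_base
    period = 1.0 / freq
    phase = (t - offset) % period
    if phase < dur:
        return r_dilated
    return r_base


@njit(cache=True)
def _vessel_fluxes(radius, glc_i, lac_i, p):
    """(glucose, lactate) source into the interstitium, mM/s.

    Radius-scaled transfer coefficient against fixed blood concentrations:
    the transfer is affine in radius, from a small basal fraction at r_min
    (the constricted vessel still supplies a trickle) up to the full
    coefficient at r_max, so supply is strictly positive at r_min while
    the blood-side concentration exceeds the interstitial one.
    """
    frac = (radius - p[PRMIN]) / (p[PRMAX] - p[PRMIN])
    if frac < 0.0:
        frac = 0.0
    elif frac > 1.0:
        frac = 1.0
    scale = p[PBASAL] + (1.0 - p[PBASAL]) * frac
    j_glc = p[PTGV] * scale * (
        p[PGLCB] / (p[PGLCB] + p[PKGV]) - glc_i / (glc_i + p[PKGV]))
    j_lac = p[PTLV] * scale * (
        p[PLACB] / (p[PLACB] + p[PKLV]) - lac_i / (lac_i + p[PKLV]))
    return j_glc, j_lac


def smooth_muscle_rhs(eet: float, v_sm: float, params: ModelParams) -> float:
    """dV_SM/dt: first-order relaxation toward the EET-set target (mV/s)."""
    return _smooth_muscle_rhs(eet, v_sm, params.vector())


def radius_from_vsm(v_sm: float, params: ModelParams) -> float:
    """Lumen radius (um) from smooth-muscle voltage: the linear map.

    Affine and monotone decreasing in V_SM; hits exactly 8 um at -30 mV
    and 30 um at -75 mV, clamping outside that voltage range.
    """
    return _radius_from_vsm(v_sm, params.vector())


def vessel_metabolite_flux(radius: float, params: ModelParams,
                           glc_i: float | None = None,
                           lac_i: float | None = None):
    """(glucose, lactate) source rates into the interstitium (mM/s).

    Interstitial concentrations default to zero (maximal gradient), which
    exposes the pure radius proportionality of the transfer.
    """
    p = params.vector()
    if not p[PRMIN] <= radius <= p[PRMAX]:
        raise ValueError(f"radius {radius} um outside "
                         f"[{p[PRMIN]}, {p[PRMAX]}] um")
    return _vessel_fluxes(radius, glc_i or 0.0, lac_i or 0.0, p)


def forced_radius(t: float, protocol: VasomotionProtocol) -> float:
    """Externally-imposed radius waveform at time ``t`` (s)."""
    if t < 0.0:
        raise ValueError("t must be non-negative")
    return _forced_radius(t, protocol.frequency, protocol.dilation_duration,
                          protocol.dilated_radius, protocol.baseline_radius,
                          protocol.phase_offset)
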