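"""Coupled-loop assembly and time integration.

The 29 coupled equations (membrane, ion bookkeeping, synapse, astrocyte,
vessel, metabolism) are concatenated into one compiled right-hand side with
shared interstitial pools.  Integration uses a stiff-capable adaptive
method (LSODA by default) in short chunks; at chunk boundaries the seeded
probabilistic transmitter-recycling step is applied, which is the model's
only source of randomness.  In ``forced_vessel`` mode the radius is read
from the vasomotion protocol and the EET -> smooth-muscle branch is
severed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .errors import ConfigError, IntegrationError, SolverError
from .params import (
    ModelParams,
    PT, PGAMN, PGAMO, PPMAX, PKAP, PKNAP, PKKP, PSTIMSMOOTH,
    PKREC, PGMAX, PWI, PWA, PWN,
    PVGLYA, PKGLYA, PVGLYN, PKGLYN, PLDHFA, PLDHRA, PLDHFN, PLDHRN,
    PVTCAN, PKTCAN, PYATPN, PATPMAXN, PVTCAA, PKTCAA, PYATPA, PATPMAXA,
    PEPSATPN, PEPSATPA, PRHOA, PKNAA, PKAA, PKNALEAKA, PNAPERGLU,
    PHOUSEA,
    PTGIA, PKGIA, PTGIN, PKGIN, PTLIA, PKLIA, PTLIN, PKLIN,
    PVSMREST, PTAUSM,
)
from .state import (
    NSTATE, STATE_NAMES,
    IV, IM, IH, IN, INAI, IKI, INAO, IKO, IKBUF, ICAN, IATPN, IRPOOL,
    IGLU, IUREC, IIP3, ICAA, IHER, IEET, INAA, IATPA, IVSM,
    IGLCI, IGLCA, IGLCN, ILACI, ILACA, ILACN, IPYRA, IPYRN,
)
from .neuron import _nernst, _membrane_rhs, _membrane_currents, \
    _pump_cycle_current, _ion_balance, m_inf, h_inf, n_inf
from .synapse import _calcium_rhs, _release_flux, _clearance_flux, \
    recycle_step
from .astrocyte import _ip3_rhs, _store_calcium_rhs, _eet_rhs, \
    _k_buffer_flux, _k_siphon_flux, _glu_uptake, ca_rest_fixed_point
from .vessel import (VasomotionProtocol, _smooth_muscle_rhs,
                     _radius_from_vsm, _forced_radius, _vessel_fluxes)
from .metabolism import _carrier, _cell_metabolism

__all__ = ["ScenarioConfig", "TimeSeries", "assemble_rhs",
           "run_simulation", "scenario_library", "resting_state",
           "SCENARIO_LABELS"]

# drive-vector layout: stimulus and forced-vasomotion description
_DAMP, _DTON, _DTOFF, _DFORCED, _DFREQ, _DDUR, _DRDIL, _DRBASE, _DOFF = \
    range(9)


@njit(cache=True)
def _logistic(x: float) -> float:
    if x > 40.0:
        return 1.0
    if x < -40.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True)
def _stim_current(t, drive, smooth):
    """Stimulus in uA/cm^2, edges smoothed over ``smooth`` seconds."""
    return drive[_DAMP] * _logistic((t - drive[_DTON]) / smooth) \
        * _logistic((drive[_DTOFF] - t) / smooth)


@njit(cache=True)
def _full_rhs(t, y, p, drive):
    dy = np.zeros(NSTATE)

    v = y[IV]
    m = min(max(y[IM], 0.0), 1.0)
    h = min(max(y[IH], 0.0), 1.0)
    n = min(max(y[IN], 0.0), 1.0)
    na_i = max(y[INAI], 1e-9)
    k_i = max(y[IKI], 1e-9)
    na_o = max(y[INAO], 1e-9)
    k_o = max(y[IKO], 1e-9)
    k_buf = max(y[IKBUF], 0.0)
    ca_n = max(y[ICAN], 0.0)
    atp_n = max(y[IATPN], 0.0)
    r_pool = min(max(y[IRPOOL], 0.0), 1.0)
    glu = max(y[IGLU], 0.0)
    ip3 = max(y[IIP3], 0.0)
    ca_a = max(y[ICAA], 1e-9)
    h_er = min(max(y[IHER], 0.0), 1.0)
    eet = max(y[IEET], 0.0)
    na_a = max(y[INAA], 1e-9)
    atp_a = max(y[IATPA], 0.0)
    v_sm = y[IVSM]
    glc_i = max(y[IGLCI], 0.0)
    glc_a = max(y[IGLCA], 0.0)
    glc_n = max(y[IGLCN], 0.0)
    lac_i = max(y[ILACI], 0.0)
    lac_a = max(y[ILACA], 0.0)
    lac_n = max(y[ILACN], 0.0)
    pyr_a = max(y[IPYRA], 0.0)
    pyr_n = max(y[IPYRN], 0.0)

    # --- membrane and pump ---
    i_stim = _stim_current(t, drive, p[PSTIMSMOOTH])
    dv, dm, dh, dn = _membrane_rhs(v, m, h, n, na_i, na_o, k_i, k_o,
                                   atp_n, i_stim, p)
    dy[IV], dy[IM], dy[IH], dy[IN] = dv, dm, dh, dn
    e_na = _nernst(1.0, na_o, na_i, p[PT])
    e_k = _nernst(1.0, k_o, k_i, p[PT])
    i_na, i_k = _membrane_currents(v, m, h, n, e_na, e_k, p)
    cyc = _pump_cycle_current(atp_n, na_i, k_o, p[PPMAX], p[PKAP],
                              p[PKNAP], p[PKKP])

    # --- ion bookkeeping, buffer, astrocytic Na+ handling ---
    j_buf = _k_buffer_flux(k_o, k_buf, atp_a, p)
    dna_i, dna_o, dk_i, dk_o = _ion_balance(i_na, i_k, cyc, j_buf,
                                            p[PGAMN], p[PGAMO])
    dk_o -= _k_siphon_flux(k_o, p)  # perivascular clearance valve
    dy[IKBUF] = j_buf

    j_up = _glu_uptake(glu, p)
    cyc_a = p[PRHOA] * (atp_a / (atp_a + p[PKAA])) \
        * (na_a / (na_a + p[PKNAA])) ** 3
    j_leak_a = p[PKNALEAKA] * (na_o - na_a)
    dy[INAA] = p[PNAPERGLU] * j_up - 3.0 * cyc_a + j_leak_a
    dna_o += (3.0 * cyc_a - j_leak_a) * p[PWA] / p[PWI]

    dy[INAI], dy[INAO], dy[IKI], dy[IKO] = dna_i, dna_o, dk_i, dk_o

    # --- synapse ---
    dy[ICAN] = _calcium_rhs(v, ca_n, p)
    j_rel = _release_flux(ca_n, r_pool, p)
    j_clr = _clearance_flux(glu, p)
    dy[IRPOOL] = p[PKREC] * (1.0 - r_pool) - j_rel / p[PGMAX]
    dy[IGLU] = j_rel - j_clr - j_up
    dy[IUREC] = j_up

    # --- astrocyte signalling ---
    dy[IIP3] = _ip3_rhs(glu, ip3, p)
    dca_a, dh_er = _store_calcium_rhs(ip3, ca_a, h_er, p)
    dy[ICAA] = dca_a
    dy[IHER] = dh_er
    dy[IEET] = _eet_rhs(ca_a, eet, p)

    # --- vessel ---
    if drive[_DFORCED] > 0.5:
        radius = _forced_radius(t, drive[_DFREQ], drive[_DDUR],
                                drive[_DRDIL], drive[_DRBASE], drive[_DOFF])
        dy[IVSM] = (p[PVSMREST] - v_sm) / p[PTAUSM]  # branch severed
    else:
        dy[IVSM] = _smooth_muscle_rhs(eet, v_sm, p)
        radius = _radius_from_vsm(v_sm, p)
    j_glc_v, j_lac_v = _vessel_fluxes(radius, glc_i, lac_i, p)

    # --- carrier transport (fluxes in interstitial mM/s) ---
    j_g_ia = _carrier(glc_i, glc_a, p[PTGIA], p[PKGIA])
    j_g_in = _carrier(glc_i, glc_n, p[PTGIN], p[PKGIN])
    j_l_ia = _carrier(lac_i, lac_a, p[PTLIA], p[PKLIA])
    j_l_in = _carrier(lac_i, lac_n, p[PTLIN], p[PKLIN])
    dy[IGLCI] = j_glc_v - j_g_ia - j_g_in
    dy[ILACI] = j_lac_v - j_l_ia - j_l_in

    wi_a = p[PWI] / p[PWA]
    wi_n = p[PWI] / p[PWN]

    # --- intracellular metabolism and ATP ---
    dg_a, dl_a, dp_a, datp_a = _cell_metabolism(
        glc_a, lac_a, pyr_a, atp_a, p[PVGLYA], p[PKGLYA], p[PLDHFA],
        p[PLDHRA], p[PVTCAA], p[PKTCAA], p[PYATPA], p[PATPMAXA])
    dy[IGLCA] = j_g_ia * wi_a + dg_a
    dy[ILACA] = j_l_ia * wi_a + dl_a
    dy[IPYRA] = dp_a
    # housekeeping drain saturates in ATP_a so the pool cannot go negative
    dy[IATPA] = datp_a - p[PEPSATPA] * cyc_a \
        - p[PHOUSEA] * atp_a / (atp_a + 0.8)

    dg_n, dl_n, dp_n, datp_n = _cell_metabolism(
        glc_n, lac_n, pyr_n, atp_n, p[PVGLYN], p[PKGLYN], p[PLDHFN],
        p[PLDHRN], p[PVTCAN], p[PKTCAN], p[PYATPN], p[PATPMAXN])
    dy[IGLCN] = j_g_in * wi_n + dg_n
    dy[ILACN] = j_l_in * wi_n + dl_n
    dy[IPYRN] = dp_n
    dy[IATPN] = datp_n - p[PEPSATPN] * cyc

    return dy


# ----------------------------------------------------------------------
@dataclass
class ScenarioConfig:
    """Declarative description of one simulation run.

    ``amplitude`` is in mA/cm^2 (the printed stimulus unit); a ``pulse``
    stimulus lasts ``pulse_duration`` seconds from ``onset``, a
    ``constant`` stimulus runs to the end of the simulation.
    """

    name: str = "custom"
    stim_type: str = "constant"          # "constant" | "pulse"
    amplitude: float = 0.1               # mA/cm^2
    onset: float = 0.0                   # s
    pulse_duration: float = 1.0          # s, used when stim_type == "pulse"
    atp0: float = 20.0                   # uM initial neuronal ATP
    duration: float = 30.0               # s
    mode: str = "closed_loop"            # "closed_loop" | "forced_vessel"
    vasomotion: VasomotionProtocol | None = None
    solver_method: str = "LSODA"
    rtol: float = 1.0e-6
    atol: float = 1.0e-8
    max_step: float = 5.0e-3             # s
    seed: int = 0
    dt_sample: float = 5.0e-4            # s
    recycle_interval: float = 0.05       # s between recycling draws
    recycling: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be non-negative")
        if self.stim_type not in ("constant", "pulse"):
            raise ConfigError(f"unknown stim_type {self.stim_type!r}")
        if self.mode not in ("closed_loop", "forced_vessel"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "forced_vessel" and self.vasomotion is None:
            self.vasomotion = VasomotionProtocol()
        if self.atp0 < 0:
            raise ConfigError("atp0 must be non-negative")
        if self.dt_sample <= 0 or self.dt_sample > self.duration:
            raise ConfigError("dt_sample must be in (0, duration]")

    @property
    def stim_end(self) -> float:
        if self.stim_type == "pulse":
            return self.onset + self.pulse_duration
        return self.duration

    def drive_vector(self) -> np.ndarray:
        d = np.zeros(9)
        d[_DAMP] = 1000.0 * self.amplitude  # -> uA/cm^2
        d[_DTON] = self.onset
        d[_DTOFF] = self.stim_end if self.stim_type == "pulse" \
            else self.duration + 1.0
        if self.mode == "forced_vessel":
            vm = self.vasomotion
            d[_DFORCED] = 1.0
            d[_DFREQ] = vm.frequency
            d[_DDUR] = vm.dilation_duration
            d[_DRDIL] = vm.dilated_radius
            d[_DRBASE] = vm.baseline_radius
            d[_DOFF] = vm.phase_offset
        return d


@dataclass
class TimeSeries:
    """Sampled trajectory of the full state plus derived observables."""

    t: np.ndarray                      # (n,) strictly increasing, s
    y: np.ndarray                      # (n, NSTATE)
    config: ScenarioConfig
    params: ModelParams = field(repr=False, default_factory=ModelParams)

    def column(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES.index(name)]

    @property
    def radius(self) -> np.ndarray:
        """Lumen radius (um): protocol waveform in forced mode."""
        if self.config.mode == "forced_vessel":
            vm = self.config.vasomotion
            return np.array([_forced_radius(tt, vm.frequency,
                                            vm.dilation_duration,
                                            vm.dilated_radius,
                                            vm.baseline_radius,
                                            vm.phase_offset)
                             for tt in self.t])
        p = self.params.vector()
        return np.array([_radius_from_vsm(v, p) for v in self.y[:, IVSM]])

    def derived(self) -> dict[str, np.ndarray]:
        from .neuron import reversal_potentials

        p = self.params.vector()
        e_na, e_k = reversal_potentials(self.y[:, INAI], self.y[:, INAO],
                                        self.y[:, IKI], self.y[:, IKO],
                                        self.params.neuron.temperature)
        cyc = np.array([_pump_cycle_current(a, na, ko, p[PPMAX], p[PKAP],
                                            p[PKNAP], p[PKKP])
                        for a, na, ko in zip(self.y[:, IATPN],
                                             self.y[:, INAI],
                                             self.y[:, IKO])])
        return {"E_Na": e_na, "E_K": e_k, "I_pump_Na": 3.0 * cyc,
                "I_pump_K": -2.0 * cyc, "radius": self.radius}

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.t}
        for i, name in enumerate(STATE_NAMES):
            data[name] = self.y[:, i]
        data.update(self.derived())
        return pd.DataFrame(data)


# ----------------------------------------------------------------------
def resting_state(params: ModelParams | None = None, atp0: float = 20.0
                  ) -> np.ndarray:
    """Construct the reference resting state.

    The ionic side (V_m, gates, Na+/K+ pools, buffer occupancy) is an
    exact fixed point by parameter construction; the astrocytic Ca2+
    pair is solved numerically; metabolite pools are the documented
    near-steady values.  ``atp0`` sets the scenario's initial neuronal
    ATP — the ATP pool deliberately has no resting equilibrium.
    """
    params = params or ModelParams()
    n, a, t = params.neuron, params.astrocyte, params.transport
    ca_a, h_er = ca_rest_fixed_point(params)
    y0 = np.zeros(NSTATE)
    y0[IV] = n.V_rest
    y0[IM] = m_inf(n.V_rest)
    y0[IH] = h_inf(n.V_rest)
    y0[IN] = n_inf(n.V_rest)
    y0[INAI] = n.Na_i_rest
    y0[IKI] = n.K_i_rest
    y0[INAO] = n.Na_o_rest
    y0[IKO] = n.K_o_rest
    y0[IKBUF] = a.K_buf_rest
    y0[ICAN] = params.synapse.Ca_rest
    y0[IATPN] = atp0
    y0[IRPOOL] = 1.0
    y0[IGLU] = 0.0
    y0[IUREC] = 0.0
    y0[IIP3] = 0.0
    y0[ICAA] = ca_a
    y0[IHER] = h_er
    y0[IEET] = 0.0
    y0[INAA] = a.Na_a_rest
    y0[IATPA] = atp0  # metabolic stress is shared by neuron and astrocyte
    y0[IVSM] = params.vessel.V_SM_rest
    y0[IGLCI] = t.Glc_i0
    y0[IGLCA] = t.Glc_a0
    y0[IGLCN] = t.Glc_n0
    y0[ILACI] = t.Lac_i0
    y0[ILACA] = t.Lac_a0
    y0[ILACN] = t.Lac_n0
    y0[IPYRA] = t.Pyr_a0
    y0[IPYRN] = t.Pyr_n0
    return y0


def assemble_rhs(y: np.ndarray, t: float, config: ScenarioConfig,
                 params: ModelParams | None = None) -> np.ndarray:
    """Full derivative vector of the coupled loop at state ``y``, time ``t``.

    Deterministic in (y, t, config); raises :class:`IntegrationError`
    naming the first non-finite component if the state or the derivative
    is not finite.
    """
    params = params or ModelParams()
    y = np.asarray(y, dtype=float)
    if y.shape != (NSTATE,):
        raise ConfigError(f"state must have shape ({NSTATE},), got {y.shape}")
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        name = STATE_NAMES[bad[0]]
        raise IntegrationError(f"non-finite state component {name}", name)
    dy = _full_rhs(t, y, params.vector(), config.drive_vector())
    bad = np.flatnonzero(~np.isfinite(dy))
    if bad.size:
        name = STATE_NAMES[bad[0]]
        raise IntegrationError(f"non-finite derivative component {name}", name)
    return dy


def run_simulation(config: ScenarioConfig,
                   params: ModelParams | None = None) -> TimeSeries:
    """Integrate a scenario and return the sampled trajectory.

    Uses the configured stiff-capable adaptive solver in chunks of
    ``recycle_interval`` seconds; the seeded probabilistic recycling draw
    is applied at each chunk boundary, so runs are bit-reproducible for a
    fixed (config, seed).
    """
    params = params or ModelParams()
    p = params.vector()
    drive = config.drive_vector()
    rng = np.random.default_rng(config.seed)

    n_samp = int(round(config.duration / config.dt_sample)) + 1
    t_grid = np.linspace(0.0, config.duration, n_samp)
    y_out = np.empty((n_samp, NSTATE))

    y = resting_state(params, atp0=config.atp0)
    y_out[0] = y
    filled = 1

    def fun(t, yy):
        return _full_rhs(t, yy, p, drive)

    n_chunks = max(int(math.ceil(config.duration / config.recycle_interval)), 1)
    edges = np.linspace(0.0, config.duration, n_chunks + 1)
    for t0, t1 in zip(edges[:-1], edges[1:]):
        sel = (t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)
        t_eval = np.clip(t_grid[sel], t0, t1)  # guard float rounding
        sol = solve_ivp(fun, (t0, t1), y, method=config.solver_method,
                        t_eval=t_eval if t_eval.size else None,
                        rtol=config.rtol, atol=config.atol,
                        max_step=config.max_step)
        if not sol.success:
            raise SolverError(
                f"solver failed at t={sol.t[-1] if sol.t.size else t0:.6f} s: "
                f"{sol.message}", t_last=sol.t[-1] if sol.t.size else t0,
                state_last=sol.y[:, -1] if sol.t.size else y)
        y = sol.y[:, -1].copy()
        if not np.isfinite(y).all():
            bad = np.flatnonzero(~np.isfinite(y))[0]
            raise IntegrationError(
                f"non-finite state component {STATE_NAMES[bad]} "
                f"at t={t1:.6f} s", STATE_NAMES[bad])
        if t_eval.size:
            y_out[filled:filled + t_eval.size] = sol.y.T[:t_eval.size]
            filled += t_eval.size
        if config.recycling:
            r_new, u_new = recycle_step(y[IRPOOL], y[IUREC], rng, params)
            y[IRPOOL], y[IUREC] = r_new, u_new
    if filled != n_samp:  # pragma: no cover - defensive
        raise RuntimeError("sampling grid was not filled completely")
    return TimeSeries(t=t_grid, y=y_out, config=config, params=params)


# ----------------------------------------------------------------------
#: published firing-pattern label of each library scenario
SCENARIO_LABELS = {
    "continuous": "continuous",
    "pulse": "resting",
    "subthreshold": "pause_then_fire",
    "bursting": "bursting",
    "vasomotion": "bursting",
}


def scenario_library() -> dict[str, ScenarioConfig]:
    """The five published stimulation scenarios.

    continuous      constant 0.1 mA/cm^2, [ATP]_0 = 20 uM
    pulse           1 s pulse 0.1 mA/cm^2, [ATP]_0 = 20 uM
    subthreshold    constant 0.05 mA/cm^2, [ATP]_0 = 20 uM
    bursting        1 s pulse 0.1 mA/cm^2, [ATP]_0 = 5 uM
    vasomotion      forced vessel at 0.2 Hz (30 um for 0.5 s per cycle),
                    constant 0.1 mA/cm^2, [ATP]_0 = 5 uM
    """
    return {
        "continuous": ScenarioConfig(name="continuous", stim_type="constant",
                                     amplitude=0.1, atp0=20.0),
        "pulse": ScenarioConfig(name="pulse", stim_type="pulse",
                                amplitude=0.1, pulse_duration=1.0,
                                atp0=20.0),
        "subthreshold": ScenarioConfig(name="subthreshold",
                                       stim_type="constant",
                                       amplitude=0.05, atp0=20.0),
        "bursting": ScenarioConfig(name="bursting", stim_type="pulse",
                                   amplitude=0.1, pulse_duration=1.0,
                                   atp0=5.0),
        "vasomotion": ScenarioConfig(name="vasomotion", stim_type="constant",
                                     amplitude=0.1, atp0=5.0,
                                     mode="forced_vessel", duration=20.0,
                                     vasomotion=VasomotionProtocol()),
    }


def short_pulse_protocol() -> ScenarioConfig:
    """Protocol used to read off the gamma-band firing rate:
    a 0.1 mA/cm^2 pulse from 0.2 s to 0.4 s, from rest."""
    return ScenarioConfig(name="short_pulse", stim_type="pulse", amplitude=0.1,
                          onset=0.2, pulse_duration=0.2, duration=0.6)
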