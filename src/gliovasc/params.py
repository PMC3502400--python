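"""Model parameters.

Every rate constant, conductance and kinetic constant of the loop lives in
one of the per-compartment records below and is aggregated by
:class:`ModelParams`.  Defaults were calibrated once against the published
behaviour of the loop (gamma-band firing rate, 0.07 mA/cm^2 sustained-firing
threshold, 1.9 s sub-threshold pause, 9.5 mM interstitial K+ plateau with
E_K = -80 mV, ~6 s Na+ recovery, 1.8 / 2.5 mM synaptic glutamate peaks) and
are frozen; scenario files may override any field.

Several quantities are *derived*, not free: the Na+ and K+ leak conductances
and the backward buffer rate are solved from the requirement that the
reference resting state is an exact fixed point of the ionic subsystem (see
:func:`ModelParams.derived`), and the pump maximal rate is solved from the
prescribed resting pump current.

Units follow ``gliovasc.state``; currents are uA/cm^2, conductances mS/cm^2,
rates per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import BODY_TEMP, rt_over_f

# --- flat parameter indices (compiled kernels index into this layout) ----
PT = 0
PCM = 1
PGNA = 2
PGK = 3
PGNAL = 4
PGKL = 5
PKTAU = 6
PPMAX = 7
PKAP = 8
PKNAP = 9
PKKP = 10
PGAMN = 11
PGAMO = 12
PKBF = 13
PKBB = 14
PBMAX = 15
PKCAIN = 16
PVCAH = 17
PVCAS = 18
PTAUCA = 19
PCAREST = 20
PKREL = 21
PKCAREL = 22
PGMAX = 23
PKREC = 24
PKCLR = 25
PEPSCLR = 26
PVGLUUP = 27
PKGLUUP = 28
PNAPERGLU = 29
PVIP3 = 30
PKGLUIP3 = 31
PHILLIP3 = 32
PKIP3DEG = 33
PC0 = 34
PC1 = 35
PV1 = 36
PV2 = 37
PV3 = 38
PK3 = 39
PD1 = 40
PD2 = 41
PD3 = 42
PD5 = 43
PA2 = 44
PCATH = 45
PKEET = 46
PVMAXEET = 47
PKMEET = 48
PVSMREST = 49
PVSMHYP = 50
PRMIN = 51
PRMAX = 52
PEETMID = 53
PEETHILL = 54
PTAUSM = 55
PWI = 56
PWA = 57
PWN = 58
PGLCB = 59
PLACB = 60
PTGV = 61
PKGV = 62
PTLV = 63
PKLV = 64
PTGIA = 65
PKGIA = 66
PTGIN = 67
PKGIN = 68
PTLIA = 69
PKLIA = 70
PTLIN = 71
PKLIN = 72
PVGLYA = 73
PKGLYA = 74
PVGLYN = 75
PKGLYN = 76
PLDHFA = 77
PLDHRA = 78
PLDHFN = 79
PLDHRN = 80
PVTCAN = 81
PKTCAN = 82
PYATPN = 83
PATPMAXN = 84
PVTCAA = 85
PKTCAA = 86
PYATPA = 87
PATPMAXA = 88
PEPSATPN = 89
PRHOA = 90
PKNAA = 91
PKAA = 92
PEPSATPA = 93
PKNALEAKA = 94
PSTIMSMOOTH = 95
PBASAL = 96
PKABUF = 97
PHOUSEA = 98
PKBTH = 99
PKBSIG = 100
PKSIPH = 101
PKSIPHTH = 102

NPARAM = 103


@dataclass
class NeuronParams:
    """Membrane, pump and ion-bookkeeping constants (Kager-style lineage).

    The leak is split into Na+- and K+-specific components so that every
    leaked charge is accounted for in the concentration bookkeeping; both
    leak conductances are derived from the resting balance rather than set
    directly.  ``k_tau`` multiplies the K+-channel time constant tau_n and
    is the single knob that sets the gamma-band firing rate.
    """

    C_m: float = 1.0            # uF/cm^2
    g_Na: float = 200.0         # mS/cm^2
    g_K: float = 36.0           # mS/cm^2
    k_tau: float = 1.25         # dimensionless, >= 1
    temperature: float = BODY_TEMP

    # Na+/K+-ATPase: I_cycle = pump_rest/(rest factors) * f_ATP*f_Na*f_K,
    # 3 Na+ out : 2 K+ in per cycle, net +1 charge out.
    pump_rest_current: float = 22.0   # uA/cm^2 net pump current at reference rest
    K_ATP_pump: float = 6.0           # uM, e-folding scale of the ATP factor
    K_Na_pump: float = 20.0           # mM, Hill-6 half-point of the Na_i factor
    K_K_pump: float = 2.0             # mM

    # membrane area-to-volume conversions, mM per (uA/cm^2) per s;
    # the interstitium is a much smaller compartment than the cell, so its
    # concentrations move faster per unit current
    gamma_n: float = 0.004
    gamma_o: float = 0.035

    # reference resting state (the constructed fixed point)
    V_rest: float = -70.0       # mV
    Na_i_rest: float = 10.0     # mM
    Na_o_rest: float = 145.0    # mM
    K_i_rest: float = 190.0     # mM (chosen so E_K(-80 mV) holds at K_o = 9.5)
    K_o_rest: float = 9.5       # mM
    ATP_ref: float = 20.0       # uM, reference ATP for the rest balance

    def __post_init__(self) -> None:
        if self.k_tau < 1.0:
            raise ValueError("k_tau must be >= 1")
        for name in ("C_m", "g_Na", "g_K", "pump_rest_current",
                     "K_ATP_pump", "K_Na_pump", "K_K_pump", "gamma_n",
                     "gamma_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SynapseParams:
    """Neuronal Ca2+ entry and quantal glutamate release (Lee-style)."""

    k_Ca_in: float = 250.0      # uM/s maximal voltage-gated Ca2+ entry
    V_Ca_half: float = 0.0      # mV, half-activation of the Ca2+ gate
    V_Ca_slope: float = 5.0     # mV
    tau_Ca: float = 0.15        # s, Ca2+ extrusion time constant
    Ca_rest: float = 0.1        # uM

    k_release: float = 8.0      # 1/s maximal fractional release rate
    K_Ca_release: float = 0.55  # uM, half-activation (4th-order Hill)
    G_max: float = 2.9          # mM, fully-releasable transmitter content
    k_recover: float = 0.3      # 1/s vesicle replenishment from the reserve

    k_clear: float = 1.3        # mM/s constant-rate (zero-order) clearance
    eps_clear: float = 0.01     # mM, softening scale of the zero clamp

    # probabilistic astrocytic recycling of recovered transmitter
    recycle_prob: float = 0.05
    quantum_mM: float = 0.02    # transmitter per recycled quantum


@dataclass
class AstrocyteParams:
    """mGluR -> IP3 -> store Ca2+ -> EET transduction plus K+ buffering.

    The store model is Li-Rinzel gating in the Bennett lineage.  Note the
    deliberate unit quirk: Ca_a is carried on the standard Li-Rinzel
    numerical scale but *labelled* mM so the printed 0.1 mM EET threshold
    applies verbatim (see docs/methods.md).
    """

    v_ip3: float = 0.15         # uM/s maximal mGluR-driven IP3 production
    K_glu_ip3: float = 0.05     # mM
    hill_ip3: float = 0.7       # Hill exponent of the mGluR transduction
    k_ip3_deg: float = 0.12     # 1/s first-order IP3 degradation

    # Li-Rinzel store parameters
    c0: float = 2.0             # total free-Ca2+ equivalent
    c1: float = 0.185           # ER/cytosol volume ratio
    v1: float = 6.0             # 1/s max channel flux
    v2: float = 0.11            # 1/s leak
    v3: float = 0.9             # mM/s SERCA Vmax
    k3: float = 0.1             # mM SERCA activation
    d1: float = 0.13            # uM IP3 binding
    d2: float = 1.049           # mM Ca2+ inactivation
    d3: float = 0.9434          # uM IP3 dissociation
    d5: float = 0.08234         # mM Ca2+ activation
    a2: float = 0.2             # 1/(mM s) gate closing rate

    Ca_threshold: float = 0.1   # mM, hard EET-production threshold
    k_EET: float = 45.0         # uM EET / (mM Ca2+ s) production gain
    Vmax_EET: float = 40.0      # uM/s Michaelis-Menten EET removal
    Km_EET: float = 5.0         # uM

    # astrocytic K+ buffer: uptake engages sigmoidally above an
    # elevated-K_o threshold (glial uptake in the Kager lineage), is
    # fueled by astrocytic ATP, and unbinds passively
    k_buf_f: float = 30.0       # mM/s maximal uptake at full engagement
    B_max: float = 300.0        # mM-equivalent buffer capacity
    K_buf_rest: float = 30.0    # mM-equivalent occupancy at rest
    K_buf_th: float = 13.6      # mM, K_o half-engagement of uptake
    K_buf_sig: float = 0.35     # mM, steepness of the engagement sigmoid
    K_ATP_buf: float = 15.0     # uM, half-saturation of the ATP_a gate
    k_house_a: float = 0.7      # uM/s astrocytic housekeeping ATP drain
    # perivascular spatial-buffering siphon: removes interstitial K+ only
    # during pathological elevations, preventing unbounded accumulation
    k_siphon: float = 2.0       # 1/s
    K_siphon_th: float = 20.0   # mM, engagement threshold

    # glutamate uptake with Na+ co-transport, and the astrocytic pump
    v_glu_up: float = 1.5       # mM/s maximal uptake
    K_glu_up: float = 2.0       # mM
    na_per_glu: float = 3.0     # Na+ co-transported per glutamate
    rho_pump_a: float = 0.06    # mM/s astrocytic pump cycle rate
    K_Na_pump_a: float = 15.0   # mM
    K_ATP_pump_a: float = 3.0   # uM
    Na_a_rest: float = 15.0     # mM

    def __post_init__(self) -> None:
        if self.Ca_threshold <= 0:
            raise ValueError("Ca_threshold must be positive")
        if not 0.0 < self.K_buf_rest < self.B_max:
            raise ValueError("K_buf_rest must lie inside (0, B_max)")


@dataclass
class VesselParams:
    """Lumped smooth-muscle/radius map and radius-gated metabolite supply."""

    V_SM_rest: float = -30.0    # mV, contracted
    V_SM_hyper: float = -75.0   # mV, fully dilated
    r_min: float = 8.0          # um
    r_max: float = 30.0         # um
    EET_mid: float = 3.0        # uM, midpoint of the EET->V_SM sigmoid
    EET_hill: float = 4.0
    tau_SM: float = 4.0         # s, V_SM relaxation time constant
    basal_supply_frac: float = 0.02  # fraction of the dilated transfer at r_min

    def __post_init__(self) -> None:
        if not self.V_SM_hyper < self.V_SM_rest:
            raise ValueError("V_SM_hyper must be below V_SM_rest")
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be below r_max")


@dataclass
class TransportParams:
    """Mangia-style carrier transport and lumped intracellular metabolism.

    Carrier fluxes are symmetric saturable forms
    ``T_max * (S/(S+K_t) - D/(D+K_t))``; the vessel source scales the same
    form by radius (``r / r_max``), i.e. a radius-scaled transfer
    coefficient against fixed blood-side concentrations.  ATP yields are
    lumped calibration constants (effective pool, see docs).
    """

    # relative compartment volume fractions
    w_i: float = 0.2
    w_a: float = 0.3
    w_n: float = 0.4

    Glc_blood: float = 4.8      # mM, constant blood-side glucose
    Lac_blood: float = 3.0      # mM

    # vessel -> interstitium (per unit of r/r_max)
    T_glc_vessel: float = 0.09  # mM/s
    K_glc_vessel: float = 1.0
    T_lac_vessel: float = 0.08
    K_lac_vessel: float = 0.3

    # GLUT carriers
    T_glc_ia: float = 0.08      # interstitium <-> astrocyte
    K_glc_ia: float = 0.5
    T_glc_in: float = 0.10      # interstitium <-> neuron
    K_glc_in: float = 0.3
    # MCT carriers
    T_lac_ia: float = 0.08
    K_lac_ia: float = 0.5
    T_lac_in: float = 0.05
    K_lac_in: float = 0.2

    # lumped glycolysis (Glc -> 2 Pyr)
    v_gly_a: float = 0.03       # mM/s
    K_gly_a: float = 0.1
    v_gly_n: float = 0.03
    K_gly_n: float = 0.1

    # LDH interconversion, rate = f*Pyr - r*Lac (positive toward lactate)
    ldh_f_a: float = 0.08
    ldh_r_a: float = 0.005
    ldh_f_n: float = 0.02
    ldh_r_n: float = 0.1

    # TCA (Pyr -> ATP), production throttled by the ATP cap
    v_tca_n: float = 0.2        # mM/s
    K_tca_n: float = 0.02
    Y_atp_n: float = 150.0      # uM ATP per mM pyruvate (lumped yield)
    ATP_max_n: float = 30.0     # uM
    v_tca_a: float = 0.008
    K_tca_a: float = 0.02
    Y_atp_a: float = 150.0
    ATP_max_a: float = 100.0

    # pump ATP costs
    eps_atp_n: float = 0.0236   # uM ATP per (uA/cm^2) of net pump current per s
    eps_atp_a: float = 5.0      # uM ATP per mM of astrocytic pump cycles

    # documented near-steady resting pools (see docs/methods.md)
    Glc_i0: float = 0.02
    Glc_a0: float = 0.01
    Glc_n0: float = 0.01
    Lac_i0: float = 0.02
    Lac_a0: float = 0.02
    Lac_n0: float = 0.01
    Pyr_a0: float = 0.005
    Pyr_n0: float = 0.002
    ATP_a0: float = 20.0        # uM


@dataclass
class ModelParams:
    """Aggregate of all compartment parameter records."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    astrocyte: AstrocyteParams = field(default_factory=AstrocyteParams)
    vessel: VesselParams = field(default_factory=VesselParams)
    transport: TransportParams = field(default_factory=TransportParams)
    stim_smooth: float = 1.0e-2  # s, stimulus edge smoothing (accommodation-scale ramp)

    # ------------------------------------------------------------------
    def derived(self) -> dict:
        """Solve the rest-balance constraints.

        Returns the quantities that are functions of the free parameters:
        pump maximal cycle rate, the two leak conductances, the backward
        buffer rate, the interstitial conversion factor and the astrocytic
        Na+ leak rate.  The construction makes the reference resting state
        an exact fixed point of the ionic equations.
        """
        from . import neuron as _nrn  # deferred to avoid a cycle

        n, a, t = self.neuron, self.astrocyte, self.transport
        rtf = rt_over_f(n.temperature)
        e_na = rtf * math.log(n.Na_o_rest / n.Na_i_rest)
        e_k = rtf * math.log(n.K_o_rest / n.K_i_rest)
        v0 = n.V_rest

        f_atp = 1.0 - math.exp(-n.ATP_ref / n.K_ATP_pump)
        na2 = n.Na_i_rest ** 2
        f_na = (na2 / (na2 + n.K_Na_pump ** 2)) ** 3
        f_k = (n.K_o_rest / (n.K_o_rest + n.K_K_pump)) ** 2
        pump_max = n.pump_rest_current / (f_atp * f_na * f_k)

        p0 = n.pump_rest_current
        m0 = _nrn.m_inf(v0)
        h0 = _nrn.h_inf(v0)
        n0 = _nrn.n_inf(v0)
        i_na_hh = n.g_Na * m0 ** 3 * h0 * (v0 - e_na)
        i_k_hh = n.g_K * n0 ** 4 * (v0 - e_k)
        g_na_leak = (-3.0 * p0 - i_na_hh) / (v0 - e_na)
        g_k_leak = (2.0 * p0 - i_k_hh) / (v0 - e_k)
        if g_na_leak <= 0 or g_k_leak <= 0:
            raise ValueError(
                "rest balance yields a non-positive leak conductance; "
                "check pump_rest_current against the resting state"
            )

        f_buf0 = n.ATP_ref / (n.ATP_ref + a.K_ATP_buf)
        sig0 = 1.0 / (1.0 + math.exp(-(n.K_o_rest - a.K_buf_th) / a.K_buf_sig))
        k_buf_b = a.k_buf_f * f_buf0 * sig0 \
            * (a.B_max - a.K_buf_rest) / (a.B_max * a.K_buf_rest)

        # astrocytic Na+ leak balancing the resting astrocytic pump
        f_atp_a = n.ATP_ref / (n.ATP_ref + a.K_ATP_pump_a)
        f_na_a = (a.Na_a_rest / (a.Na_a_rest + a.K_Na_pump_a)) ** 3
        cyc_a0 = a.rho_pump_a * f_atp_a * f_na_a
        k_na_leak_a = 3.0 * cyc_a0 / (n.Na_o_rest - a.Na_a_rest)

        return {
            "pump_max": pump_max,
            "g_Na_leak": g_na_leak,
            "g_K_leak": g_k_leak,
            "k_buf_b": k_buf_b,
            "k_Na_leak_a": k_na_leak_a,
            "E_Na_rest": e_na,
            "E_K_rest": e_k,
        }

    # ------------------------------------------------------------------
    def vector(self) -> np.ndarray:
        """Flatten to the layout the compiled kernels index into."""
        n, s, a, v, t = (self.neuron, self.synapse, self.astrocyte,
                         self.vessel, self.transport)
        d = self.derived()
        p = np.zeros(NPARAM)
        p[PT] = n.temperature
        p[PCM] = n.C_m
        p[PGNA] = n.g_Na
        p[PGK] = n.g_K
        p[PGNAL] = d["g_Na_leak"]
        p[PGKL] = d["g_K_leak"]
        p[PKTAU] = n.k_tau
        p[PPMAX] = d["pump_max"]
        p[PKAP] = n.K_ATP_pump
        p[PKNAP] = n.K_Na_pump
        p[PKKP] = n.K_K_pump
        p[PGAMN] = n.gamma_n
        p[PGAMO] = n.gamma_o
        p[PKBF] = a.k_buf_f
        p[PKBB] = d["k_buf_b"]
        p[PBMAX] = a.B_max
        p[PKCAIN] = s.k_Ca_in
        p[PVCAH] = s.V_Ca_half
        p[PVCAS] = s.V_Ca_slope
        p[PTAUCA] = s.tau_Ca
        p[PCAREST] = s.Ca_rest
        p[PKREL] = s.k_release
        p[PKCAREL] = s.K_Ca_release
        p[PGMAX] = s.G_max
        p[PKREC] = s.k_recover
        p[PKCLR] = s.k_clear
        p[PEPSCLR] = s.eps_clear
        p[PVGLUUP] = a.v_glu_up
        p[PKGLUUP] = a.K_glu_up
        p[PNAPERGLU] = a.na_per_glu
        p[PVIP3] = a.v_ip3
        p[PKGLUIP3] = a.K_glu_ip3
        p[PHILLIP3] = a.hill_ip3
        p[PKIP3DEG] = a.k_ip3_deg
        p[PC0] = a.c0
        p[PC1] = a.c1
        p[PV1] = a.v1
        p[PV2] = a.v2
        p[PV3] = a.v3
        p[PK3] = a.k3
        p[PD1] = a.d1
        p[PD2] = a.d2
        p[PD3] = a.d3
        p[PD5] = a.d5
        p[PA2] = a.a2
        p[PCATH] = a.Ca_threshold
        p[PKEET] = a.k_EET
        p[PVMAXEET] = a.Vmax_EET
        p[PKMEET] = a.Km_EET
        p[PVSMREST] = v.V_SM_rest
        p[PVSMHYP] = v.V_SM_hyper
        p[PRMIN] = v.r_min
        p[PRMAX] = v.r_max
        p[PEETMID] = v.EET_mid
        p[PEETHILL] = v.EET_hill
        p[PTAUSM] = v.tau_SM
        p[PWI] = t.w_i
        p[PWA] = t.w_a
        p[PWN] = t.w_n
        p[PGLCB] = t.Glc_blood
        p[PLACB] = t.Lac_blood
        p[PTGV] = t.T_glc_vessel
        p[PKGV] = t.K_glc_vessel
        p[PTLV] = t.T_lac_vessel
        p[PKLV] = t.K_lac_vessel
        p[PTGIA] = t.T_glc_ia
        p[PKGIA] = t.K_glc_ia
        p[PTGIN] = t.T_glc_in
        p[PKGIN] = t.K_glc_in
        p[PTLIA] = t.T_lac_ia
        p[PKLIA] = t.K_lac_ia
        p[PTLIN] = t.T_lac_in
        p[PKLIN] = t.K_lac_in
        p[PVGLYA] = t.v_gly_a
        p[PKGLYA] = t.K_gly_a
        p[PVGLYN] = t.v_gly_n
        p[PKGLYN] = t.K_gly_n
        p[PLDHFA] = t.ldh_f_a
        p[PLDHRA] = t.ldh_r_a
        p[PLDHFN] = t.ldh_f_n
        p[PLDHRN] = t.ldh_r_n
        p[PVTCAN] = t.v_tca_n
        p[PKTCAN] = t.K_tca_n
        p[PYATPN] = t.Y_atp_n
        p[PATPMAXN] = t.ATP_max_n
        p[PVTCAA] = t.v_tca_a
        p[PKTCAA] = t.K_tca_a
        p[PYATPA] = t.Y_atp_a
        p[PATPMAXA] = t.ATP_max_a
        p[PEPSATPN] = t.eps_atp_n
        p[PRHOA] = a.rho_pump_a
        p[PKNAA] = a.K_Na_pump_a
        p[PKAA] = a.K_ATP_pump_a
        p[PEPSATPA] = t.eps_atp_a
        p[PKNALEAKA] = d["k_Na_leak_a"]
        p[PSTIMSMOOTH] = self.stim_smooth
        p[PBASAL] = v.basal_supply_frac
        p[PKABUF] = a.K_ATP_buf
        p[PHOUSEA] = a.k_house_a
        p[PKBTH] = a.K_buf_th
        p[PKBSIG] = a.K_buf_sig
        p[PKSIPH] = a.k_siphon
        p[PKSIPHTH] = a.K_siphon_th
        return p

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        kwargs = {}
        for key, sub in (("neuron", NeuronParams), ("synapse", SynapseParams),
                         ("astrocyte", AstrocyteParams), ("vessel", VesselParams),
                         ("transport", TransportParams)):
            if key in data:
                kwargs[key] = sub(**data[key])
        if "stim_smooth" in data:
            kwargs["stim_smooth"] = float(data["stim_smooth"])
        return cls(**kwargs)
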