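"""State-vector layout and typed views of the coupled model state.

The full model is a 29-dimensional ODE.  The flat layout below is what the
compiled right-hand side operates on; the dataclasses give a typed,
unit-annotated view of slices of that vector for the public API.

Units
-----
=====================  =========================================
membrane potentials    mV
gating variables       dimensionless, in [0, 1]
ion concentrations     mM (Na+, K+ in every compartment)
neuronal Ca2+          uM
astrocytic Ca2+        mM (printed-threshold scale, see docs)
ATP pools              uM
IP3, EET               uM
glutamate, metabolites mM
vessel radius          um
time                   s
=====================  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# --- flat state indices -------------------------------------------------
IV = 0      # membrane potential (mV)
IM = 1      # Na+ activation gate
IH = 2      # Na+ inactivation gate
IN = 3      # K+ activation gate
INAI = 4    # intracellular Na+ (mM)
IKI = 5     # intracellular K+ (mM)
INAO = 6    # interstitial Na+ (mM)
IKO = 7     # interstitial K+ (mM)
IKBUF = 8   # astrocyte-bound K+ (interstitial mM-equivalent)
ICAN = 9    # neuronal cytosolic Ca2+ (uM)
IATPN = 10  # neuronal ATP (uM)
IRPOOL = 11  # releasable vesicle-pool fraction
IGLU = 12   # synaptic glutamate (mM)
IUREC = 13  # astrocytic recycling glutamate pool (mM)
IIP3 = 14   # astrocytic IP3 (uM)
ICAA = 15   # astrocytic cytosolic Ca2+ (mM)
IHER = 16   # ER IP3-receptor gate
IEET = 17   # perivascular EET (uM)
INAA = 18   # astrocytic Na+ (mM)
IATPA = 19  # astrocytic ATP (uM)
IVSM = 20   # smooth-muscle membrane potential (mV)
IGLCI = 21  # interstitial glucose (mM)
IGLCA = 22  # astrocytic glucose (mM)
IGLCN = 23  # neuronal glucose (mM)
ILACI = 24  # interstitial lactate (mM)
ILACA = 25  # astrocytic lactate (mM)
ILACN = 26  # neuronal lactate (mM)
IPYRA = 27  # astrocytic pyruvate (mM)
IPYRN = 28  # neuronal pyruvate (mM)

NSTATE = 29

STATE_NAMES = (
    "V_m", "m", "h", "n", "Na_i", "K_i", "Na_o", "K_o", "K_buf",
    "Ca_n", "ATP_n", "R_pool", "Glu_syn", "Glu_rec", "IP3", "Ca_a",
    "h_ER", "EET", "Na_a", "ATP_a", "V_SM",
    "Glc_i", "Glc_a", "Glc_n", "Lac_i", "Lac_a", "Lac_n",
    "Pyr_a", "Pyr_n",
)
assert len(STATE_NAMES) == NSTATE


@dataclass
class NeuronState:
    """Excitable-membrane state with explicit ion bookkeeping."""

    V_m: float          # mV
    m: float
    h: float
    n: float
    Na_i: float         # mM
    Na_o: float         # mM
    K_i: float          # mM
    K_o: float          # mM
    Ca_n: float         # uM
    ATP_n: float        # uM

    def validate(self) -> None:
        for g, name in ((self.m, "m"), (self.h, "h"), (self.n, "n")):
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gating variable {name}={g} outside [0, 1]")
        for c, name in (
            (self.Na_i, "Na_i"), (self.Na_o, "Na_o"),
            (self.K_i, "K_i"), (self.K_o, "K_o"),
            (self.Ca_n, "Ca_n"), (self.ATP_n, "ATP_n"),
        ):
            if c < 0.0:
                raise ValueError(f"concentration {name}={c} is negative")


@dataclass
class SynapseState:
    """Quantal-release bookkeeping for the glutamatergic synapse."""

    Glu_syn: float      # mM
    R_pool: float       # releasable fraction in [0, 1]
    Glu_rec: float      # mM, recycled-transmitter pool held by the astrocyte

    def validate(self) -> None:
        if self.Glu_syn < 0.0:
            raise ValueError("Glu_syn is negative")
        if not 0.0 <= self.R_pool <= 1.0:
            raise ValueError("releasable pool fraction outside [0, 1]")


@dataclass
class AstrocyteState:
    """IP3/Ca2+/EET signalling arm plus K+ buffer occupancy."""

    IP3: float          # uM
    Ca_a: float         # mM (printed-threshold scale)
    h_ER: float
    EET: float          # uM
    Na_a: float         # mM
    K_buf: float        # mM-equivalent
    ATP_a: float        # uM

    def validate(self) -> None:
        if not 0.0 <= self.h_ER <= 1.0:
            raise ValueError("h_ER outside [0, 1]")
        for c, name in (
            (self.IP3, "IP3"), (self.Ca_a, "Ca_a"), (self.EET, "EET"),
            (self.Na_a, "Na_a"), (self.K_buf, "K_buf"), (self.ATP_a, "ATP_a"),
        ):
            if c < 0.0:
                raise ValueError(f"{name}={c} is negative")


@dataclass
class VesselState:
    V_SM: float         # mV
    radius: float       # um


@dataclass
class MetabolicState:
    Glc_i: float
    Glc_a: float
    Glc_n: float
    Lac_i: float
    Lac_a: float
    Lac_n: float
    Pyr_a: float
    Pyr_n: float


def neuron_view(y: np.ndarray) -> NeuronState:
    return NeuronState(
        V_m=y[IV], m=y[IM], h=y[IH], n=y[IN],
        Na_i=y[INAI], Na_o=y[INAO], K_i=y[IKI], K_o=y[IKO],
        Ca_n=y[ICAN], ATP_n=y[IATPN],
    )


def synapse_view(y: np.ndarray) -> SynapseState:
    return SynapseState(Glu_syn=y[IGLU], R_pool=y[IRPOOL], Glu_rec=y[IUREC])


def astrocyte_view(y: np.ndarray) -> AstrocyteState:
    return AstrocyteState(
        IP3=y[IIP3], Ca_a=y[ICAA], h_ER=y[IHER], EET=y[IEET],
        Na_a=y[INAA], K_buf=y[IKBUF], ATP_a=y[IATPA],
    )


def metabolic_view(y: np.ndarray) -> MetabolicState:
    return MetabolicState(
        Glc_i=y[IGLCI], Glc_a=y[IGLCA], Glc_n=y[IGLCN],
        Lac_i=y[ILACI], Lac_a=y[ILACA], Lac_n=y[ILACN],
        Pyr_a=y[IPYRA], Pyr_n=y[IPYRN],
    )
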