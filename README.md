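# gliovasc

A closed-loop biophysical simulator of neuron–astrocyte–vessel
(neuro-glio-vascular) coupling.

Most models of neurovascular coupling describe only the forward pathway:
active neurons release glutamate, astrocytes transduce it into
vasodilators, vessels dilate.  `gliovasc` closes the loop.  The dilated
vessel delivers glucose and lactate, the metabolised ATP fuels the
neuron's Na⁺/K⁺-ATPase, and the pump in turn maintains the ionic
gradients that make firing possible — so the neuron's firing pattern
depends on its own metabolic history.  Depending on stimulation current
I_s and initial ATP, the same neuron fires continuously, fires after an
initial pause, bursts under metabolic stress, or returns to rest.  The
package is for computational neuroscientists and systems biologists who
want a compact, testable model of metabolic feedback on excitability.

## The model in brief

* **Neuron** — Hodgkin–Huxley membrane with *dynamic* Nernst potentials,

  E_X = (RT/F)·ln([X]_o/[X]_i),  X ∈ {Na⁺, K⁺},

  Kager-style ion bookkeeping, a K⁺ time constant slowed by a factor
  k_τ to reach gamma-band rates, and an ATP-gated pump with exact 3:2
  stoichiometry,

  I_pump = I_max · (1 − e^(−ATP/K_A)) · f(Na_i) · g(K_o),
  I_Na : I_K = 3 : −2.

* **Synapse** — spike-driven Ca²⁺ entry and quantal glutamate release
  with zero-order clearance and seeded probabilistic recycling through
  the astrocyte.
* **Astrocyte** — mGluR → IP3 → Li–Rinzel store Ca²⁺; EET production is
  threshold-linear in Ca²⁺ (hard threshold 0.1 mM) with
  Michaelis–Menten removal; ATP-fueled sigmoidal K⁺ buffering.
* **Vessel** — EET hyperpolarises smooth muscle through a sigmoid; V_SM
  maps linearly onto radius between (−30 mV, 8 µm) and (−75 mV, 30 µm);
  radius scales glucose/lactate delivery.  A forced-vasomotion mode
  replaces the astrocytic drive with a square-wave radius protocol.
* **Metabolism** — saturable GLUT/MCT carriers between compartments and
  a lumped glycolysis/LDH/TCA pathway with an energy-state (Pasteur)
  feedback producing the ATP that fuels both pumps.

See `docs/methods.md` for the full account, parameter defaults and known
limitations.

## Worked example

```python
import gliovasc as gv
from gliovasc.analysis import detect_spikes, classify_regime

sub = gv.run_simulation(gv.scenario_library()["subthreshold"])
cont = gv.run_simulation(gv.scenario_library()["continuous"])

spikes = detect_spikes(sub.t, sub.column("V_m"))
print(f"sub-threshold regime: {classify_regime(sub)}")
print(f"first spike:          {spikes.times[0]:.2f} s after onset")
print(f"continuous regime:    {classify_regime(cont)}")
print(f"peak vessel radius:   {cont.radius.max():.1f} um")
```

prints

```
sub-threshold regime: pause_then_fire
first spike:          2.23 s after onset
continuous regime:    continuous
peak vessel radius:   18.9 um
```

At 0.05 mA/cm² the neuron stays silent for about two seconds while the
sub-threshold current erodes the potassium gradient, then fires.  At
0.1 mA/cm² it fires from onset; sustained glutamate release drives
astrocytic EET production and the vessel dilates from its contracted
8 µm resting radius, feeding the metabolic loop that keeps the firing
going for the whole run.

The same machinery is available from the shell:

```bash
gliovasc classify --scenario continuous
gliovasc simulate --scenario pulse --out pulse.csv
gliovasc threshold --atp0 20           # bisect the sustained-firing current
gliovasc scan --i-s 0.02,0.05,0.08 --atp0 2,5,20 --out regimes.csv
```

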