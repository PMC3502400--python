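# Model and methods

`gliovasc` simulates one lumped neuro-glio-vascular unit: a neuron, an
astrocyte, a vessel segment and the interstitium that couples them.  The
loop closes in both directions — neuronal firing releases glutamate, the
astrocyte transduces glutamate into the vasodilator EET, the dilated vessel
delivers glucose and lactate, and the metabolised ATP fuels the Na+/K+
pump that keeps the neuron excitable.  This note records the equations'
functional forms, the choices made where the design was genuinely open, and
what the package does and does not reproduce.

## Neuron

A single-compartment Hodgkin–Huxley membrane (classical squid gating
kinetics, rates scaled ×1000 to seconds) with three departures:

* **Dynamic Nernst potentials.** `E_Na` and `E_K` are recomputed from the
  instantaneous intracellular/interstitial concentrations at 310.15 K;
  every channel, leak and pump charge is booked into the ion pools through
  area-to-volume factors `gamma_n` (neuron, 0.004 mM per µA cm⁻² per s) and
  `gamma_o` (interstitium, 0.03 — the interstitium is a much smaller
  compartment, so its concentrations move an order of magnitude faster).
* **Slowed K⁺ kinetics.** τ_n is multiplied by `k_tau` ≥ 1 (default 1.25),
  placing the firing rate in the gamma band; sweeping `k_tau` from ~1 to 4
  spans roughly 80 down to 40 Hz at the standard 0.1 mA/cm² drive.
* **ATP-dependent Na⁺/K⁺-ATPase.** Cycle rate
  `pump_max · f_ATP · f_Na · f_K` with exact 3 Na⁺ : 2 K⁺ stoichiometry
  (net +1 charge out per cycle).  `f_ATP = 1 − exp(−ATP/6 µM)` is
  exponential-saturating: nearly flat above 20 µM (so the restored resting
  state is insensitive to the exact replenished ATP level) and steep below
  10 µM (metabolic stress disables the pump).  `f_Na` is a sixth-order Hill
  term (half-point 20 mM), a cooperative reading of the 3-site binding;
  with a shallow cubic form intracellular Na⁺ accumulates over a 30 s run,
  E_Na collapses and spike amplitudes fade.  `f_K` is the classical
  quadratic Michaelis–Menten term (half-saturation 2 mM).

The leak is split into Na⁺- and K⁺-specific conductances so that leaked
charge appears in the bookkeeping.  Both leak conductances, the pump
maximal rate and the buffer backward rate are *derived* from the
requirement that the reference resting state is an exact fixed point of the
ionic subsystem.  The resting state itself is pinned by two published
post-pulse facts — interstitial K⁺ near 9.5 mM and E_K at −80 mV — which
jointly imply K_i ≈ 190 mM; this is high relative to textbook values and
is accepted deliberately so both printed numbers hold at once.

Stimulus edges are smoothed over 10 ms.  A hard step fires a spurious
phasic spike even at sub-threshold amplitudes (classical HH behaviour),
which would erase the published ~2 s pause at 0.05 mA/cm²; a 10 ms ramp
engages accommodation while shifting supra-threshold first-spike latency
by only tens of milliseconds.

### Firing regimes

With the loop closed, the model reproduces the published behavioural map:

* **Continuous firing** above ≈ 0.06–0.07 mA/cm²: interstitial K⁺ is held
  near 13.5 mM by the fueled glial uptake, the dilated vessel supplies
  enough carbon to balance the pump's ATP cost, and firing persists for
  the whole 30 s run.
* **Firing with initial pause** below threshold: the stimulated membrane
  sits just under its firing threshold while interstitial K⁺ drifts
  upward (efflux exceeds pump reuptake and the glial buffer is disengaged
  below its threshold); the rising E_K depolarises the cell until firing
  starts ~2 s after onset.  The pause shortens with stronger drive.
  Post-pause firing from the degraded state cannot be maintained
  indefinitely and collapses before the end of the run — this is exactly
  what separates the sub-threshold regime from sustained firing in the
  threshold search.
* **Return to rest** after a 1 s pulse at 20 µM ATP: the pump restores
  Na⁺ within ~6 s and the buffer/pump equilibrium parks K_o at ≈ 9.0–9.6
  mM with E_K ≈ −81 mV.

## Synapse

Spike-driven Ca²⁺ entry (sigmoidal voltage gate, half-activation 0 mV)
with first-order extrusion (τ = 0.15 s) feeds a quantal release scheme: a
releasable vesicle fraction is consumed at a fourth-order Ca²⁺-cooperative
rate and replenished from an implicit reserve (0.3 s⁻¹).  Clearance is
zero-order ("constant rate", 1.3 mM/s) with a soft clamp at zero
(softening scale 0.01 mM), so synaptic glutamate can never go negative.
Glutamate taken up by the astrocyte (saturable, 3 Na⁺ co-transported per
molecule) accumulates in a recycling pool and is returned to the
releasable pool quantum-by-quantum through seeded Bernoulli draws at each
integrator chunk boundary — the model's only source of randomness, applied
every 50 ms with per-quantum probability 0.05.  With recycling disabled and
a fixed seed, trajectories are bit-reproducible.

Because clearance is zero-order, a *sustained* intermediate glutamate
plateau is structurally unstable: after the early release transient
(~2.2 mM peak) the cleft concentration falls to a low trickle set by the
clamp.  The mGluR transduction below is deliberately supersensitive
(half-point 0.05 mM) so this trickle still reports ongoing firing to the
astrocyte.

## Astrocyte

mGluR transduction produces IP3 at a saturating Hill-0.7 rate with
first-order degradation (0.12 s⁻¹), so IP3 integrates synaptic activity
over ~8 s — a brief 1 s volley does *not* lift IP3 past the store-release
threshold (the published "critical duration" of stimulation), while
sustained firing does.  Store Ca²⁺ follows Li–Rinzel gating (standard
parameter set); sustained mid-range IP3 produces limit-cycle oscillations,
and the slow inactivation gate is what delays release after an IP3 rise.
Cytosolic Ca²⁺ is carried numerically on the standard Li–Rinzel scale but
*labelled* mM so the published 0.1 mM EET threshold applies verbatim;
physiological astrocytic Ca²⁺ is µM-scale and the label is inherited, not
a unit conversion.

EET production is threshold-linear, `45 · max(Ca − 0.1, 0)` µM/s, exactly
zero at or below threshold; removal is Michaelis–Menten (V_max 40 µM/s,
K_m 5 µM), standing in for diffusion and degradation together.

Interstitial K⁺ handling has three limbs:

1. a reversible buffer whose uptake engages sigmoidally above 13.6 mM
   K_o (glial uptake in the Kager lineage), is proportional to free
   buffer sites and fueled by astrocytic ATP (`ATP_a/(ATP_a+15 µM)`), so
   buffering fades under metabolic stress while unbinding stays passive;
2. the neuronal pump (above), which performs the steady-state clearance
   during supported firing;
3. a perivascular siphon, threshold-linear above 20 mM, which only
   engages during pathological spreading-depolarization-like excursions
   and prevents unbounded K⁺ accumulation.  It is inactive throughout the
   physiological range, so K⁺ conservation over neuron + interstitium +
   buffer holds exactly in all stimulus-off windows.

The astrocytic pump recycles the Na⁺ co-transported with glutamate; its
K⁺ half-cycle is taken as exactly compensated by BK-channel K⁺ release at
the endfoot, so it moves only Na⁺ in the bookkeeping.

## Vessel

EET hyperpolarises the smooth muscle through a Hill-4 sigmoid (midpoint
3 µM); V_SM relaxes first-order (τ = 4 s) toward the EET-set target,
clamped to [−75, −30] mV, and maps linearly onto radius between the two
published endpoint pairs (−30 mV, 8 µm) and (−75 mV, 30 µm).  Glucose and
lactate transfer across the endothelium is a radius-scaled carrier against
fixed blood-side concentrations (4.8 mM glucose, 3.0 mM lactate): affine
in radius from a small basal fraction (0.06) at r_min to the full
coefficient at r_max, so a constricted vessel still supplies a trickle
while dilation raises delivery ~16-fold.  In forced-vasomotion mode the
radius is read from the square-wave protocol (0.2 Hz, 30 µm for 0.5 s per
cycle, first window at 4.5 s) and the EET→V_SM branch is severed.

## Metabolism

Symmetric saturable carriers (GLUT/MCT forms,
`T_max·[S/(S+K_t) − D/(D+K_t)]`) move glucose and lactate between
interstitium, astrocyte and neuron; fluxes convert between compartments
through volume fractions (interstitium 0.2, astrocyte 0.3, neuron 0.4).
Inside each cell a lumped pathway runs glycolysis (1 glucose → 2
pyruvate), LDH interconversion (astrocytic kinetics favour lactate export,
neuronal kinetics favour oxidation) and a TCA step producing ATP with a
lumped yield (150 µM ATP per mM pyruvate — an *effective* coefficient on
the effective tens-of-µM ATP pool, not a whole-cell stoichiometry).
Glycolysis, lactate oxidation and the TCA step are all throttled by
`1 − ATP/ATP_max` (a lumped Pasteur-type energy-state feedback), so carbon
consumption tracks demand.  Oxygen is assumed unlimited.

Both pumps consume ATP in strict proportion to their cycle rate; the
neuronal coefficient (0.0236 µM per µA cm⁻² per s) is a calibration
constant of the effective pool.  The resting metabolite pools are small,
documented values near the constricted-vessel steady state; crucially the
rest state has *no* ATP equilibrium — basal supply covers only about half
of the resting pump cost, so an unstimulated neuron slowly spends its
reserve.  This deliberate deficit is what makes initial ATP a meaningful
experimental variable.

## Numerics

The 29 coupled equations are compiled with numba and integrated with
LSODA (rtol 1e-6, atol 1e-8, max step 5 ms) in 50 ms chunks; the seeded
recycling draw is applied at chunk boundaries.  Output is sampled at
0.5 ms.  Halving the solver tolerances moves spike times by less than the
sampling interval (convergence self-check in the test suite).  Spikes are
detected as upward crossings of −15 mV with a 2 ms refractory guard: late
in a long run action potentials ride a depolarised baseline with reduced
overshoot, and −15 mV still clears subthreshold oscillations (which sit
near −38 mV) by more than 20 mV.  "Sustained firing" means the final 20%
of the run is covered by spiking with no silent gap longer than 1.35 s;
regime classification uses a 0.3 s pause cutoff and a 0.25 s burst gap,
with bursts distinguished from episodic firing by cluster duration
(< 2 s) and a dominant quiescent fraction.

Simulations run 30 s of model time (the published protocol duration);
a full closed-loop run takes a few seconds on one CPU.

## Known limitations

* The spontaneous "SOS" bursting of the metabolically stressed neuron is
  present mechanistically — after the low-ATP pulse the pump and the
  glial buffer both fade and interstitial K⁺ drifts toward the
  spontaneous-firing threshold — but with the default calibration the
  first burst emerges at ~35 s, beyond the 30 s scenario window.  The
  low-ATP scenario therefore classifies as "resting" and burst statistics
  (the published ~40 Hz intra-burst rate) are not reproduced.  The
  corresponding acceptance tests fail and are left failing.
* Forced vasomotion at 5 µM ATP: the initial volley exhausts the ATP
  pool and the neuron settles into a stable depolarised state; the 0.5 s
  dilation windows deliver too little carbon to restore pump function, so
  the published dilation-locked bursting is not reproduced either.
* The synthetic scenarios exercise exactly the published protocol space
  (constant/pulsed current, two initial ATP levels, one vasomotion
  protocol).  Passing tests demonstrate the loop's behaviour under those
  conditions, not fidelity to any particular biological recording; spatial
  diffusion, NO signalling, oxygen transport and multi-cell coupling are
  all outside the model.
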