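# cahomeo

Cell-autonomous calcium homeostasis in conductance-based hippocampal CA1
pyramidal model neurons.

`cahomeo` is a simulator for studying how a neuron that regulates its own
ion-channel expression toward a fixed cytosolic-calcium target reacts to
behavioral-state switches in afferent drive. It is aimed at computational
neuroscientists interested in homeostatic plasticity, degenerate model
populations, and the dissociation between calcium homeostasis,
"channelostasis", and functional homeostasis.

## The model

A single cylindrical compartment (d = L = 100 μm, R_m = 35 kΩ·cm²,
C_m = 1 μF/cm²; passive R_in ≈ 111 MΩ, τ_m = 35 ms) carries 12
conductances in Hodgkin–Huxley form — Leak, NaF, KDR, KA, KM, HCN, CaT,
CaR, CaN, CaL, SK, BK — with first-order Boltzmann gates

    x∞(v) = 1 / (1 + exp(−(v − V½)/k)),    τ_x dx/dt = x∞(v) − x,

plus a lumped glutamatergic synapse whose AMPAR/NMDAR currents are
Goldman–Hodgkin–Katz fluxes of Na⁺, K⁺ and Ca²⁺ with voltage-dependent
Mg²⁺ block, tied together by the NMDAR:AMPAR permeability ratio (NAR).
Cytosolic calcium evolves over four concentric annuli with radial
diffusion, a static buffer, SERCA uptake, an ER leak calibrated for zero
net flux at rest, and a threshold-linear membrane extrusion pump:

    d[Ca]/dt = D_Ca ∇²[Ca] + β(J_leak − J_SERCA) + R_buf + J_VGCC − J_pump.

Channel expression is under integral control by a single
calcium-dependent transcription factor: each mRNA integrates the error
between the calcium target and the submembrane (cytosolic) concentration,
and each conductance relaxes toward its mRNA,

    τᵢ dmᵢ/dt = [Ca]_tgt − [Ca]_c,      τ_g dgᵢ/dt = mᵢ − gᵢ,

with transcription time constants derived from a reference model's
conductances (τᵢ gᵢ = const, anchored at τ_Na = 10 ms). Afferent drive is
either an 8 Hz theta-band sinusoidal permeability modulation or sharp-wave
ripple events (150 Hz ripple under a sharp-wave envelope, repeating at
3 Hz), and the package runs theta–SWR–theta / SWR–theta–SWR switch
protocols with robust/plastic classification of the resulting conductance
changes.

A model is characterized by seven intrinsic measurements — firing rate at
250 pA (f₂₅₀), spike amplitude (V_AP), input resistance (R_in), impedance
maximum (|Z|_max), resonance frequency (f_R), resonance strength (Q) and
total inductive phase (Φ_L) — and is *valid* when all seven fall inside
experimental CA1 bounds. Random populations (48 parameters sampled
uniformly from their testing ranges) are filtered through this validation
and analyzed for pairwise parameter correlations.

## Worked example

```python
from cahomeo import ModelParameters, Simulation, measure_all, validate
from cahomeo.homeostasis import HomeostasisEngine, HomeostasisParams, run_to_steady_state
from cahomeo.stimulus import Epoch, calibrate_theta_amplitude

params = ModelParameters.base()            # hand-tuned table defaults
sim = Simulation(params, dt=0.05)          # 50-us step for interactive use

m = measure_all(sim)
ok, _ = validate(m)
print(f"f250={m.f250:.0f} Hz  V_AP={m.v_ap:.1f} mV  R_in={m.r_in:.1f} MOhm")

amp = calibrate_theta_amplitude(lambda: Simulation(params, dt=0.05))
engine = HomeostasisEngine(params, HomeostasisParams(tau_scale=0.5, seed=1))
engine.reset(sim)                          # conductances start near zero
res = run_to_steady_state(sim, engine, Epoch("theta", 40_000.0, amp, 8.0))
print(f"steady state: [Ca]c={res.mean_calcium*1e6:.1f} nM  "
      f"firing={res.firing_rate:.1f} Hz  g_Na={res.conductances[1]:.2e} S/cm2")
```

prints

```
f250=10 Hz  V_AP=93.2 mV  R_in=64.8 MOhm
steady state: [Ca]c=200.0 nM  firing=8.0 Hz  g_Na=2.28e-03 S/cm2
```

The base model fires 5 spikes during a 500 ms, 250 pA step (f₂₅₀ = 10 Hz)
with 93 mV spikes and a 65 MΩ input resistance — inside all seven
validation windows. Starting the homeostasis engine from near-zero
conductances under minimum-spiking theta drive, the integral controller
pulls mean cytosolic calcium to its 200 nM target exactly, with the
neuron firing one spike per theta cycle and a sodium conductance the
controller chose on its own (≈ 2.3 mS/cm², about a third of the reference
model's) — calcium homeostasis without channel-level homeostasis.

A `cahomeo` command-line tool exposes the same operations
(`cahomeo model probe`, `cahomeo population sample|evaluate|correlate`,
`cahomeo homeostasis run --sequence theta-swr-theta`, ...).

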