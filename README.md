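# gammares

Gamma-oscillation resonance in a conductance-based spiking model of
primary visual cortex, and its control by thalamocortical synaptic
strength.

## The science

Cortical networks of excitatory (E) and inhibitory (I) neurons
spontaneously generate gamma-band rhythms (30–70 Hz) when driven by
temporally unstructured input.  Sensory input, however, often arrives
already rhythmic.  This package simulates a 1 mm × 1 mm sheet of 3341
Hodgkin–Huxley neurons (75% E, 25% I, distance-decayed recurrent
coupling) in which every cell receives an independent Poisson afferent
whose rate can be sinusoidally modulated,

    r(t) = r₀ + A·sin(2π f_in t),   r₀ = 40 spikes/s, A ∈ {0, 10, 20},

and asks how the *spontaneous* rhythm (frequency f_s, emerging from
E–I interaction) and the *stimulus-driven* rhythm at f_in interact:

* far apart, the two oscillations coexist as separate spectral peaks;
* close together, they **resonate** — a single peak near f_in remains,
  spike synchrony tightens, and the probability that an afferent spike
  evokes a cortical spike rises;
* the peak feedforward EPSC conductance **g_max** (30–70 µS/cm², the
  model's synaptic-plasticity knob) moves f_s across roughly 37–61 Hz,
  so plasticity of the thalamocortical synapse *re-tunes the resonance*:
  which input frequencies are amplified is set by g_max;
* within each gamma cycle, inputs arriving in the rising phase of the
  population rate (a "pass band" peaking near −90°, with 0° at the
  cycle peak) are far more effective than those in the falling phase
  (the "block band").

The library provides the network builder, the Poisson drive generator,
an exponential-Euler integrator fast enough for full-scale sweeps on
one core, the full measurement battery (spectra and peak
classification, ISI sharpness, unity-normalised correlograms,
response probability/delay, unpaired-spike selection, gamma phase,
phase-binned input efficacy) and the sweep experiments, behind both a
Python API and a small `gammares` CLI.  See `docs/methods.md` for
model details and `examples/` for narrative scripts.

## Worked example

`python examples/spontaneous_gamma.py` builds the quarter-scale
network (835 neurons, recurrent weights rescaled so per-neuron drive
matches full scale), drives it with static 40 spikes/s Poisson input
for 6 s and prints:

```
network: 835 neurons (626 E / 209 I)
spontaneous gamma peak: 38.0 Hz
mean rates: E 6.4 spikes/s, I 36.9 spikes/s
ISI sharpness (1/CV): E 1.13, I 5.40
-> I cells fire about once per gamma cycle (rate ~ peak frequency);
   E cells fire less than once per cycle, so the rhythm is paced by
   fast, regular inhibition.
```

The inhibitory rate (≈37 spikes/s) sitting at the spectral peak
(38 Hz) while the excitatory rate stays far below it is the signature
of an inhibition-paced gamma rhythm.  The other examples show
coexistence versus resonance (`entrainment_and_resonance.py`), the
g_max → f_s curve (`plasticity_frequency_curve.py`) and phase-gating
(`phase_gating.py`).

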