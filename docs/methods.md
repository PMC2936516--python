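# Methods

## The model

`gammares` simulates a 1 mm × 1 mm sheet of primary visual cortex
containing 3341 single-compartment neurons, 75% excitatory (E) and 25%
inhibitory (I).  Each neuron is a Hodgkin–Huxley membrane

    C dV/dt = − g_L (V − V_L) − G_Na m³h (V − V_Na) − G_K n⁴ (V − V_K)
              − g_E (V − V_E) − g_I (V − V_I)

with C = 10⁻⁶ F/cm², g_L = 50×10⁻⁶ S/cm², V_L = −70 mV, V_Na = 55 mV,
V_K = −80 mV, V_E = 0 mV, V_I = −80 mV, G_Na = 120 mS/cm² and
G_K = 36 mS/cm².  g_E is the sum of recurrent excitatory and
feedforward conductances, g_I the recurrent inhibitory conductance.

### Channel kinetics

The gating variables m, h, n follow the classical squid-axon rate
functions (modern voltage convention).  A membrane with those rates,
the conductance maxima above and our leak rests near −75 mV, not at
V_L, and no *common* voltage shift of the rates can fix this: at
−70 mV the steady-state K current always exceeds the Na window current.
The two channels are therefore displaced independently along the
voltage axis: Na by +5 mV, which places the firing threshold near
−55 mV, and K by +12.5814 mV, solved numerically so that the net
steady-state membrane current vanishes at −70 mV exactly.  The
resulting resting state is stable and the package's resting-potential
test holds it to within 0.1 mV over one second.  Both shifts are
ordinary config keys.

### Synapses

Every synaptic event adds a difference-of-exponentials conductance
transient exp(−t/τ_d) − exp(−t/τ_r), normalised so its peak equals the
synaptic weight.  Time constants (τ_d, τ_r) are (3, 1) ms for
excitatory sources and (7, 1) ms for inhibitory sources; the
source-population reading of "for σ = E/I" is a documented choice, as
is reusing the excitatory kernel shape for the thalamocortical EPSC.
The feedforward EPSC peak, g_max, is the model's synaptic-plasticity
knob, swept over 30–70 µS/cm².

### Connectivity

Recurrent coupling is deterministic and all-to-all within a cutoff
radius: the weight from neuron j to neuron i is W_(σσ′) · f(r_ij),
where σ/σ′ are the target/source populations, f(r) = exp(−r/λ) with
λ = 200 µm for excitatory sources and 100 µm for inhibitory sources,
and pairs beyond 600 µm (3λ_E) are unconnected.  A Gaussian profile is
available as a config switch.  The Methods-level description we
implement specifies a conductance *weighting*, not a connection
probability, which is why the realisation is deterministic; positions
come from a jittered square grid (jitter ±25% of the pitch) and type
labels from a seeded shuffle hitting exactly 2506 E / 835 I.

### The four coupling weights and their calibration

The numeric W_(σσ′) values are not part of the printed parameter set,
so they are fixed by calibration: the requirement that the network
driven by static 40 spikes/s Poisson input at the low end of the g_max
range (30 µS/cm²) shows one spontaneous gamma peak at 38 ± 1 Hz, with
I cells firing in nearly every cycle and E cells firing less than once
per cycle on average.  `calibrate_weights` implements this as a
multiplicative coordinate search over the four weights (weights are
peak conductances in mS/cm² at zero distance).  The shipped default
configuration contains the frozen result of that calibration; sweeps
never silently re-calibrate.  Everything downstream of the 38 Hz anchor
— the 37–61 Hz plasticity range, the g_max-dependent resonance points,
the pass-band phase — is an out-of-calibration prediction of the model.

## Feedforward drive

Each cortical neuron has one private afferent: an inhomogeneous Poisson
train with shared rate r(t) = r₀ + A sin(2π f_in t + φ), r₀ =
40 spikes/s, A ∈ {0, 10, 20} spikes/s, f_in ∈ 25–55 Hz.  Trains are
generated by thinning a homogeneous process at the peak rate (exact for
any modulation frequency) and are reproducible per (seed, neuron id).
Per-neuron independence and a shared modulation phase are modelling
choices: independence matches the flat input correlogram of the
unmodulated condition, and a shared phase is what allows the afferent
population to entrain the cortical rhythm.  The generator does not
model any retinal/geniculate spiking structure beyond this rate
modulation — real LGN trains carry burst structure and pairwise
correlations that these tests deliberately exclude, so passing tests
say nothing about responses to naturally correlated input.

## Integration

The integrator is exponential Euler (the standard solver of the
compartmental-simulator family this model descends from) at
dt = 0.05 ms, with gating steady states and relaxation factors
pre-sampled on a 0.01 mV grid and linearly interpolated.  Synaptic
state uses two exponential variables per (target, source-type) channel;
spikes increment both by weight/peak so the kernel is reproduced
exactly at grid times, and the cost scales with neurons, not synapses.
Spikes are upward crossings of 0 mV with a 2 ms lockout.  A
step-halving test requires the dominant spectral peak to move < 1 Hz.
The accuracy contract against an adaptive-step reference integration of
the same vector field is < 0.5 mV away from spikes and < 0.2 ms spike
timing over ~100 ms; over longer spiking stretches the fixed-step
integrator accumulates a slow phase drift (~0.02 ms per spike), which
is why trace comparisons exclude a ±4 ms window around spikes.

## Measurements

* Population rate: spikes per 2 ms bin per neuron.  2 ms bins put the
  Nyquist frequency at 250 Hz, covering the full 20–130 Hz analysis
  band (10 ms bins would cap it at 50 Hz).
* Spectrum: Welch averaged periodogram of the mean-subtracted rate,
  2 s segments, 50% overlap.  Peaks are local maxima in 20–130 Hz
  whose power exceeds 3× the baseline (median in-band power excluding
  ±3 Hz around candidate peaks); two such peaks classify the condition
  as "coexisting", exactly one as "resonant".  A peak only counts as a
  distinct rhythm: shoulders within 5 Hz of a stronger peak and
  harmonics (within 4 Hz of 2× or 3× a stronger peak) are merged into
  it, and secondary peaks must reach 2% of the dominant peak's power.
  The 3× rule replaces visual classification and is a config knob.
* Correlogram: pooled cross-neuron coincidence counts per lag divided
  by the independence expectation Σ_{i≠j} N_i N_j · Δ/T, so
  uncorrelated trains sit at 1 exactly in expectation.  Same-neuron
  pairs are removed when a raster is correlated against itself.
* ISI sharpness: 1/CV of the type-pooled inter-spike intervals, capped
  at 10³ for perfectly periodic trains.
* Response probability/delay: an input spike is answered if its target
  cortical neuron fires within (0, 10] ms; the 10 ms window is shorter
  than one gamma period at every studied frequency, so at most one
  cycle can answer.  Delay is the mean latency of first answers; with
  no answers it is reported as missing, never 0.  Unpaired input spikes
  are those with no same-afferent neighbour within ±20 ms; for a
  Poisson train the retained fraction is e^(−2rw) ≈ 0.202 at
  r = 40 spikes/s, w = 20 ms, which the tests verify.
* Gamma phase: the population rate is band-passed ±10 Hz around the
  dominant peak (3rd-order Butterworth, zero-phase), the analytic
  signal taken, and the phase convention set so 0° sits at cycle peaks
  of the band-passed rate.  Efficacy per 30° phase bin is the response
  probability of unpaired inputs divided by the spike-count-weighted
  mean across bins (weighted mean ≡ 1 by construction).

## Experiments and problem sizes

Full-scale runs use all 3341 neurons.  Parameter sweeps use a
quarter-scale fixture: 835 neurons on a 0.5 mm sheet with preserved
density and E/I split, whose recurrent weights are multiplied, per
source type, by the ratio of mean incoming spatial-weight sums in the
full versus reduced sheet.  This conserves expected per-neuron
recurrent drive including edge effects (a plain inverse-count rescale
would not, because the spatial kernels truncate differently in a
smaller sheet), and in practice reproduces the full-scale
spontaneous-frequency curve to within about 1 Hz.  Default problem
sizes: the spontaneous-frequency anchor runs 6–10 s at full scale;
g_max sweeps run 4–6 s per condition at quarter scale with 2–3 seeds —
long enough for ~0.5 Hz spectral resolution and stable response
probabilities, and chosen as the package's desk-scale defaults.

## Known limitations

* No corticothalamic feedback, no conduction delays, no plasticity
  during a run (g_max is fixed per simulation), single-compartment
  cells only.
* The W_(σσ′) values are calibration products, not measurements; other
  weight vectors reproduce the 38 Hz anchor with different
  out-of-calibration curves.
* Spectral peak classification at few Welch segments (< ~4 s of data)
  is noisy; classification-sensitive conclusions should use ≥ 6 s runs.
* The resonance-point measure (argmax over a 5 µS/cm² grid of a
  stochastic enhancement) has inherent one-grid-step jitter at small
  repeat counts.
* The phase-efficacy pass band is nearly flat (within ~0.5%) across
  its −105° to −15° span, so the peak-bin location is ill-conditioned:
  the package pools response counts over repeated seeded runs (its
  standard estimator, e.g. 6 × 20 s for the headline measurement), and
  even then adjacent bins trade places between seeds.  The robust
  statements are the band's location (rising half-cycle, before the
  population-rate peak) and the deep post-peak block band.
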