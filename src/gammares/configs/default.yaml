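# Calibrated default model configuration.
# Physiological constants carry their conventional units:
# capacitance F/cm^2, conductances S/cm^2, potentials mV, lengths um,
# kernel time constants ms, feedforward gmax uS/cm^2.
geometry:
  sheet_width: 1.0
  sheet_height: 1.0
  neuron_count: 3341
  excitatory_fraction: 0.75
  grid_jitter: 0.25
connectivity:
  decay_length_exc: 200.0
  decay_length_inh: 100.0
  weight_EE: 7.5e-05
  weight_EI: 0.0029
  weight_IE: 0.002
  weight_II: 0.003
  connection_radius_cutoff: 600.0
  spatial_profile: exponential
neuron:
  membrane_capacitance: 1.0e-06
  leak_conductance: 5.0e-05
  leak_reversal: -70.0
  na_reversal: 55.0
  k_reversal: -80.0
  exc_reversal: 0.0
  inh_reversal: -80.0
  na_max_conductance: 0.12
  k_max_conductance: 0.036
  spike_detection_threshold: 0.0
  spike_lockout: 2.0
  na_kinetics_shift: 5.0
  k_kinetics_shift: 12.5814
feedforward_gmax: 30.0
gmax_bounds: [30.0, 70.0]
simulation:
  time_step: 0.05
  duration: 10.0
  warmup_discard: 0.5
  seed: 0
  record_voltages: []
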