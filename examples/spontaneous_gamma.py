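"""Spontaneous gamma from temporally unstructured drive.

Builds the quarter-scale model cortex, drives every neuron with an
independent static 40 spikes/s Poisson afferent, and measures the
population-rate power spectrum.  The network should produce a single
spontaneous gamma peak near 38 Hz, carried by inhibitory cells firing in
nearly every cycle while excitatory cells fire sparsely.
"""

from gammares import (
    DriveSpec,
    SimulationConfig,
    default_config,
    generate_poisson_raster,
    isi_distribution,
    make_fixture_network,
    population_rate,
    power_spectrum,
    run_simulation,
)

config = default_config()
net = make_fixture_network(config, 0.25, seed=0)
print(f"network: {net.n_neurons} neurons "
      f"({net.geometry.n_excitatory} E / {net.geometry.n_inhibitory} I)")

drive = DriveSpec(mean_rate=40.0, duration=6.0, seed=0)
raster = generate_poisson_raster(drive, net.n_neurons)
result = run_simulation(net, raster,
                        SimulationConfig(duration=6.0, warmup_discard=0.5, seed=0))

out = result.output_raster
isE = net.geometry.is_excitatory
T = drive.duration - 0.5
rate_e = isE[out.neuron_ids].sum() / isE.sum() / T
rate_i = (~isE[out.neuron_ids]).sum() / (~isE).sum() / T

_, rate = population_rate(out, 2.0)
spec = power_spectrum(rate[250:], 2.0, segment_length=2.0)
isi = isi_distribution(out, types=isE)

print(f"spontaneous gamma peak: {spec.dominant_peak:.1f} Hz")
print(f"mean rates: E {rate_e:.1f} spikes/s, I {rate_i:.1f} spikes/s")
print(f"ISI sharpness (1/CV): E {isi.sharpness['E']:.2f}, I {isi.sharpness['I']:.2f}")
print("-> I cells fire about once per gamma cycle (rate ~ peak frequency);")
print("   E cells fire less than once per cycle, so the rhythm is paced by")
print("   fast, regular inhibition.")
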