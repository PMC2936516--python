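"""Membrane dynamics and the exponential-Euler integrator.

The independent oracle throughout is scipy's adaptive ODE solver run on
the smooth Hodgkin-Huxley vector field (no tables, no fixed step).
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gammares import hh
from gammares.drive import DriveSpec, SpikeRaster, generate_poisson_raster
from gammares.engine import run_simulation, run_single_neuron
from gammares.network import build_network, synaptic_kernel
from gammares.params import (
    ConnectivitySpec,
    GeometrySpec,
    NeuronParameters,
    SimulationConfig,
    default_kernels,
)


def reference_trace(params, g_exc_fn, g_inh_fn, t_end_ms, rtol=1e-8):
    """Adaptive-step reference integration of the single-neuron ODE."""

    def rhs(t, y):
        v, m, h, n = y
        d = hh.membrane_derivatives(
            {"V": v, "m": m, "h": h, "n": n}, params,
            g_exc_fn(t), g_inh_fn(t))
        return [float(d["V"][0]), float(d["m"][0]), float(d["h"][0]),
                float(d["n"][0])]

    rest = hh.resting_state(params)
    y0 = [float(rest[k][0]) for k in ("V", "m", "h", "n")]
    sol = solve_ivp(rhs, (0.0, t_end_ms), y0, rtol=rtol, atol=1e-10,
                    dense_output=True, max_step=0.5)
    return sol


class TestMembrane:
    def test_resting_fixed_point(self, neuron_params):
        state = hh.resting_state(neuron_params)
        d = hh.membrane_derivatives(state, neuron_params, 0.0, 0.0)
        assert abs(d["V"][0]) < 1e-6  # mV/ms

    def test_rest_holds_for_one_second(self, neuron_params):
        n_steps = 20000  # 1 s at dt = 0.05 ms
        z = np.zeros(n_steps)
        cfg = SimulationConfig(duration=1.0, warmup_discard=0.0)
        _, v, spikes = run_single_neuron(neuron_params, z, z, cfg)
        assert np.abs(v - neuron_params.leak_reversal).max() < 0.1
        assert spikes.size == 0

    def test_current_signs(self, neuron_params):
        state = hh.resting_state(neuron_params)
        base = hh.membrane_derivatives(state, neuron_params, 0.0, 0.0)["V"][0]
        up = hh.membrane_derivatives(state, neuron_params, 0.01, 0.0)["V"][0]
        down = hh.membrane_derivatives(state, neuron_params, 0.0, 0.01)["V"][0]
        assert up > base  # V < V_E: excitation depolarises
        assert down < base  # V > V_I: inhibition hyperpolarises

    def test_passive_relaxation_time_constant(self, neuron_params):
        # channels blocked: V relaxes to V_L with tau = C/g_L = 20 ms
        p = NeuronParameters(na_max_conductance=0.0, k_max_conductance=0.0)
        d = hh.membrane_derivatives(
            {"V": -60.0, "m": 0.0, "h": 1.0, "n": 0.0}, p, 0.0, 0.0)
        # dV/dt = -(V - V_L)/tau -> at V = -60, dV/dt = -10/20 = -0.5 mV/ms
        assert d["V"][0] == pytest.approx(-0.5, rel=1e-9)

    def test_non_finite_state_identified(self, neuron_params):
        with pytest.raises(FloatingPointError, match="neuron index 1"):
            hh.membrane_derivatives(
                {"V": np.array([-70.0, np.nan]), "m": np.zeros(2),
                 "h": np.zeros(2), "n": np.zeros(2)},
                neuron_params, np.zeros(2), np.zeros(2))


class TestSingleNeuronOracle:
    def test_subthreshold_trace_matches_reference(self, neuron_params):
        dt = 0.05
        t_end = 200.0
        n_steps = int(t_end / dt)
        kE = default_kernels()["E"]
        t_grid = (np.arange(n_steps) + 1) * dt
        # weak EPSP barrage: kernels at fixed times, peak 0.005 mS/cm^2
        onsets = np.array([20.0, 60.0, 61.0, 120.0, 150.0])

        def g_of(t):
            t = np.atleast_1d(t)
            g = sum(np.where(t >= t0, synaptic_kernel(np.maximum(t - t0, 0.0), kE), 0.0)
                    for t0 in onsets)
            return 0.005 * g

        g_wave = g_of(t_grid)
        _, v, spikes = run_single_neuron(
            neuron_params, g_wave, np.zeros(n_steps),
            SimulationConfig(duration=t_end / 1e3, warmup_discard=0.0))
        assert spikes.size == 0
        sol = reference_trace(neuron_params, lambda t: float(g_of(t)[0]),
                              lambda t: 0.0, t_end)
        v_ref = sol.sol(t_grid)[0]
        assert np.abs(v - v_ref).max() < 0.5

    def test_spiking_trace_matches_reference_spike_times(self, neuron_params):
        dt = 0.05
        t_end = 120.0
        n_steps = int(t_end / dt)
        g_wave = np.full(n_steps, 0.03)  # sustained suprathreshold drive
        t_grid = (np.arange(n_steps) + 1) * dt
        _, v, spikes = run_single_neuron(
            neuron_params, g_wave, np.zeros(n_steps),
            SimulationConfig(duration=t_end / 1e3, warmup_discard=0.0))
        assert spikes.size >= 3
        sol = reference_trace(neuron_params, lambda t: 0.03, lambda t: 0.0,
                              t_end, rtol=1e-10)
        v_ref = sol.sol(t_grid)[0]
        # reference spike times: upward 0-crossings of the dense solution
        fine_t = np.arange(0, t_end, 0.001)
        v_fine = sol.sol(fine_t)[0]
        crossings = fine_t[1:][(v_fine[:-1] < 0) & (v_fine[1:] >= 0)]
        ref_spikes = [crossings[0]]
        for c in crossings[1:]:
            if c - ref_spikes[-1] > 2.0:
                ref_spikes.append(c)
        ref_spikes = np.array(ref_spikes)
        k = min(spikes.size, ref_spikes.size)
        assert np.abs(spikes[:k] - ref_spikes[:k]).max() < 0.2
        # away from spikes (> 4 ms from any reference spike, outside the
        # steep pre-spike ramp where accumulated phase drift dominates)
        dist = np.min(np.abs(t_grid[:, None] - ref_spikes[None, :]), axis=1)
        quiet = (dist > 4.0) & (v_ref < -50.0)
        assert np.abs(v[quiet] - v_ref[quiet]).max() < 0.5

    def test_one_spike_for_brief_strong_pulse(self, neuron_params):
        n_steps = 4000
        g = np.zeros(n_steps)
        g[1000:1100] = 0.5  # 5 ms, strong
        _, _, spikes = run_single_neuron(
            neuron_params, g, np.zeros(n_steps),
            SimulationConfig(duration=0.2, warmup_discard=0.0))
        assert spikes.size == 1

    def test_fi_curve_monotone(self, neuron_params):
        rates = []
        n_steps = 20000
        for g0 in (0.02, 0.04, 0.08):
            g = np.full(n_steps, g0)
            _, _, spikes = run_single_neuron(
                neuron_params, g, np.zeros(n_steps),
                SimulationConfig(duration=1.0, warmup_discard=0.0))
            rates.append(spikes.size)
        assert rates[0] > 0
        assert rates[0] < rates[1] < rates[2]


class TestNetworkEngine:
    def test_no_drive_no_output(self):
        net = build_network(GeometrySpec(neuron_count=30), ConnectivitySpec(),
                            seed=0, feedforward_gmax=30.0)
        empty = SpikeRaster(np.empty(0, dtype=int), np.empty(0), 30, 0.5)
        res = run_simulation(net, empty,
                             SimulationConfig(duration=0.5, warmup_discard=0.0))
        assert res.output_raster.n_spikes == 0

    def test_population_mismatch_rejected(self):
        net = build_network(GeometrySpec(neuron_count=30), ConnectivitySpec(),
                            seed=0)
        raster = SpikeRaster(np.zeros(1, dtype=int), np.array([10.0]), 31, 0.5)
        with pytest.raises(ValueError, match="population"):
            run_simulation(net, raster, SimulationConfig(duration=0.5,
                                                         warmup_discard=0.0))

    def test_deterministic_given_inputs(self, fixture_network):
        net = fixture_network
        drive = DriveSpec(mean_rate=40.0, duration=1.0, seed=3)
        raster = generate_poisson_raster(drive, net.n_neurons)
        cfg = SimulationConfig(duration=1.0, warmup_discard=0.0, seed=3)
        a = run_simulation(net, raster, cfg).output_raster
        b = run_simulation(net, raster, cfg).output_raster
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.neuron_ids, b.neuron_ids)

    def test_voltage_recording_and_config_echo(self, fixture_network):
        net = fixture_network
        drive = DriveSpec(mean_rate=40.0, duration=0.5, seed=1)
        raster = generate_poisson_raster(drive, net.n_neurons)
        cfg = SimulationConfig(duration=0.5, warmup_discard=0.0, seed=1,
                               record_voltages=(0, 5))
        res = run_simulation(net, raster, cfg)
        assert set(res.voltage_traces) == {0, 5}
        assert res.voltage_traces[0].size == res.trace_times.size
        assert res.config_echo["n_neurons"] == net.n_neurons
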