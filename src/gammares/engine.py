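"""Time-stepping engine: exponential-Euler integration of the network.

The integrator advances membrane potential and gating variables with the
exponential-Euler scheme (the standard solver of compartmental
simulators) at dt = 0.05 ms by default.  Synapses are represented by two
exponential state variables per (target, source-type) channel whose
difference reproduces the difference-of-exponentials kernel exactly at
the grid times; an incoming spike increments both states by the synaptic
weight divided by the kernel's peak value, so a single spike's
conductance transient peaks exactly at the weight.

Gating steady states and relaxation factors are pre-sampled on a 0.01 mV
grid and linearly interpolated inside the numba kernel, which makes a
10 s run of the full 3341-neuron sheet a matter of tens of seconds on
one core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from numba import njit

from . import hh
from .drive import SpikeRaster
from .network import Network, kernel_peak
from .params import SimulationConfig


class IntegrationError(RuntimeError):
    """Numerical blow-up; carries the neuron index and time of failure."""

    def __init__(self, neuron: int, time_ms: float):
        super().__init__(
            f"non-finite membrane state at neuron {neuron}, t = {time_ms:.3f} ms"
        )
        self.neuron = neuron
        self.time_ms = time_ms


@dataclass
class SimulationResult:
    """Everything a run produced, plus the record needed to re-run it."""

    output_raster: SpikeRaster
    input_raster: SpikeRaster
    voltage_traces: dict[int, np.ndarray] | None
    trace_times: np.ndarray | None
    config_echo: dict[str, Any]


@njit(cache=True, fastmath=True)
def _step_neuron(v, m, h, n, g_exc, g_inh,
                 gL, VL, GNa, VNa, GK, VK, VE, VI, inv_c, dt,
                 vmin_tab, inv_dv, ntab, tab):
    # gating via table lookup with linear interpolation
    x = (v - vmin_tab) * inv_dv
    k = int(x)
    if k < 0:
        k = 0
    elif k > ntab - 2:
        k = ntab - 2
    w1 = x - k
    w0 = 1.0 - w1
    m_inf = w0 * tab[k, 0] + w1 * tab[k + 1, 0]
    e_m = w0 * tab[k, 1] + w1 * tab[k + 1, 1]
    h_inf = w0 * tab[k, 2] + w1 * tab[k + 1, 2]
    e_h = w0 * tab[k, 3] + w1 * tab[k + 1, 3]
    n_inf = w0 * tab[k, 4] + w1 * tab[k + 1, 4]
    e_n = w0 * tab[k, 5] + w1 * tab[k + 1, 5]
    m = m_inf + (m - m_inf) * e_m
    h = h_inf + (h - h_inf) * e_h
    n = n_inf + (n - n_inf) * e_n

    g_na = GNa * m * m * m * h
    g_k = GK * n * n * n * n
    g_tot = gL + g_na + g_k + g_exc + g_inh
    v_inf = (gL * VL + g_na * VNa + g_k * VK + g_exc * VE + g_inh * VI) / g_tot
    v = v_inf + (v - v_inf) * np.exp(-g_tot * dt * inv_c)
    return v, m, h, n


@njit(cache=True, fastmath=True)
def _integrate_network(n, n_steps, dt,
                       v, m, h, ng,
                       zdE, zrE, zdI, zrI, zdF, zrF,
                       fdE, frE, fdI, frI,
                       gL, VL, GNa, VNa, GK, VK, VE, VI, inv_c,
                       thr, lockout_steps,
                       vmin_tab, inv_dv, tab,
                       is_exc, weights,
                       in_steps, in_targets, ff_inc,
                       rec_ids, v_rec,
                       out_ids, out_steps, max_out):
    ntab = tab.shape[0]
    n_rec = rec_ids.shape[0]
    n_out = 0
    p_in = 0
    n_in = in_steps.shape[0]
    last_spike = np.full(n, -10**9, dtype=np.int64)
    spiking = np.empty(n, dtype=np.int64)
    for step in range(n_steps):
        # scheduled feedforward spikes for this step
        while p_in < n_in and in_steps[p_in] == step:
            tgt = in_targets[p_in]
            zdF[tgt] += ff_inc
            zrF[tgt] += ff_inc
            p_in += 1
        # synaptic state decay over dt
        for i in range(n):
            zdE[i] *= fdE
            zrE[i] *= frE
            zdI[i] *= fdI
            zrI[i] *= frI
            zdF[i] *= fdE
            zrF[i] *= frE
        # membrane update and spike detection
        n_spiking = 0
        for i in range(n):
            g_exc = (zdE[i] - zrE[i]) + (zdF[i] - zrF[i])
            g_inh = zdI[i] - zrI[i]
            if g_exc < 0.0:
                g_exc = 0.0
            if g_inh < 0.0:
                g_inh = 0.0
            v_old = v[i]
            v_new, m_new, h_new, n_new = _step_neuron(
                v_old, m[i], h[i], ng[i], g_exc, g_inh,
                gL, VL, GNa, VNa, GK, VK, VE, VI, inv_c, dt,
                vmin_tab, inv_dv, ntab, tab)
            if not np.isfinite(v_new):
                return n_out, i, step
            v[i] = v_new
            m[i] = m_new
            h[i] = h_new
            ng[i] = n_new
            if v_old < thr and v_new >= thr and step - last_spike[i] >= lockout_steps:
                last_spike[i] = step
                spiking[n_spiking] = i
                n_spiking += 1
                if n_out < max_out:
                    out_ids[n_out] = i
                    out_steps[n_out] = step
                    n_out += 1
                else:
                    return n_out, -2, step
        # recurrent propagation (takes effect from the next step on)
        for s in range(n_spiking):
            j = spiking[s]
            row = weights[j]
            if is_exc[j]:
                for i2 in range(n):
                    w = row[i2]
                    if w != 0.0:
                        zdE[i2] += w
                        zrE[i2] += w
            else:
                for i2 in range(n):
                    w = row[i2]
                    if w != 0.0:
                        zdI[i2] += w
                        zrI[i2] += w
        for r in range(n_rec):
            v_rec[r, step] = v[rec_ids[r]]
    return n_out, -1, n_steps


def run_simulation(network: Network, input_raster: SpikeRaster,
                   config: SimulationConfig) -> SimulationResult:
    """Integrate the network driven by ``input_raster``.

    Deterministic given (network, raster, config).  Each input spike at
    time t adds the feedforward EPSC kernel, peak ``feedforward_gmax``,
    to its target's excitatory conductance; each output spike propagates
    the source-type recurrent kernel scaled by the pairwise weight.
    Spikes inside the warmup interval are excluded from the returned
    output raster.
    """
    n = network.n_neurons
    if input_raster.population_size != n:
        raise ValueError(
            f"input raster population ({input_raster.population_size}) does not "
            f"match network size ({n})"
        )
    p = network.neuron_params
    dt = config.time_step
    n_steps = int(round(1e3 * config.duration / dt))

    kE, kI = network.kernels["E"], network.kernels["I"]
    pkE, pkI = kernel_peak(kE)[1], kernel_peak(kI)[1]
    # weights are peak conductances; pre-divide by the kernel peak so the
    # state-variable difference is the conductance directly
    weights = np.ascontiguousarray(network.weights / np.where(
        network.geometry.is_excitatory[:, None], pkE, pkI))

    vmin_tab, inv_dv, tab = hh.build_gating_tables(p, dt)
    state = hh.resting_state(p, n)
    v, m, h, ng = state["V"].copy(), state["m"].copy(), state["h"].copy(), state["n"].copy()
    z = [np.zeros(n) for _ in range(6)]

    in_steps = np.minimum((input_raster.times / dt).astype(np.int64), n_steps - 1)
    order = np.argsort(in_steps, kind="stable")
    in_steps = np.ascontiguousarray(in_steps[order])
    in_targets = np.ascontiguousarray(input_raster.neuron_ids[order])

    rec_ids = np.asarray(sorted(config.record_voltages), dtype=np.int64)
    v_rec = np.empty((rec_ids.size, n_steps)) if rec_ids.size else np.empty((0, 0))

    max_out = int(n * config.duration * 300) + 1000
    out_ids = np.empty(max_out, dtype=np.int64)
    out_steps = np.empty(max_out, dtype=np.int64)

    gL = 1e3 * p.leak_conductance
    n_out, err, err_step = _integrate_network(
        n, n_steps, dt, v, m, h, ng, *z,
        np.exp(-dt / kE.decay_time_constant), np.exp(-dt / kE.rise_time_constant),
        np.exp(-dt / kI.decay_time_constant), np.exp(-dt / kI.rise_time_constant),
        gL, p.leak_reversal,
        1e3 * p.na_max_conductance, p.na_reversal,
        1e3 * p.k_max_conductance, p.k_reversal,
        p.exc_reversal, p.inh_reversal,
        1.0 / (1e6 * p.membrane_capacitance),
        p.spike_detection_threshold,
        int(round(p.spike_lockout / dt)),
        vmin_tab, inv_dv, tab,
        np.ascontiguousarray(network.geometry.is_excitatory),
        weights, in_steps, in_targets,
        1e-3 * network.feedforward_gmax / pkE,
        rec_ids, v_rec, out_ids, out_steps, max_out)
    if err >= 0:
        raise IntegrationError(err, (err_step + 1) * dt)
    if err == -2:
        raise IntegrationError(-2, (err_step + 1) * dt)

    times = (out_steps[:n_out] + 1) * dt
    ids = out_ids[:n_out]
    keep = times >= 1e3 * config.warmup_discard
    output = SpikeRaster(ids[keep], times[keep], n, config.duration)

    traces = None
    trace_times = None
    if rec_ids.size:
        traces = {int(rid): v_rec[r] for r, rid in enumerate(rec_ids)}
        trace_times = (np.arange(n_steps) + 1) * dt
    echo = {
        "time_step": dt,
        "duration": config.duration,
        "warmup_discard": config.warmup_discard,
        "seed": config.seed,
        "n_neurons": n,
        "feedforward_gmax": network.feedforward_gmax,
        "connectivity": {
            k: getattr(network.connectivity, k)
            for k in ("weight_EE", "weight_EI", "weight_IE", "weight_II",
                      "decay_length_exc", "decay_length_inh",
                      "connection_radius_cutoff", "spatial_profile")
        },
    }
    return SimulationResult(output, input_raster, traces, trace_times, echo)


@njit(cache=True, fastmath=True)
def _integrate_single(n_steps, dt, v0, m0, h0, n0, g_exc_wave, g_inh_wave,
                      gL, VL, GNa, VNa, GK, VK, VE, VI, inv_c,
                      thr, lockout_steps, vmin_tab, inv_dv, tab):
    ntab = tab.shape[0]
    v_out = np.empty(n_steps)
    spikes = np.empty(n_steps, dtype=np.int64)
    n_sp = 0
    last = -10**9
    v, m, h, n = v0, m0, h0, n0
    for step in range(n_steps):
        v_old = v
        v, m, h, n = _step_neuron(v, m, h, n, g_exc_wave[step], g_inh_wave[step],
                                  gL, VL, GNa, VNa, GK, VK, VE, VI, inv_c, dt,
                                  vmin_tab, inv_dv, ntab, tab)
        if v_old < thr and v >= thr and step - last >= lockout_steps:
            last = step
            spikes[n_sp] = step
            n_sp += 1
        v_out[step] = v
    return v_out, spikes[:n_sp]


def run_single_neuron(neuron_params, g_exc_wave, g_inh_wave,
                      config: SimulationConfig):
    """Integrate one isolated neuron under given conductance waveforms.

    ``g_exc_wave``/``g_inh_wave`` are sampled at the integration step, in
    mS/cm^2.  Returns ``(times_ms, voltage_mV, spike_times_ms)``.  Mainly
    an oracle harness: the same update rule as the network engine, in
    isolation, so it can be checked against reference integrations.
    """
    g_exc_wave = np.ascontiguousarray(g_exc_wave, dtype=float)
    g_inh_wave = np.ascontiguousarray(g_inh_wave, dtype=float)
    if g_exc_wave.shape != g_inh_wave.shape:
        raise ValueError("conductance waveforms must have equal length")
    if np.any(g_exc_wave < 0) or np.any(g_inh_wave < 0):
        raise ValueError("conductances must be non-negative")
    p = neuron_params
    dt = config.time_step
    n_steps = g_exc_wave.size
    vmin_tab, inv_dv, tab = hh.build_gating_tables(p, dt)
    rest = hh.resting_state(p)
    v_out, spike_steps = _integrate_single(
        n_steps, dt, float(rest["V"][0]), float(rest["m"][0]),
        float(rest["h"][0]), float(rest["n"][0]),
        g_exc_wave, g_inh_wave,
        1e3 * p.leak_conductance, p.leak_reversal,
        1e3 * p.na_max_conductance, p.na_reversal,
        1e3 * p.k_max_conductance, p.k_reversal,
        p.exc_reversal, p.inh_reversal,
        1.0 / (1e6 * p.membrane_capacitance),
        p.spike_detection_threshold, int(round(p.spike_lockout / dt)),
        vmin_tab, inv_dv, tab)
    times = (np.arange(n_steps) + 1) * dt
    return times, v_out, (spike_steps + 1) * dt
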