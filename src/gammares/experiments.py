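"""End-to-end experiment orchestration: weight calibration, the input-
frequency sweep, the g_max -> spontaneous-frequency curve and the g_max
resonance sweep.

Every sweep produces a tidy :class:`pandas.DataFrame` (one row per
condition x repeat) plus a provenance record (config echo and seeds)
sufficient to re-run it bit-identically.  The static (unmodulated)
reference condition is simulated once per g_max and shared by all
driven conditions of the sweep.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import (
    detect_oscillation_peaks,
    phase_efficacy,
    population_rate,
    power_spectrum,
    gamma_phase,
    spike_phases,
    response_probability,
    response_enhancement,
    select_unpaired_spikes,
)
from .drive import DriveSpec, generate_poisson_raster
from .engine import run_simulation
from .network import Network, build_network
from .params import (
    ConfigurationError,
    GeometrySpec,
    ModelConfig,
    SimulationConfig,
)

#: default sweep grids
DEFAULT_FIN_GRID = tuple(float(f) for f in range(25, 60, 5))
DEFAULT_GMAX_GRID = tuple(float(g) for g in range(30, 75, 5))
RESONANCE_FIN_GRID = (40.0, 45.0, 50.0)


@dataclass
class SweepSpec:
    """What to sweep and under which drive conditions."""

    swept_parameter: str = "input_frequency"  # or "gmax"
    values: tuple[float, ...] = DEFAULT_FIN_GRID
    modulation_amplitudes: tuple[float, ...] = (10.0, 20.0)
    repeats: int = 3
    mean_rate: float = 40.0
    duration: float = 10.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.swept_parameter not in ("input_frequency", "gmax"):
            raise ConfigurationError(
                f"swept_parameter must be 'input_frequency' or 'gmax', "
                f"got {self.swept_parameter!r}"
            )
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")


@dataclass
class SweepResult:
    table: pd.DataFrame
    provenance: dict


def _spectrum_of(output, bin_width=2.0, segment_length=2.0, warmup=0.5):
    # the output raster excludes warmup spikes, so drop those empty bins
    _, rate = population_rate(output, bin_width)
    skip = int(round(1e3 * warmup / bin_width))
    rate = rate[skip:]
    available = rate.size * bin_width / 1e3  # s
    if segment_length >= available:
        segment_length = available / 2.0
    return power_spectrum(rate, bin_width, segment_length=segment_length)


def _static_run(network: Network, spec_like, gmax: float, seed: int,
                duration: float, mean_rate: float = 40.0,
                warmup: float = 0.5):
    net = network
    net.feedforward_gmax = gmax
    drive = DriveSpec(mean_rate=mean_rate, modulation_amplitude=0.0,
                      duration=duration, seed=seed)
    raster = generate_poisson_raster(drive, net.n_neurons)
    cfg = SimulationConfig(duration=duration, warmup_discard=warmup, seed=seed)
    return run_simulation(net, raster, cfg)


def spontaneous_peak(network: Network, gmax: float, seed: int = 0,
                     duration: float = 10.0, mean_rate: float = 40.0,
                     segment_length: float = 2.0) -> float | None:
    """Dominant spectral peak (Hz) under static drive at ``gmax``."""
    res = _static_run(network, None, gmax, seed, duration, mean_rate)
    spec = _spectrum_of(res.output_raster, segment_length=segment_length)
    return spec.dominant_peak


def calibrate_weights(target_frequency: float, config: ModelConfig,
                      seed: int = 0, tolerance: float = 1.0,
                      duration: float = 6.0, max_evals: int = 24,
                      network_builder=None) -> tuple[dict, pd.DataFrame]:
    """Tune the four recurrent coupling weights to a spontaneous-frequency
    target.

    Coordinate search (multiplicative steps on one weight at a time)
    until the static-drive dominant peak at the low end of the g_max
    sweep is within ``tolerance`` Hz of ``target_frequency``.  Returns
    the calibrated weight dict and the evaluation report; raises
    ``RuntimeError`` with the best-found report if the budget runs out.
    Deterministic for fixed seeds.
    """
    if not (30.0 <= target_frequency <= 70.0):
        raise ConfigurationError(
            f"target_frequency must lie in the 30-70 Hz gamma range, "
            f"got {target_frequency}"
        )
    gmax_low = config.gmax_bounds[0]
    weights = {
        "weight_EE": config.connectivity.weight_EE,
        "weight_EI": config.connectivity.weight_EI,
        "weight_IE": config.connectivity.weight_IE,
        "weight_II": config.connectivity.weight_II,
    }
    builder = network_builder or (lambda w: build_network(
        config.geometry,
        dataclasses.replace(config.connectivity, **w),
        config.neuron, seed=seed, feedforward_gmax=gmax_low,
    ))
    rows = []
    n_evals = 0

    def measure(w):
        nonlocal n_evals
        n_evals += 1
        net = builder(w)
        peak = spontaneous_peak(net, gmax_low, seed=seed, duration=duration)
        err = abs(peak - target_frequency) if peak is not None else np.inf
        rows.append({**w, "peak_hz": peak, "abs_error_hz": err, "eval": n_evals})
        return err

    best_err = measure(weights)
    if best_err <= tolerance:
        return weights, pd.DataFrame(rows)
    # multiplicative coordinate descent; inhibitory weights slow the rhythm,
    # excitatory ones speed it up, but the search only assumes "try both".
    order = ("weight_EI", "weight_II", "weight_IE", "weight_EE")
    factors = (0.85, 1.18)
    while n_evals < max_evals:
        improved = False
        for key in order:
            if n_evals >= max_evals or best_err <= tolerance:
                break
            if weights[key] == 0.0:
                continue
            for f in factors:
                trial = dict(weights)
                trial[key] = weights[key] * f
                err = measure(trial)
                if err < best_err:
                    best_err = err
                    weights = trial
                    improved = True
                    break
        if best_err <= tolerance:
            return weights, pd.DataFrame(rows)
        if not improved:
            break
    report = pd.DataFrame(rows)
    raise RuntimeError(
        f"calibration failed after {n_evals} evaluations; best error "
        f"{best_err:.2f} Hz\n{report.to_string()}"
    )


def make_fixture_network(config: ModelConfig, scale_factor: float = 1.0,
                         seed: int = 0, gmax: float | None = None) -> Network:
    """Reduced-scale network with per-neuron synaptic drive conserved.

    ``scale_factor`` is the fraction of neurons (and of sheet area) kept;
    density and the E/I split are preserved.  Recurrent weights are then
    multiplied, per source type, by the ratio of mean incoming
    spatial-weight sums in the full versus the reduced sheet, so each
    neuron receives the same expected recurrent drive as at full scale --
    this compensates both the smaller neighbourhood and its edge effects.
    """
    if not (0.0 < scale_factor <= 1.0):
        raise ConfigurationError(f"scale_factor must be in (0, 1], got {scale_factor}")
    g = config.geometry
    gmax = config.feedforward_gmax if gmax is None else gmax
    if scale_factor == 1.0:
        return build_network(g, config.connectivity, config.neuron,
                             seed=seed, feedforward_gmax=gmax)
    n_small = max(8, int(round(g.neuron_count * scale_factor)))
    side = float(np.sqrt(scale_factor))
    small_spec = GeometrySpec(
        sheet_width=g.sheet_width * side, sheet_height=g.sheet_height * side,
        neuron_count=n_small, excitatory_fraction=g.excitatory_fraction,
        grid_jitter=g.grid_jitter)
    net = build_network(small_spec, config.connectivity, config.neuron,
                        seed=seed, feedforward_gmax=gmax)
    full = build_network(g, config.connectivity, config.neuron,
                         seed=seed, feedforward_gmax=gmax)
    for exc in (True, False):
        src_full = full.geometry.is_excitatory == exc
        src_small = net.geometry.is_excitatory == exc
        drive_full = full.weights[src_full].sum(axis=0).mean()
        drive_small = net.weights[src_small].sum(axis=0).mean()
        if drive_small > 0:
            net.weights[src_small] *= drive_full / drive_small
    return net


def _analyse_condition(net, output, input_raster, static_stats,
                       unpaired_window=20.0, response_window=10.0):
    spec = _spectrum_of(output)
    klass, peaks = detect_oscillation_peaks(spec)
    stats = response_probability(input_raster, output,
                                 response_window=response_window)
    unpaired = select_unpaired_spikes(input_raster, unpaired_window)
    stats_unp = (response_probability(unpaired, output,
                                      response_window=response_window,
                                      condition="unpaired")
                 if unpaired.n_spikes else None)
    row = {
        "dominant_peak_hz": spec.dominant_peak,
        "secondary_peak_hz": spec.peak_frequencies[1] if len(spec.peak_frequencies) > 1 else None,
        "oscillation_class": klass,
        "response_probability": stats.response_probability,
        "response_delay_ms": stats.response_delay,
        "unpaired_probability": stats_unp.response_probability if stats_unp else None,
    }
    if static_stats is not None:
        d_prob, d_delay = response_enhancement(stats, static_stats)
        row["probability_enhancement"] = d_prob
        row["delay_decrement_ms"] = d_delay
    return row, stats


def run_frequency_sweep(network: Network, spec: SweepSpec,
                        warmup: float = 0.5) -> SweepResult:
    """Fig-2 style experiment: drive at each f_in and amplitude, compare
    against the shared static reference at the same g_max."""
    n = network.n_neurons
    rows = []
    for rep in range(spec.repeats):
        seed = spec.base_seed + 1000 * rep
        static = _static_run(network, spec, network.feedforward_gmax, seed,
                             spec.duration, spec.mean_rate, warmup)
        static_stats = response_probability(static.input_raster, static.output_raster)
        srow, _ = _analyse_condition(network, static.output_raster,
                                     static.input_raster, None)
        rows.append({"input_frequency_hz": None, "modulation_amplitude": 0.0,
                     "repeat": rep, **srow})
        for amp in spec.modulation_amplitudes:
            for fin in spec.values:
                # a zero-amplitude "modulated" drive is the static drive:
                # frequency is inert, so share the reference realisation
                drive_seed = seed if amp == 0 else seed + int(fin) * 7 + int(amp)
                drive = DriveSpec(spec.mean_rate, amp, fin, 0.0,
                                  spec.duration, seed=drive_seed)
                raster = generate_poisson_raster(drive, n)
                cfg = SimulationConfig(duration=spec.duration,
                                       warmup_discard=warmup, seed=seed)
                res = run_simulation(network, raster, cfg)
                row, _ = _analyse_condition(network, res.output_raster, raster,
                                            static_stats)
                rows.append({"input_frequency_hz": fin,
                             "modulation_amplitude": amp, "repeat": rep, **row})
    table = pd.DataFrame(rows)
    prov = {"spec": dataclasses.asdict(spec), "gmax": network.feedforward_gmax,
            "n_neurons": n}
    return SweepResult(table, prov)


def run_gmax_frequency_curve(network: Network, gmax_values=DEFAULT_GMAX_GRID,
                             duration: float = 6.0, seed: int = 0,
                             mean_rate: float = 40.0) -> pd.DataFrame:
    """Spontaneous-frequency curve f_out^s(g_max) under static drive."""
    rows = []
    for g in gmax_values:
        peak = spontaneous_peak(network, g, seed=seed, duration=duration,
                                mean_rate=mean_rate)
        rows.append({"gmax": g, "spontaneous_peak_hz": peak})
    df = pd.DataFrame(rows)
    peaks = df["spontaneous_peak_hz"].to_numpy(dtype=float)
    df.attrs["monotone_nondecreasing"] = bool(
        np.all(np.diff(peaks[np.isfinite(peaks)]) >= -1.0)
    )
    return df


def run_gmax_resonance_sweep(network: Network,
                             fin_values=RESONANCE_FIN_GRID,
                             gmax_values=DEFAULT_GMAX_GRID,
                             amplitude: float = 20.0,
                             duration: float = 4.0,
                             repeats: int = 3,
                             base_seed: int = 0,
                             mean_rate: float = 40.0,
                             warmup: float = 0.5) -> SweepResult:
    """Fig-4 style experiment: enhancement vs g_max per input frequency.

    For every g_max the static reference is simulated once per repeat and
    shared across input frequencies.  Returns per-condition rows and, in
    the provenance, the argmax g_max (resonance point) per f_in.
    """
    n = network.n_neurons
    rows = []
    for rep in range(repeats):
        for g in gmax_values:
            seed = base_seed + 1000 * rep
            network.feedforward_gmax = g
            static = _static_run(network, None, g, seed, duration, mean_rate,
                                 warmup)
            static_stats = response_probability(static.input_raster,
                                                static.output_raster)
            for fin in fin_values:
                drive = DriveSpec(mean_rate, amplitude, fin, 0.0, duration,
                                  seed=seed + int(fin) * 7)
                raster = generate_poisson_raster(drive, n)
                cfg = SimulationConfig(duration=duration,
                                       warmup_discard=warmup, seed=seed)
                res = run_simulation(network, raster, cfg)
                stats = response_probability(raster, res.output_raster)
                d_prob, d_delay = response_enhancement(stats, static_stats)
                rows.append({
                    "gmax": g, "input_frequency_hz": fin, "repeat": rep,
                    "static_probability": static_stats.response_probability,
                    "driven_probability": stats.response_probability,
                    "probability_enhancement": d_prob,
                    "delay_decrement_ms": d_delay,
                })
    table = pd.DataFrame(rows)
    mean = table.groupby(["input_frequency_hz", "gmax"], as_index=False)[
        "probability_enhancement"].mean()
    resonance_points = {
        float(fin): float(sub.loc[sub["probability_enhancement"].idxmax(), "gmax"])
        for fin, sub in mean.groupby("input_frequency_hz")
    }
    prov = {"resonance_points": resonance_points, "amplitude": amplitude,
            "duration": duration, "repeats": repeats, "base_seed": base_seed,
            "n_neurons": n, "gmax_values": list(gmax_values)}
    return SweepResult(table, prov)


def phase_efficacy_experiment(network: Network, fin: float | None = None,
                              amplitude: float = 20.0, duration: float = 6.0,
                              seed: int = 0, mean_rate: float = 40.0,
                              n_bins: int = 12, warmup: float = 0.5,
                              repeats: int = 1):
    """Drive at (or near) the spontaneous frequency and measure the
    phase-binned efficacy of unpaired input spikes.

    Returns ``(curve, f_in_used)``.  When ``fin`` is None the spontaneous
    peak under static drive is measured first and used as the drive
    frequency (the resonant condition).  With ``repeats`` > 1 the per-bin
    response counts of independently seeded runs are pooled before
    normalising, which is the package's standard estimator for the
    peak-efficacy phase (the pass band is broad, so single short runs
    leave the argmax bin noise-limited).
    """
    from .analysis import efficacy_from_counts, phase_response_counts

    if fin is None:
        fin = spontaneous_peak(network, network.feedforward_gmax, seed=seed,
                               duration=duration, mean_rate=mean_rate)
        if fin is None:
            raise RuntimeError("no spontaneous peak found to drive at")
    tot_spk = np.zeros(n_bins, dtype=np.int64)
    tot_hit = np.zeros(n_bins, dtype=np.int64)
    for rep in range(repeats):
        rep_seed = seed + 1000 * rep
        drive = DriveSpec(mean_rate, amplitude, float(fin), 0.0, duration,
                          seed=rep_seed)
        raster = generate_poisson_raster(drive, network.n_neurons)
        cfg = SimulationConfig(duration=duration, warmup_discard=warmup,
                               seed=rep_seed)
        res = run_simulation(network, raster, cfg)
        times, rate = population_rate(res.output_raster, 2.0)
        keep = times >= 1e3 * warmup
        _, analytic = gamma_phase(times[keep], rate[keep], center=float(fin))
        unpaired = select_unpaired_spikes(raster, 20.0)
        mask = unpaired.times >= 1e3 * warmup
        unpaired_late = type(unpaired)(unpaired.neuron_ids[mask],
                                       unpaired.times[mask],
                                       unpaired.population_size,
                                       unpaired.duration)
        phases = spike_phases(unpaired_late.times, times[keep], analytic)
        n_spk, n_hit = phase_response_counts(unpaired_late, res.output_raster,
                                             phases, n_bins=n_bins)
        tot_spk += n_spk
        tot_hit += n_hit
    return efficacy_from_counts(tot_spk, tot_hit), float(fin)
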