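"""Spike-train measurements: rates, spectra, ISIs, correlograms,
response statistics, gamma phase and phase-binned input efficacy.

All operations consume :class:`gammares.drive.SpikeRaster` objects and
return small result containers that serialise to tidy tables.  The
population firing rate is the LFP proxy throughout: spectra, phase and
peak classification are computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .drive import SpikeRaster

#: analysis band for oscillation peaks, Hz
GAMMA_BAND = (20.0, 130.0)


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz
    power: np.ndarray
    peak_frequencies: list[float] = field(default_factory=list)
    peak_prominences: list[float] = field(default_factory=list)
    baseline: float = 0.0

    @property
    def dominant_peak(self) -> float | None:
        return self.peak_frequencies[0] if self.peak_frequencies else None


@dataclass
class ISIHistogram:
    bin_edges: np.ndarray  # ms
    counts: dict[str, np.ndarray]
    cv: dict[str, float]
    sharpness: dict[str, float]  # 1/CV, capped


@dataclass
class Correlogram:
    lags: np.ndarray  # ms
    normalized_coincidence: np.ndarray  # baseline 1 for independent trains

    @property
    def modulation_depth(self) -> float:
        """Peak-to-trough span of the normalised correlogram."""
        c = self.normalized_coincidence
        return float(c.max() - c.min())


@dataclass
class ResponseStats:
    response_probability: float
    response_delay: float | None  # ms; None when no input spike was answered
    n_input_spikes: int
    condition: str = "all"


@dataclass
class PhaseEfficacyCurve:
    phase_bin_centers: np.ndarray  # degrees, (-180, 180]
    normalized_efficacy: np.ndarray
    spike_counts: np.ndarray
    max_efficacy: float
    peak_phase: float


def population_rate(raster: SpikeRaster, bin_width: float = 2.0,
                    type_filter: np.ndarray | None = None):
    """Population firing rate in spikes/s per neuron.

    ``type_filter`` is an optional boolean mask over neuron ids (e.g. the
    excitatory cells); ``bin_width`` in ms.  Returns ``(bin_centers_ms,
    rate)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t_end = 1e3 * raster.duration
    edges = np.arange(0.0, t_end + bin_width / 2, bin_width)
    if type_filter is not None:
        mask = type_filter[raster.neuron_ids]
        times = raster.times[mask]
        n_pop = int(np.asarray(type_filter).sum())
    else:
        times = raster.times
        n_pop = raster.population_size
    counts, _ = np.histogram(times, bins=edges)
    rate = counts / (n_pop * bin_width * 1e-3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def power_spectrum(rate_series: np.ndarray, bin_width: float = 2.0,
                   segment_length: float = 2.0, overlap: float = 0.5,
                   baseline_factor: float = 3.0) -> PowerSpectrum:
    """Averaged-periodogram (Welch) spectrum of a rate series.

    ``bin_width`` in ms, ``segment_length`` in s.  The series is mean
    subtracted.  Peaks are detected within the gamma analysis band
    (20-130 Hz) by prominence, and the spectral baseline is the median
    in-band power away from peaks.
    """
    rate_series = np.asarray(rate_series, dtype=float)
    fs = 1e3 / bin_width
    nperseg = int(round(segment_length * fs))
    if rate_series.size <= nperseg:
        raise ValueError("rate series must be longer than one segment")
    freqs, pxx = signal.welch(rate_series - rate_series.mean(), fs=fs,
                              nperseg=nperseg,
                              noverlap=int(round(overlap * nperseg)))
    spec = PowerSpectrum(freqs, pxx)
    _find_peaks(spec, baseline_factor)
    return spec


def _find_peaks(spec: PowerSpectrum, baseline_factor: float) -> None:
    lo, hi = GAMMA_BAND
    band = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    f_band, p_band = spec.frequencies[band], spec.power[band]
    if p_band.size < 5:
        return
    idx, props = signal.find_peaks(p_band, prominence=0.0)
    if idx.size == 0:
        return
    order = np.argsort(props["prominences"])[::-1]
    idx, prom = idx[order], props["prominences"][order]
    # baseline: median in-band power excluding +-3 Hz around candidate peaks
    excl = np.zeros(f_band.size, dtype=bool)
    for i in idx[:5]:
        excl |= np.abs(f_band - f_band[i]) <= 3.0
    baseline = float(np.median(p_band[~excl])) if (~excl).any() else float(np.median(p_band))
    spec.baseline = baseline
    keep = p_band[idx] > baseline_factor * baseline
    freqs, proms = f_band[idx[keep]], prom[keep]
    powers = p_band[idx[keep]]
    # a "peak" worth classifying is a distinct rhythm: suppress harmonics
    # of stronger peaks, merge shoulders within 5 Hz of a stronger peak,
    # and require secondary peaks to reach 2% of the dominant power
    kept_f: list[float] = []
    kept_p: list[float] = []
    p_dom = powers[0] if powers.size else 0.0
    for f, p, pw in zip(freqs, proms, powers):
        if kept_f and pw < 0.02 * p_dom:
            continue
        shoulder = any(abs(f - f0) <= 5.0 for f0 in kept_f)
        harmonic = any(abs(f - k * f0) <= 4.0 for f0 in kept_f for k in (2, 3))
        if not (shoulder or harmonic):
            kept_f.append(float(f))
            kept_p.append(float(p))
    spec.peak_frequencies = kept_f
    spec.peak_prominences = kept_p


def detect_oscillation_peaks(spec: PowerSpectrum, baseline_factor: float = 3.0):
    """Classify the oscillation regime of a spectrum.

    Returns ``(classification, peaks)`` where classification is
    ``"coexisting"`` (two or more peaks above ``baseline_factor`` times
    the spectral baseline), ``"resonant"`` (exactly one) or ``"none"``.
    """
    _find_peaks(spec, baseline_factor)
    peaks = spec.peak_frequencies
    if len(peaks) >= 2:
        return "coexisting", peaks
    if len(peaks) == 1:
        return "resonant", peaks
    return "none", peaks


_SHARPNESS_CAP = 1e3


def isi_distribution(raster: SpikeRaster, types: np.ndarray | None = None,
                     bin_width: float = 1.0, max_isi: float = 100.0) -> ISIHistogram:
    """Pooled per-type inter-spike-interval histogram with 1/CV sharpness.

    ``types`` is a boolean is-excitatory mask per neuron id; without it
    all neurons are pooled under type ``"all"``.
    """
    trains = raster.by_neuron()
    groups: dict[str, list[np.ndarray]] = {}
    for nid, tr in enumerate(trains):
        if tr.size < 2:
            continue
        if types is None:
            key = "all"
        else:
            key = "E" if types[nid] else "I"
        groups.setdefault(key, []).append(np.diff(tr))
    if not groups:
        raise ValueError("need at least one neuron with >= 2 spikes")
    edges = np.arange(0.0, max_isi + bin_width / 2, bin_width)
    counts, cvs, sharp = {}, {}, {}
    for key, isis in groups.items():
        pooled = np.concatenate(isis)
        counts[key], _ = np.histogram(pooled, bins=edges)
        mu = pooled.mean()
        cv = float(pooled.std() / mu) if mu > 0 else np.inf
        cvs[key] = cv
        sharp[key] = float(min(1.0 / cv, _SHARPNESS_CAP)) if cv > 0 else _SHARPNESS_CAP
    return ISIHistogram(edges, counts, cvs, sharp)


def spike_correlogram(raster_a: SpikeRaster, raster_b: SpikeRaster,
                      max_lag: float = 50.0, bin_width: float = 1.0) -> Correlogram:
    """Cross-neuron coincidence histogram normalised to 1 for independence.

    Counts spike-time differences between all neuron pairs of the two
    rasters (excluding same-neuron pairs when the rasters share a
    population) and divides by the expected count for independent
    homogeneous trains of the same rates, so uncorrelated activity gives
    a flat correlogram at unity.
    """
    if raster_a.n_spikes == 0 or raster_b.n_spikes == 0:
        raise ValueError("correlogram requires non-empty rasters")
    same = raster_a is raster_b or (
        raster_a.population_size == raster_b.population_size
        and raster_a.n_spikes == raster_b.n_spikes
        and np.array_equal(raster_a.times, raster_b.times)
        and np.array_equal(raster_a.neuron_ids, raster_b.neuron_ids)
    )
    t_end = 1e3 * max(raster_a.duration, raster_b.duration)
    n_bins_t = int(np.ceil(t_end / bin_width))
    lag_bins = int(round(max_lag / bin_width))

    ca = np.bincount((raster_a.times / bin_width).astype(int), minlength=n_bins_t)
    cb = np.bincount((raster_b.times / bin_width).astype(int), minlength=n_bins_t)
    # pooled cross-correlation via FFT
    nfft = 1
    while nfft < 2 * n_bins_t:
        nfft *= 2
    fa, fb = np.fft.rfft(ca, nfft), np.fft.rfft(cb, nfft)
    xc = np.fft.irfft(np.conj(fa) * fb, nfft)
    lags = np.arange(-lag_bins, lag_bins + 1)
    counts = xc[lags % nfft]

    if same:
        # remove same-neuron pairs (incl. zero-lag self pairs)
        for tr in raster_a.by_neuron():
            if tr.size == 0:
                continue
            for lag_idx, lag in enumerate(lags):
                lo = np.searchsorted(tr, tr + (lag - 0.5) * bin_width, side="left")
                hi = np.searchsorted(tr, tr + (lag + 0.5) * bin_width, side="left")
                counts[lag_idx] -= (hi - lo).sum()

    # expectation under independence, per pair: Ni*Nj*bin/T
    na = np.bincount(raster_a.neuron_ids, minlength=raster_a.population_size)
    nb = np.bincount(raster_b.neuron_ids, minlength=raster_b.population_size)
    total = float(na.sum()) * float(nb.sum())
    if same:
        total -= float((na.astype(float) ** 2).sum())
    expected = total * bin_width / t_end
    if expected <= 0:
        raise ValueError("degenerate raster: no cross-neuron pairs to normalise by")
    return Correlogram(lags * bin_width, counts / expected)


def select_unpaired_spikes(raster: SpikeRaster, isolation_window: float = 20.0) -> SpikeRaster:
    """Keep only spikes with no same-neuron neighbour within the window.

    For a homogeneous Poisson train of rate r the retained fraction is
    exp(-2 r w).  Idempotent: isolated spikes stay isolated.
    """
    if isolation_window <= 0:
        raise ValueError("isolation_window must be positive")
    keep_ids, keep_times = [], []
    for nid, tr in enumerate(raster.by_neuron()):
        if tr.size == 0:
            continue
        gap_prev = np.diff(tr, prepend=tr[0] - 2 * isolation_window)
        gap_next = np.diff(tr, append=tr[-1] + 2 * isolation_window)
        mask = (gap_prev > isolation_window) & (gap_next > isolation_window)
        keep_ids.append(np.full(int(mask.sum()), nid, dtype=np.int64))
        keep_times.append(tr[mask])
    ids = np.concatenate(keep_ids) if keep_ids else np.empty(0, dtype=np.int64)
    times = np.concatenate(keep_times) if keep_times else np.empty(0)
    return SpikeRaster(ids, times, raster.population_size, raster.duration)


def response_probability(input_raster: SpikeRaster, output_raster: SpikeRaster,
                         afferent_map: np.ndarray | None = None,
                         response_window: float = 10.0,
                         condition: str = "all") -> ResponseStats:
    """Probability and mean latency of cortical responses to input spikes.

    An input spike at t on afferent ``i`` is "answered" if its target
    neuron (``afferent_map[i]``, identity by default) emits at least one
    spike in ``(t, t + window]`` ms; the delay is the mean latency to the
    first such spike over answered inputs, or None when nothing was
    answered.
    """
    if response_window <= 0:
        raise ValueError("response_window must be positive")
    if afferent_map is None:
        afferent_map = np.arange(input_raster.population_size)
    out_trains = output_raster.by_neuron()
    n_in = 0
    n_resp = 0
    delays = []
    in_trains = input_raster.by_neuron()
    for aff, tr in enumerate(in_trains):
        if tr.size == 0:
            continue
        tgt = int(afferent_map[aff])
        out = out_trains[tgt] if tgt < len(out_trains) else np.empty(0)
        n_in += tr.size
        if out.size == 0:
            continue
        idx = np.searchsorted(out, tr, side="right")
        valid = idx < out.size
        first = np.where(valid, out[np.minimum(idx, out.size - 1)], np.inf)
        lat = first - tr
        hit = (lat > 0) & (lat <= response_window)
        n_resp += int(hit.sum())
        if hit.any():
            delays.append(lat[hit])
    if n_in == 0:
        raise ValueError("input raster has no spikes")
    prob = n_resp / n_in
    delay = float(np.concatenate(delays).mean()) if delays else None
    return ResponseStats(prob, delay, n_in, condition)


def gamma_phase(rate_times: np.ndarray, rate_series: np.ndarray,
                band: tuple[float, float] | None = None,
                center: float | None = None, half_width: float = 10.0):
    """Instantaneous gamma phase of the population rate, in degrees.

    Band-passes the series around the dominant oscillation (``center``
    +- ``half_width`` Hz, or an explicit ``band``), takes the analytic
    signal and returns its phase with the convention that 0 degrees sits
    at the cycle peaks of the band-passed rate, in (-180, 180].  Returns
    ``(phase_degrees, analytic_signal)``.
    """
    rate_series = np.asarray(rate_series, dtype=float)
    dt_s = (rate_times[1] - rate_times[0]) * 1e-3
    fs = 1.0 / dt_s
    if band is None:
        if center is None:
            spec = power_spectrum(rate_series, bin_width=1e3 * dt_s)
            if spec.dominant_peak is None:
                raise ValueError("no dominant oscillation peak to phase-lock to")
            center = spec.dominant_peak
        band = (max(center - half_width, 1.0), center + half_width)
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {fs / 2}")
    n_cycles = (rate_times[-1] - rate_times[0]) * 1e-3 * lo
    if n_cycles < 10:
        raise ValueError("series must cover at least 10 oscillation cycles")
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rate_series - rate_series.mean())
    analytic = signal.hilbert(filtered)
    # rotate so the raw rate's cycle maxima map to 0 degrees: the gamma
    # cycle is asymmetric (fast rise, slower decay), so the peak of the
    # band-passed fundamental can lead or lag the true rate peak
    raw_peaks, _ = signal.find_peaks(rate_series,
                                     distance=max(1, int(0.7 / (hi * dt_s))))
    interior = raw_peaks[(raw_peaks > 10) & (raw_peaks < rate_series.size - 10)]
    if interior.size >= 5:
        mean_vec = np.mean(analytic[interior] / np.abs(analytic[interior]))
        if np.abs(mean_vec) > 0.2:  # coherent peak phase: apply rotation
            analytic = analytic * np.conj(mean_vec / np.abs(mean_vec))
    phase = np.rad2deg(np.angle(analytic))
    phase = np.where(phase <= -180.0, phase + 360.0, phase)
    return phase, analytic


def spike_phases(spike_times: np.ndarray, rate_times: np.ndarray,
                 analytic: np.ndarray) -> np.ndarray:
    """Phase (degrees) of each spike, interpolated on the analytic signal."""
    re = np.interp(spike_times, rate_times, analytic.real)
    im = np.interp(spike_times, rate_times, analytic.imag)
    ph = np.rad2deg(np.arctan2(im, re))
    return np.where(ph <= -180.0, ph + 360.0, ph)


def phase_efficacy(unpaired_inputs: SpikeRaster, output_raster: SpikeRaster,
                   input_phases: np.ndarray,
                   afferent_map: np.ndarray | None = None,
                   response_window: float = 10.0,
                   n_bins: int = 12) -> PhaseEfficacyCurve:
    """Normalised response efficacy of input spikes versus gamma phase.

    ``input_phases`` assigns each spike of ``unpaired_inputs`` (in raster
    order) a phase in (-180, 180].  Per-bin response probabilities are
    divided by their spike-count-weighted mean, so the weighted mean of
    the curve is exactly 1.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    input_phases = np.asarray(input_phases, dtype=float)
    if input_phases.shape != unpaired_inputs.times.shape:
        raise ValueError("one phase per unpaired input spike is required")
    n_spk, n_hit = phase_response_counts(unpaired_inputs, output_raster,
                                         input_phases, afferent_map,
                                         response_window, n_bins)
    return efficacy_from_counts(n_spk, n_hit)


def phase_response_counts(unpaired_inputs: SpikeRaster, output_raster: SpikeRaster,
                          input_phases: np.ndarray,
                          afferent_map: np.ndarray | None = None,
                          response_window: float = 10.0,
                          n_bins: int = 12):
    """Per-phase-bin input-spike and answered-input counts.

    The raw material of the efficacy curve; counts from repeated runs can
    be summed before normalising (see :func:`efficacy_from_counts`).
    """
    input_phases = np.asarray(input_phases, dtype=float)
    if afferent_map is None:
        afferent_map = np.arange(unpaired_inputs.population_size)
    out_trains = output_raster.by_neuron()
    responded = np.zeros(unpaired_inputs.n_spikes, dtype=bool)
    for k, (aff, t) in enumerate(zip(unpaired_inputs.neuron_ids, unpaired_inputs.times)):
        out = out_trains[int(afferent_map[aff])]
        if out.size == 0:
            continue
        i = np.searchsorted(out, t, side="right")
        if i < out.size and 0 < out[i] - t <= response_window:
            responded[k] = True
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    which = np.clip(np.digitize(input_phases, edges) - 1, 0, n_bins - 1)
    n_spk = np.bincount(which, minlength=n_bins)
    n_hit = np.bincount(which[responded], minlength=n_bins)
    return n_spk, n_hit


def efficacy_from_counts(n_spk: np.ndarray, n_hit: np.ndarray) -> PhaseEfficacyCurve:
    """Normalise per-bin response counts into a PhaseEfficacyCurve."""
    n_bins = n_spk.size
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    with np.errstate(invalid="ignore"):
        p = np.where(n_spk > 0, n_hit / np.maximum(n_spk, 1), 0.0)
    weighted_mean = float((n_spk * p).sum() / n_spk.sum())
    if weighted_mean <= 0:
        raise ValueError("no responses at any phase; efficacy undefined")
    eff = p / weighted_mean
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(eff))
    return PhaseEfficacyCurve(centers, eff, n_spk, float(eff[peak]), float(centers[peak]))


def response_enhancement(stats_condition: ResponseStats,
                         stats_static: ResponseStats):
    """Probability enhancement and delay decrement relative to static drive.

    Returns ``(probability_enhancement, delay_decrement_ms)``; the
    decrement is ``delay(static) - delay(condition)`` so a negative value
    means the condition slowed responses, or None when either delay is
    undefined.
    """
    d_prob = stats_condition.response_probability - stats_static.response_probability
    if stats_condition.response_delay is None or stats_static.response_delay is None:
        return d_prob, None
    return d_prob, stats_static.response_delay - stats_condition.response_delay


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy one-row-per-condition table of analysis outputs."""
    return pd.DataFrame(rows)
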