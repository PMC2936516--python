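"""Spike-train measurements: spectra, ISIs, correlograms, responses,
phase and efficacy."""

import numpy as np
import pytest

from gammares.analysis import (
    detect_oscillation_peaks,
    gamma_phase,
    isi_distribution,
    phase_efficacy,
    population_rate,
    power_spectrum,
    response_enhancement,
    response_probability,
    select_unpaired_spikes,
    spike_correlogram,
    spike_phases,
    ResponseStats,
)
from gammares.drive import DriveSpec, SpikeRaster, generate_poisson_raster


def _raster(ids, times, n, dur):
    return SpikeRaster(np.asarray(ids, dtype=int), np.asarray(times, float), n, dur)


class TestPopulationRate:
    def test_empty_raster_gives_zero_series(self):
        r = _raster([], [], 10, 1.0)
        _, rate = population_rate(r, 10.0)
        assert rate.shape == (100,)
        assert not rate.any()

    def test_poisson_rate_recovered(self):
        r = generate_poisson_raster(DriveSpec(40.0, duration=20.0, seed=1), 30)
        _, rate = population_rate(r, 10.0)
        se = np.sqrt(40.0 / (30 * 20.0))
        assert rate.mean() == pytest.approx(40.0, abs=3 * se)


class TestPowerSpectrum:
    def make_series(self, freqs, duration=20.0, fs=500.0, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, duration, 1 / fs)
        x = sum(np.sin(2 * np.pi * f * t) for f in freqs)
        return np.asarray(x) + noise * rng.standard_normal(t.size)

    def test_single_sinusoid_peak_located(self):
        spec = power_spectrum(self.make_series([38.0]), bin_width=2.0)
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(spec.dominant_peak - 38.0) <= df

    def test_two_sinusoids_two_peaks(self):
        spec = power_spectrum(self.make_series([30.0, 50.0]), bin_width=2.0)
        klass, peaks = detect_oscillation_peaks(spec)
        assert klass == "coexisting"
        assert {round(p / 10) for p in peaks[:2]} == {3, 5}

    def test_single_sinusoid_classified_resonant(self):
        spec = power_spectrum(self.make_series([38.0]), bin_width=2.0)
        klass, _ = detect_oscillation_peaks(spec)
        assert klass == "resonant"

    def test_white_noise_has_no_peak(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(20000)  # 40 s at 500 Hz: ~39 segments
        spec = power_spectrum(x, bin_width=2.0)
        klass, _ = detect_oscillation_peaks(spec)
        assert klass == "none"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.zeros(100), bin_width=2.0, segment_length=2.0)


class TestISI:
    def test_periodic_train_maximal_sharpness(self):
        times = np.arange(10.0, 1000.0, 25.0)
        r = _raster(np.zeros(times.size), times, 1, 1.0)
        hist = isi_distribution(r)
        assert hist.cv["all"] == pytest.approx(0.0, abs=1e-12)
        assert hist.sharpness["all"] == 1e3  # capped

    def test_poisson_train_cv_one(self):
        r = generate_poisson_raster(DriveSpec(40.0, duration=50.0, seed=8), 10)
        hist = isi_distribution(r, max_isi=500.0)
        assert hist.cv["all"] == pytest.approx(1.0, abs=0.1)

    def test_types_pooled_separately(self):
        ids = [0, 0, 0, 1, 1, 1]
        times = [10, 35, 60, 10, 20, 90]
        r = _raster(ids, times, 2, 0.2)
        types = np.array([True, False])
        hist = isi_distribution(r, types=types)
        assert set(hist.counts) == {"E", "I"}

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            isi_distribution(_raster([0], [10.0], 1, 1.0))


class TestCorrelogram:
    def test_independent_poisson_flat_at_unity(self):
        r = generate_poisson_raster(DriveSpec(40.0, duration=40.0, seed=31), 25)
        cg = spike_correlogram(r, r, max_lag=50.0, bin_width=2.0)
        assert cg.normalized_coincidence.mean() == pytest.approx(1.0, abs=0.02)
        assert np.abs(cg.normalized_coincidence - 1.0).max() < 0.15

    def test_symmetric_for_auto_population(self):
        r = generate_poisson_raster(DriveSpec(40.0, duration=20.0, seed=32), 10)
        cg = spike_correlogram(r, r, max_lag=30.0, bin_width=1.0)
        c = cg.normalized_coincidence
        np.testing.assert_allclose(c, c[::-1], rtol=1e-10)

    def test_driven_raster_has_stronger_modulation_than_static(self):
        static = generate_poisson_raster(DriveSpec(40.0, duration=30.0, seed=33), 20)
        driven = generate_poisson_raster(
            DriveSpec(40.0, 20.0, 38.0, 0.0, duration=30.0, seed=33), 20)
        cg_s = spike_correlogram(static, static)
        cg_d = spike_correlogram(driven, driven)
        assert cg_d.modulation_depth > 2 * cg_s.modulation_depth

    def test_empty_raster_rejected(self):
        r = _raster([], [], 3, 1.0)
        full = generate_poisson_raster(DriveSpec(40.0, duration=1.0, seed=1), 3)
        with pytest.raises(ValueError):
            spike_correlogram(r, full)


class TestUnpairedSelection:
    def test_direct_rule_application(self):
        r = _raster([0, 0, 0], [100.0, 110.0, 200.0], 1, 0.5)
        kept = select_unpaired_spikes(r, 20.0)
        assert kept.times.tolist() == [200.0]

    def test_wide_gaps_unchanged_and_idempotent(self):
        r = _raster([0, 0, 0, 1], [50.0, 100.0, 150.0, 60.0], 2, 0.3)
        kept = select_unpaired_spikes(r, 20.0)
        assert kept.n_spikes == 4
        again = select_unpaired_spikes(kept, 20.0)
        assert np.array_equal(again.times, kept.times)

    def test_poisson_retention_matches_analytic_thinning(self):
        # P(no neighbour within +-w) = exp(-2 r w) = exp(-1.6) ~ 0.2019
        r = generate_poisson_raster(DriveSpec(40.0, duration=60.0, seed=13), 20)
        kept = select_unpaired_spikes(r, 20.0)
        frac = kept.n_spikes / r.n_spikes
        expected = np.exp(-2 * 40.0 * 0.020)
        se = np.sqrt(expected * (1 - expected) / r.n_spikes)
        assert abs(frac - expected) < 3 * se


class TestResponseProbability:
    def test_shifted_output_responds_perfectly(self):
        # well-separated inputs so each output answers exactly one input
        times = np.tile(np.arange(20.0, 5000.0, 50.0), 4)
        ids = np.repeat(np.arange(4), times.size // 4)
        inp = SpikeRaster(ids, times, 4, 5.0)
        out = SpikeRaster(inp.neuron_ids, inp.times + 3.0, 4, 5.01)
        stats = response_probability(inp, out, response_window=10.0)
        assert stats.response_probability == pytest.approx(1.0)
        assert stats.response_delay == pytest.approx(3.0)
        assert stats.n_input_spikes == inp.n_spikes

    def test_empty_output_probability_zero_delay_missing(self):
        inp = generate_poisson_raster(DriveSpec(20.0, duration=2.0, seed=3), 4)
        out = _raster([], [], 4, 2.0)
        stats = response_probability(inp, out)
        assert stats.response_probability == 0.0
        assert stats.response_delay is None

    def test_afferent_map_redirects_targets(self):
        inp = _raster([0], [100.0], 2, 0.5)
        out = _raster([1], [104.0], 2, 0.5)
        direct = response_probability(inp, out)
        mapped = response_probability(inp, out, afferent_map=np.array([1, 0]))
        assert direct.response_probability == 0.0
        assert mapped.response_probability == 1.0


class TestGammaPhaseAndEfficacy:
    def make_sinusoid_rate(self, f=40.0, duration_s=2.0, bin_ms=2.0):
        t = np.arange(bin_ms, duration_s * 1e3 + bin_ms / 2, bin_ms)
        rate = 10.0 + 5.0 * np.cos(2 * np.pi * f * t / 1e3)
        return t, rate

    def test_sinusoid_phase_zero_at_maxima(self):
        t, rate = self.make_sinusoid_rate()
        phase, analytic = gamma_phase(t, rate, center=40.0)
        interior = (t > 200.0) & (t < t[-1] - 200.0)  # avoid filter edges
        ti, ri = t[interior], rate[interior]
        peaks = ti[np.argsort(ri)[-10:]]
        ph = spike_phases(peaks, t, analytic)
        assert np.abs(ph).max() < 15.0

    def test_phase_advances_monotonically_within_cycles(self):
        t, rate = self.make_sinusoid_rate()
        phase, _ = gamma_phase(t, rate, center=40.0)
        d = np.diff(phase[100:400])
        wrapped = np.where(d < -180, d + 360, d)
        assert np.all(wrapped > 0)

    def test_flat_responder_gives_unit_curve(self):
        inp = generate_poisson_raster(DriveSpec(10.0, duration=20.0, seed=5), 10)
        out = SpikeRaster(inp.neuron_ids, np.minimum(inp.times + 2.0, 20e3),
                          10, 20.0)
        rng = np.random.default_rng(0)
        phases = rng.uniform(-180, 180, inp.n_spikes)
        curve = phase_efficacy(inp, out, phases, n_bins=12)
        np.testing.assert_allclose(curve.normalized_efficacy, 1.0, atol=1e-9)
        assert curve.max_efficacy == pytest.approx(1.0)

    def test_single_bin_responder_normalisation_arithmetic(self):
        n = 1200
        ids = np.zeros(n, dtype=int)
        times = np.linspace(10, 50e3 - 10, n)
        inp = SpikeRaster(ids, times, 1, 50.0)
        rng = np.random.default_rng(1)
        phases = rng.uniform(-180, 180, n)
        in_bin = (phases > 0) & (phases <= 30)  # exactly one bin of 12
        out_times = np.sort(times[in_bin] + 1.0)
        out = SpikeRaster(np.zeros(out_times.size, dtype=int), out_times, 1, 50.0)
        curve = phase_efficacy(inp, out, phases, n_bins=12)
        # weighted mean exactly 1; responding bin's efficacy ~ 12, rest 0
        w_mean = (curve.spike_counts * curve.normalized_efficacy).sum() / n
        assert w_mean == pytest.approx(1.0, rel=1e-12)
        assert curve.max_efficacy == pytest.approx(12.0, rel=0.1)
        assert curve.peak_phase == pytest.approx(15.0)

    def test_weighted_mean_exactly_one_for_random_responder(self):
        inp = generate_poisson_raster(DriveSpec(10.0, duration=30.0, seed=6), 5)
        rng = np.random.default_rng(2)
        mask = rng.uniform(size=inp.n_spikes) < 0.3
        out_times = np.sort(inp.times[mask] + rng.uniform(0.5, 8.0, mask.sum()))
        out_ids = inp.neuron_ids[mask][np.argsort(inp.times[mask])]
        out = SpikeRaster(out_ids, out_times, 5, 30.001)
        phases = rng.uniform(-180, 180, inp.n_spikes)
        curve = phase_efficacy(inp, out, phases, n_bins=12)
        w_mean = (curve.spike_counts * curve.normalized_efficacy).sum() / \
            curve.spike_counts.sum()
        assert w_mean == pytest.approx(1.0, rel=1e-12)


class TestEnhancement:
    def test_identical_conditions_zero(self):
        s = ResponseStats(0.3, 5.0, 100)
        assert response_enhancement(s, s) == (0.0, 0.0)

    def test_probability_difference(self):
        a = ResponseStats(0.30, 6.0, 100)
        b = ResponseStats(0.22, 6.0, 100)
        assert response_enhancement(a, b)[0] == pytest.approx(0.08)

    def test_delay_decrement_sign_convention(self):
        cond = ResponseStats(0.3, 8.0, 100)
        static = ResponseStats(0.3, 6.0, 100)
        _, dec = response_enhancement(cond, static)
        assert dec == pytest.approx(-2.0)  # negative: condition is slower

    def test_missing_delay_propagates(self):
        cond = ResponseStats(0.1, None, 50)
        static = ResponseStats(0.2, 6.0, 50)
        d_prob, dec = response_enhancement(cond, static)
        assert dec is None
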