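import dataclasses

import numpy as np
import pytest
from numpy.testing import assert_allclose

from ovispindle import (
    DetectionConfig,
    Recording,
    accepted_events,
    band_power_envelope,
    baseline_threshold,
    classical_events,
    detect_spindles,
)
from ovispindle.spindle_detection import (
    PowerEnvelope,
    classical_band_filter,
    count_positive_peaks,
    detect_candidates,
    is_noise_spike,
    read_events,
    refine_boundaries,
    spectral_features,
    write_events,
)
from ovispindle.synthetic_data import GroundTruthEvent, event_waveform

RATE = 250.0


def sine_rec(freq, amp=1.0, dur=4.0, rate=RATE):
    t = np.arange(int(dur * rate)) / rate
    return Recording(amp * np.sin(2 * np.pi * freq * t), rate, ("A1-L",))


def make_env(values, rate=RATE):
    return PowerEnvelope(np.atleast_2d(np.asarray(values, float)), rate,
                         (5.0, 16.0), ("A1-L",))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(min_dur=3.5), dict(detect_band=(16.0, 5.0)),
         dict(threshold_factor=0.0), dict(boundary_rule="sideways")],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            DetectionConfig(**kwargs)


class TestBandPowerEnvelope:
    def test_power_scales_quadratically_with_amplitude(self):
        e1 = band_power_envelope(sine_rec(12.0, 1.0)).values[0]
        e2 = band_power_envelope(sine_rec(12.0, 2.0)).values[0]
        interior = slice(int(1.5 * RATE), int(2.5 * RATE))
        ratio = e2[interior].mean() / e1[interior].mean()
        assert abs(ratio - 4.0) / 4.0 < 0.05

    def test_zero_signal_zero_envelope(self):
        env = band_power_envelope(
            Recording(np.zeros(1000), RATE, ("A1-L",)))
        assert_allclose(env.values, 0.0, atol=1e-20)

    def test_in_band_tone_beats_silence(self):
        env = band_power_envelope(sine_rec(12.0)).values[0]
        interior = slice(int(1.5 * RATE), int(2.5 * RATE))
        assert env[interior].min() > 100 * env[:10].mean() or env[
            interior].min() > 0

    def test_amplitude_preserved_across_band(self):
        # L1-normalized transform: equal-amplitude tones at 11 and 15 Hz give
        # comparable envelope power
        e11 = band_power_envelope(sine_rec(11.0)).values[0]
        e15 = band_power_envelope(sine_rec(15.0)).values[0]
        interior = slice(int(1.5 * RATE), int(2.5 * RATE))
        ratio = e15[interior].mean() / e11[interior].mean()
        assert 0.5 < ratio < 2.0

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            band_power_envelope(sine_rec(5.0, rate=30.0))


class TestBaselineThreshold:
    def test_constant_envelope(self):
        thr = baseline_threshold(make_env(np.ones(100)))
        assert_allclose(thr, [1.8])

    def test_zero_envelope(self):
        assert_allclose(baseline_threshold(make_env(np.zeros(50))), [0.0])

    def test_ratio_is_exact_for_random_envelopes(self, rng):
        values = rng.random((4, 500))
        env = PowerEnvelope(values, RATE, (5.0, 16.0), tuple("abcd"))
        thr = baseline_threshold(env)
        # independent per-channel mean
        expected = 1.8 * values.sum(axis=1) / values.shape[1]
        assert_allclose(thr, expected, rtol=1e-12)


class TestDetectCandidates:
    def test_single_run(self):
        env = make_env([0, 0, 5, 5, 0])
        assert detect_candidates(env, np.array([1.0])) == [(0, (2, 4))]

    def test_all_below_threshold(self):
        env = make_env([0.1, 0.2, 0.1])
        assert detect_candidates(env, np.array([1.0])) == []

    def test_two_runs_split_by_one_sample(self):
        env = make_env([0, 5, 5, 0, 5, 0])
        assert detect_candidates(env, np.array([1.0])) == [
            (0, (1, 3)), (0, (4, 5))]

    def test_runs_at_edges(self):
        env = make_env([5, 0, 5])
        assert detect_candidates(env, np.array([1.0])) == [
            (0, (0, 1)), (0, (2, 3))]


def triangle_env():
    """Envelope rising 0 -> 10 over 1 s and back over 1 s at 250 Hz."""
    up = np.linspace(0.0, 10.0, 251)
    return np.concatenate([up, up[-2::-1]])


class TestRefineBoundaries:
    def test_triangle_drop_to_literal_rule(self):
        env = triangle_env()
        cfg = DetectionConfig(boundary_rule="drop_to")
        (i0, i1), warned = refine_boundaries(
            env, (100, 400), channel_mean=1.0, cfg=cfg, bounds=(0, len(env)))
        # cutoff = max(0.8 * 10, 1.2 * 1) = 8 -> crossings at t=0.8 and 1.2 s
        assert not warned
        assert abs(i0 - 200) <= 1 and abs(i1 - 301) <= 1
        assert 0.38 <= (i1 - i0) / RATE <= 0.42

    def test_triangle_drop_by_rule(self):
        env = triangle_env()
        (i0, i1), warned = refine_boundaries(
            env, (100, 400), channel_mean=1.0, cfg=DetectionConfig(),
            bounds=(0, len(env)))
        # cutoff = max(10 - 0.8 * 10, 1.2) = 2 -> crossings at 0.2 and 1.8 s
        assert not warned
        assert abs(i0 - 50) <= 1 and abs(i1 - 451) <= 1

    def test_rectangular_pulse_edges(self):
        env = np.zeros(500)
        env[200:300] = 10.0
        (i0, i1), _ = refine_boundaries(env, (200, 300), 0.1,
                                        DetectionConfig(), bounds=(0, 500))
        assert (i0, i1) == (200, 300)

    def test_flat_candidate_returned_with_warning(self):
        env = np.ones(100)
        interval, warned = refine_boundaries(env, (40, 60), 1.0,
                                             DetectionConfig())
        assert warned and interval == (40, 60)

    def test_never_crosses_neighbor_peak(self):
        env = np.concatenate([np.zeros(50), triangle_env(),
                              triangle_env() * 2, np.zeros(50)])
        # candidate on the first bump, bounded by the second bump's peak
        (i0, i1), _ = refine_boundaries(
            env, (200, 350), 0.01, DetectionConfig(), bounds=(0, 50 + 501))
        assert i1 <= 50 + 501


def brute_force_refine(env, candidate, channel_mean, cfg, bounds):
    """Independent exhaustive outward scan (oracle)."""
    lb, rb = max(bounds[0], 0), min(bounds[1], len(env))
    i0, i1 = candidate
    peak = i0 + int(np.argmax(env[i0:i1]))
    prom = env[peak] - max(env[lb:peak + 1].min(), env[peak:rb].min())
    if prom <= 0:
        return candidate
    if cfg.boundary_rule == "drop_by":
        cut = env[peak] - cfg.boundary_prominence_frac * prom
    else:
        cut = cfg.boundary_prominence_frac * prom
    cut = max(cut, cfg.boundary_mean_frac * channel_mean)
    start, end = lb, rb
    for i in range(peak - 1, lb - 1, -1):  # first below-cutoff sample leftward
        if env[i] < cut:
            start = i + 1
            break
    for i in range(peak + 1, rb):          # first below-cutoff sample rightward
        if env[i] < cut:
            end = i
            break
    return (start, end)


@pytest.mark.parametrize("rule", ["drop_by", "drop_to"])
def test_refinement_matches_brute_force_on_random_unimodal(rule, rng):
    cfg = DetectionConfig(boundary_rule=rule)
    for _ in range(200):
        k = int(rng.integers(5, 80))
        m = int(rng.integers(5, 80))
        peak_h = rng.uniform(2.0, 20.0)
        env = np.concatenate([
            np.sort(rng.uniform(0, peak_h, k)),
            [peak_h],
            np.sort(rng.uniform(0, peak_h, m))[::-1],
        ]) + rng.uniform(0, 0.3)
        mean = rng.uniform(0.05, 1.0)
        peak = k
        lo = int(rng.integers(0, peak + 1))
        hi = int(rng.integers(peak + 1, len(env) + 1))
        got, _ = refine_boundaries(env, (lo, hi), mean, cfg,
                                   bounds=(0, len(env)))
        want = brute_force_refine(env, (lo, hi), mean, cfg, (0, len(env)))
        assert got == want


class TestSpectralFeatures:
    def test_pure_tone_peak_within_one_bin(self):
        rec = sine_rec(12.0, dur=1.0)
        f, p, freqs, psd = spectral_features(rec.data[0], RATE,
                                             (0, rec.n_samples))
        assert abs(f - 12.0) <= RATE / 1024
        assert p == psd.max()

    def test_mixture_dominated_by_stronger_tone(self):
        t = np.arange(int(RATE)) / RATE
        x = 2 * np.sin(2 * np.pi * 12 * t) + np.sin(2 * np.pi * 14 * t)
        f, _, _, _ = spectral_features(x, RATE, (0, len(x)))
        assert abs(f - 12.0) < 0.5

    def test_dc_segment_has_negligible_in_band_power(self):
        x = np.full(250, 5.0)
        f, p, freqs, psd = spectral_features(x, RATE, (0, 250))
        in_band = psd[(freqs >= 5) & (freqs <= 16)].sum()
        assert in_band < 1e-4 * psd.sum()  # only Hann sidelobe leakage

    def test_short_interval_rejected(self):
        with pytest.raises(ValueError):
            spectral_features(np.zeros(100), RATE, (10, 11))

    def test_frequency_resolution_from_padding(self):
        # a 0.5 s segment still reports frequency on the rate/1024 grid
        rec = sine_rec(13.3, dur=0.5)
        f, _, _, _ = spectral_features(rec.data[0], RATE, (0, rec.n_samples))
        assert f % (RATE / 1024) == pytest.approx(0.0, abs=1e-9)


class TestNoiseSpike:
    def test_smooth_sinusoid_not_flagged(self):
        rec = sine_rec(12.0, dur=1.0)
        assert not is_noise_spike(rec.data[0], (0, rec.n_samples))

    def test_displaced_sample_flagged(self):
        x = sine_rec(12.0, dur=1.0).data[0].copy()
        base_step = np.abs(np.diff(x)).mean()
        x[125] += 12 * base_step
        assert is_noise_spike(x, (0, len(x)))

    def test_constant_segment_not_flagged(self):
        assert not is_noise_spike(np.full(100, 2.0), (0, 100))


class TestPositivePeaks:
    def test_one_second_of_12hz(self):
        rec = sine_rec(12.0, dur=3.0)
        filt = classical_band_filter(rec.data[0], RATE)
        n = count_positive_peaks(filt, (int(RATE), int(2 * RATE)))
        assert 11 <= n <= 13

    def test_half_cycle(self):
        t = np.arange(int(RATE / 24)) / RATE  # half a 12 Hz cycle
        seg = np.sin(2 * np.pi * 12 * t)
        assert count_positive_peaks(seg, (0, len(seg))) == 1

    def test_offset_removed_by_zero_phase_filter(self, rng):
        # a negative-offset oscillation: the band-pass removes the offset, so
        # the count equals that of an independent filter-then-count oracle
        from scipy import signal

        t = np.arange(int(2 * RATE)) / RATE
        x = -5.0 + 0.1 * np.sin(2 * np.pi * 12 * t) + 0.01 * rng.normal(
            size=len(t))
        filt = classical_band_filter(x, RATE)
        iv = (int(0.5 * RATE), int(1.5 * RATE))
        sos = signal.butter(4, (10, 16), btype="band", fs=RATE, output="sos")
        oracle_seg = signal.sosfiltfilt(sos, x)[iv[0]:iv[1]]
        peaks, _ = signal.find_peaks(oracle_seg)
        assert count_positive_peaks(filt, iv) == int(
            (oracle_seg[peaks] > 0).sum())


class TestDetectSpindles:
    def test_accepted_events_satisfy_all_filters(self, study, detections,
                                                 accepted):
        rec, _, _ = study
        cfg = DetectionConfig()
        filt = classical_band_filter(rec.data, rec.rate, cfg)
        assert accepted, "study produced no accepted events"
        eps = 1.0 / rec.rate  # float round-off on start/end differences
        for ev in accepted:
            assert cfg.min_dur - eps <= ev.duration <= cfg.max_dur + eps
            assert cfg.detect_band[0] <= ev.peak_freq <= cfg.detect_band[1]
            assert ev.n_pos_peaks >= cfg.min_pos_peaks
            c = rec.labels.index(ev.channel)
            iv = (int(round(ev.start * rec.rate)),
                  int(round(ev.end * rec.rate)))
            assert not is_noise_spike(rec.data[c], iv, cfg)
            assert count_positive_peaks(filt[c], iv) >= cfg.min_pos_peaks

    def test_rejects_recorded_with_reason(self, detections):
        rejected = [e for e in detections if not e.accepted]
        assert rejected
        assert all(e.reject_reason for e in rejected)

    def test_threshold_monotonicity(self, study):
        rec, _, _ = study
        n_default = len(accepted_events(detect_spindles(rec, rec)))
        stricter = DetectionConfig(threshold_factor=2.4)
        n_strict = len(accepted_events(detect_spindles(rec, rec, stricter)))
        assert n_strict <= n_default

    def test_translation_equivariance(self, quiet_background):
        cfg, bg = quiet_background
        ev = GroundTruthEvent(("A1-L",), 60.0, 1.0, 12.0, 0.05)
        x = bg.data[0].copy()
        sl, wave = event_waveform(ev, bg.rate, bg.n_samples)
        x[sl] += wave
        rec = Recording(x, bg.rate, bg.labels)
        k = 500  # 2 s
        shifted = Recording(np.concatenate([np.zeros(k), x]), bg.rate,
                            bg.labels)
        base = [e for e in accepted_events(detect_spindles(rec, rec))
                if abs(e.midpoint - 60.5) < 1]
        moved = [e for e in accepted_events(detect_spindles(shifted, shifted))
                 if abs(e.midpoint - 62.5) < 1]
        assert len(base) == len(moved) == 1
        assert base[0].start == pytest.approx(moved[0].start - 2.0,
                                              abs=2 / bg.rate)
        assert base[0].end == pytest.approx(moved[0].end - 2.0,
                                            abs=2 / bg.rate)

    def test_short_burst_rejected_for_duration(self, quiet_background):
        # at light smoothing a 0.2 s burst stays below the 0.3 s floor
        cfg, bg = quiet_background
        dc = DetectionConfig(smooth_s=0.1)
        x = bg.data[0].copy()
        burst = GroundTruthEvent(("A1-L",), 60.0, 0.2, 12.0, 0.08)
        sl, wave = event_waveform(burst, bg.rate, bg.n_samples)
        x[sl] += wave
        rec = Recording(x, bg.rate, bg.labels)
        events = detect_spindles(rec, rec, dc)
        near = [e for e in events if abs(e.midpoint - burst.center) < 0.5]
        assert near
        assert all(not e.accepted and e.reject_reason == "duration"
                   for e in near)

    def test_mismatched_channels_rejected(self, quiet_background):
        _, bg = quiet_background
        other = Recording(bg.data, bg.rate, ("elsewhere",))
        with pytest.raises(ValueError, match="labels"):
            detect_spindles(bg, other)

    def test_no_baseline_warns(self, quiet_background):
        _, bg = quiet_background
        with pytest.warns(UserWarning, match="baseline"):
            detect_spindles(bg)

    def test_classical_view_restricts_band(self, detections):
        cfg = DetectionConfig()
        for ev in classical_events(detections, cfg):
            assert cfg.classical_band[0] <= ev.peak_freq <= cfg.classical_band[1]

    def test_event_table_round_trip(self, tmp_path, detections):
        path = tmp_path / "events.csv"
        write_events(detections, path)
        back = read_events(path)
        assert len(back) == len(detections)
        assert [e.channel for e in back] == [e.channel for e in detections]
        assert [e.accepted for e in back] == [e.accepted for e in detections]
        np.testing.assert_allclose([e.start for e in back],
                                   [e.start for e in detections])
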