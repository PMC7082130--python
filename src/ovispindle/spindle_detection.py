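"""Wavelet-envelope sleep-spindle detection.

The pipeline: a complex-Morlet wavelet transform yields the mean 5-16 Hz
power envelope per channel; candidate events are maximal runs of envelope
above 180% of the per-channel baseline mean; boundaries are refined against
the envelope peak's prominence; a Hann-windowed 1024-bin FFT of each raw
segment gives peak frequency and power; and events are screened by duration
(0.3-3 s), in-band peak frequency, a voltage-spike rule (max successive-sample
step > 10x the mean step), and a minimum of three positive peaks in the
10-16 Hz filtered trace.  Rejected events are retained with their rejection
reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .eeg_io import Recording

REJECT_DURATION = "duration"
REJECT_PEAK_FREQ = "peak_freq"
REJECT_NOISE_SPIKE = "noise_spike"
REJECT_POS_PEAKS = "pos_peaks"


@dataclass
class DetectionConfig:
    """Detector parameters.

    ``boundary_rule`` selects how the refinement cutoff relates to the peak
    prominence: ``"drop_by"`` places the boundary where the envelope has lost
    80% of the peak's prominence (cutoff = peak - frac x prominence), while
    ``"drop_to"`` places it where the envelope falls below 80% of the
    prominence itself (cutoff = frac x prominence).  Both are floored at
    120% of the channel's baseline mean power.
    """

    detect_band: tuple[float, float] = (5.0, 16.0)
    classical_band: tuple[float, float] = (10.0, 16.0)
    threshold_factor: float = 1.8
    boundary_prominence_frac: float = 0.8
    boundary_mean_frac: float = 1.2
    min_dur: float = 0.3
    max_dur: float = 3.0
    fft_bins: int = 1024
    spike_factor: float = 10.0
    min_pos_peaks: int = 3
    freq_step: float = 0.5        # Hz, wavelet center-frequency spacing
    smooth_s: float = 0.2         # s, moving-average envelope smoothing
                                  # (~2-3 spindle cycles; stabilizes runs)
    boundary_rule: str = "drop_by"
    refine_margin_s: float = 2.0  # s, outward search bound for refinement
    wavelet: str = "cmor1.5-1.0"

    def __post_init__(self):
        if not 0 < self.min_dur < self.max_dur:
            raise ValueError("need 0 < min_dur < max_dur")
        for band in (self.detect_band, self.classical_band):
            if not band[0] < band[1]:
                raise ValueError(f"band {band} must be (low < high)")
        for name in ("threshold_factor", "boundary_prominence_frac",
                     "boundary_mean_frac", "spike_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.boundary_rule not in {"drop_by", "drop_to"}:
            raise ValueError("boundary_rule must be 'drop_by' or 'drop_to'")


@dataclass
class PowerEnvelope:
    """Per-channel mean band power versus time."""

    values: np.ndarray  # (n_channels, n_samples), power units
    rate: float
    band: tuple[float, float]
    labels: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SpindleEvent:
    """One detected spindle (accepted or rejected)."""

    channel: str
    start: float
    end: float
    peak_freq: float
    peak_freq_power: float
    mean_power: float
    n_pos_peaks: int
    accepted: bool
    reject_reason: str | None = None
    boundary_warning: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "SpindleEvent") -> bool:
        """Half-open temporal overlap."""
        return self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# stage 1: envelope and threshold
# ---------------------------------------------------------------------------


def band_power_envelope(rec: Recording, cfg: DetectionConfig | None = None) -> PowerEnvelope:
    """Mean complex-Morlet wavelet power across the detection band.

    Center frequencies span the band in ``freq_step`` increments; power is the
    squared wavelet magnitude averaged across scales, then smoothed with a
    ``smooth_s`` moving average.
    """
    cfg = cfg or DetectionConfig()
    low, high = cfg.detect_band
    if rec.rate < 2 * high:
        raise ValueError(
            f"rate {rec.rate} Hz too low for detection band up to {high} Hz"
        )
    freqs = np.arange(low, high + cfg.freq_step / 2, cfg.freq_step)
    fc = pywt.central_frequency(cfg.wavelet)
    scales = fc * rec.rate / freqs
    # accumulate per channel in scale chunks to bound memory on long records
    power = np.zeros_like(rec.data)
    chunk = 4
    for c in range(rec.n_channels):
        for s0 in range(0, len(scales), chunk):
            sc = scales[s0:s0 + chunk]
            coeffs, _ = pywt.cwt(
                rec.data[c], sc, cfg.wavelet,
                sampling_period=1.0 / rec.rate, method="fft",
            )
            # L1-normalize (divide the library's L2 coefficients by
            # sqrt(scale)) so a sinusoid of fixed amplitude yields the same
            # power at every center frequency — the MATLAB CWT convention.
            coeffs /= np.sqrt(sc)[:, None]
            power[c] += (coeffs.real ** 2 + coeffs.imag ** 2).sum(axis=0)
    power /= len(scales)
    size = max(int(round(cfg.smooth_s * rec.rate)), 1)
    power = uniform_filter1d(power, size=size, axis=-1, mode="nearest")
    return PowerEnvelope(power, rec.rate, cfg.detect_band, rec.labels)


def baseline_threshold(envelope: PowerEnvelope, threshold_factor: float = 1.8) -> np.ndarray:
    """Per-channel detection threshold: ``threshold_factor`` x mean power.

    The envelope should come from the designated baseline recording (the
    "night 2" role); the default factor is 180% of the mean.
    """
    if envelope.n_samples == 0:
        raise ValueError("empty envelope")
    return threshold_factor * envelope.values.mean(axis=1)


def detect_candidates(envelope: PowerEnvelope, threshold: np.ndarray):
    """Maximal runs of envelope strictly above threshold.

    Returns a list of ``(channel_index, (i0, i1))`` half-open sample intervals.
    """
    threshold = np.asarray(threshold, dtype=float)
    out = []
    for c in range(envelope.values.shape[0]):
        above = envelope.values[c] > threshold[c]
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, len(above)]
        out.extend((c, (int(s), int(e))) for s, e in zip(starts, ends))
    return out


# ---------------------------------------------------------------------------
# stage 2: boundary refinement
# ---------------------------------------------------------------------------


def refine_boundaries(env: np.ndarray, candidate: tuple[int, int],
                      channel_mean: float, cfg: DetectionConfig | None = None,
                      bounds: tuple[int, int] | None = None):
    """Refine a candidate interval around its envelope peak.

    The peak's prominence is its height above the higher of the two minima
    flanking it within ``bounds`` (default: the candidate extended by
    ``refine_margin_s``).  The cutoff is ``max(prominence term,
    boundary_mean_frac x channel_mean)``; the interval is grown/shrunk outward
    from the peak to the first samples where the envelope falls below the
    cutoff.  A flat candidate (zero prominence) is returned unchanged with a
    warning flag.

    Returns ``((i0, i1), warned)`` with a half-open sample interval.
    """
    cfg = cfg or DetectionConfig()
    i0, i1 = candidate
    env = np.asarray(env, dtype=float)
    peak = i0 + int(np.argmax(env[i0:i1]))
    if bounds is None:
        # rate-agnostic default: search twice the candidate span to each side
        m = max(i1 - i0, 1) * 2
        bounds = (max(i0 - m, 0), min(i1 + m, len(env)))
    lb, rb = max(bounds[0], 0), min(bounds[1], len(env))

    left_min = env[lb:peak + 1].min()
    right_min = env[peak:rb].min()
    prominence = env[peak] - max(left_min, right_min)
    if prominence <= 0:
        return (i0, i1), True

    if cfg.boundary_rule == "drop_by":
        prom_cut = env[peak] - cfg.boundary_prominence_frac * prominence
    else:  # "drop_to"
        prom_cut = cfg.boundary_prominence_frac * prominence
    cutoff = max(prom_cut, cfg.boundary_mean_frac * channel_mean)

    s = peak
    while s - 1 >= lb and env[s - 1] >= cutoff:
        s -= 1
    e = peak
    while e + 1 < rb and env[e + 1] >= cutoff:
        e += 1
    return (s, e + 1), False


# ---------------------------------------------------------------------------
# stage 3: per-event features and filters
# ---------------------------------------------------------------------------


def spectral_features(data: np.ndarray, rate: float, interval: tuple[int, int],
                      cfg: DetectionConfig | None = None):
    """Hann-windowed, zero-padded power spectrum of a raw segment.

    Returns ``(peak_freq, peak_freq_power, freqs, psd)`` where the peak is the
    maximum-power bin inside the detection band (ties broken toward the lower
    frequency).  The frequency resolution is ``rate / fft_bins`` for segments
    shorter than ``fft_bins`` samples.
    """
    cfg = cfg or DetectionConfig()
    i0, i1 = interval
    seg = np.asarray(data, dtype=float)[i0:i1]
    if len(seg) < 2:
        raise ValueError("interval must span at least 2 samples")
    nfft = max(cfg.fft_bins, len(seg))
    win = np.hanning(len(seg))
    spec = np.fft.rfft(seg * win, n=nfft)
    psd = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    low, high = cfg.detect_band
    in_band = (freqs >= low) & (freqs <= high)
    band_psd = np.where(in_band, psd, -np.inf)
    k = int(np.argmax(band_psd))  # argmax returns the first (lowest-f) maximum
    return float(freqs[k]), float(psd[k]), freqs, psd


def is_noise_spike(data: np.ndarray, interval: tuple[int, int],
                   cfg: DetectionConfig | None = None) -> bool:
    """True iff the segment contains a step > ``spike_factor`` x its mean step.

    "Variation in voltage" is read as the absolute first difference of the raw
    segment; a constant segment (mean step 0) is not a spike.
    """
    cfg = cfg or DetectionConfig()
    i0, i1 = interval
    seg = np.asarray(data, dtype=float)[i0:i1]
    diffs = np.abs(np.diff(seg))
    if diffs.size == 0:
        return False
    mean_step = diffs.mean()
    return bool(diffs.max() > cfg.spike_factor * mean_step)


def classical_band_filter(data: np.ndarray, rate: float,
                          cfg: DetectionConfig | None = None) -> np.ndarray:
    """Zero-phase 4th-order IIR band-pass in the classical 10-16 Hz band."""
    cfg = cfg or DetectionConfig()
    sos = signal.butter(4, cfg.classical_band, btype="band", fs=rate,
                        output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def count_positive_peaks(filtered: np.ndarray, interval: tuple[int, int]) -> int:
    """Local maxima with positive value in an already band-passed trace."""
    i0, i1 = interval
    seg = np.asarray(filtered, dtype=float)[i0:i1]
    if len(seg) < 3:
        return 0
    peaks, _ = signal.find_peaks(seg)
    return int((seg[peaks] > 0).sum())


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def detect_spindles(rec: Recording, baseline: Recording | None = None,
                    cfg: DetectionConfig | None = None) -> list[SpindleEvent]:
    """Run the full detection pipeline on every channel.

    ``baseline`` plays the "night 2" role: its mean envelope sets the
    per-channel threshold (180% of the mean) and the channel mean power used
    by boundary refinement.  When omitted the recording itself is used, with
    a warning.  All candidates are returned; rejected ones carry a reason.
    """
    cfg = cfg or DetectionConfig()
    if baseline is None:
        warnings.warn("no baseline recording supplied; using the recording "
                      "itself as its own baseline")
        baseline = rec
    if baseline.labels != rec.labels:
        raise ValueError("recording and baseline must share channel labels")
    if abs(baseline.rate - rec.rate) > 1e-9:
        raise ValueError("recording and baseline must share the sampling rate")

    env = band_power_envelope(rec, cfg)
    base_env = env if baseline is rec else band_power_envelope(baseline, cfg)
    channel_means = base_env.values.mean(axis=1)
    thresholds = cfg.threshold_factor * channel_means

    candidates = detect_candidates(env, thresholds)
    by_channel: dict[int, list[tuple[int, int]]] = {}
    for c, iv in candidates:
        by_channel.setdefault(c, []).append(iv)

    margin = int(round(cfg.refine_margin_s * rec.rate))
    filtered = classical_band_filter(rec.data, rec.rate, cfg)
    events: list[SpindleEvent] = []

    for c, ivs in by_channel.items():
        ivs.sort()
        peaks = [i0 + int(np.argmax(env.values[c, i0:i1])) for i0, i1 in ivs]
        refined: list[tuple[tuple[int, int], bool]] = []
        for k, iv in enumerate(ivs):
            # never extend into a neighboring candidate's peak region
            lb = max(iv[0] - margin, peaks[k - 1] + 1 if k > 0 else 0)
            rb = min(iv[1] + margin,
                     peaks[k + 1] if k + 1 < len(ivs) else env.n_samples)
            refined.append(
                refine_boundaries(env.values[c], iv, channel_means[c], cfg,
                                  bounds=(lb, rb))
            )
        # merge identical/overlapping refined intervals on the same channel
        merged: list[tuple[tuple[int, int], bool]] = []
        for iv, warned in refined:
            if merged and iv[0] < merged[-1][0][1]:
                prev, pw = merged[-1]
                if iv != prev:
                    warnings.warn("overlapping refined spindles merged")
                merged[-1] = ((prev[0], max(prev[1], iv[1])), pw or warned)
            else:
                merged.append((iv, warned))

        for (i0, i1), warned in merged:
            if i1 - i0 < 2:
                continue
            duration = (i1 - i0) / rec.rate
            peak_freq, peak_power, _, _ = spectral_features(
                rec.data[c], rec.rate, (i0, i1), cfg)
            n_pos = count_positive_peaks(filtered[c], (i0, i1))
            mean_power = float(env.values[c, i0:i1].mean())

            reason = None
            if not cfg.min_dur <= duration <= cfg.max_dur:
                reason = REJECT_DURATION
            elif not cfg.detect_band[0] <= peak_freq <= cfg.detect_band[1]:
                reason = REJECT_PEAK_FREQ
            elif is_noise_spike(rec.data[c], (i0, i1), cfg):
                reason = REJECT_NOISE_SPIKE
            elif n_pos < cfg.min_pos_peaks:
                reason = REJECT_POS_PEAKS

            events.append(
                SpindleEvent(
                    channel=rec.labels[c],
                    start=i0 / rec.rate,
                    end=i1 / rec.rate,
                    peak_freq=peak_freq,
                    peak_freq_power=peak_power,
                    mean_power=mean_power,
                    n_pos_peaks=n_pos,
                    accepted=reason is None,
                    reject_reason=reason,
                    boundary_warning=warned,
                )
            )

    events.sort(key=lambda e: (e.start, e.channel))
    return events


def write_events(events, path) -> None:
    """Write events as CSV (times in s, peak frequency in Hz)."""
    import pandas as pd

    pd.DataFrame(
        {
            "channel": [e.channel for e in events],
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
            "duration_s": [e.duration for e in events],
            "peak_freq_hz": [e.peak_freq for e in events],
            "peak_power": [e.peak_freq_power for e in events],
            "mean_power": [e.mean_power for e in events],
            "n_pos_peaks": [e.n_pos_peaks for e in events],
            "accepted": [int(e.accepted) for e in events],
            "reject_reason": [e.reject_reason or "" for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path) -> list[SpindleEvent]:
    import pandas as pd

    df = pd.read_csv(path, comment="#", keep_default_na=False)
    return [
        SpindleEvent(
            channel=str(r.channel),
            start=float(r.start_s),
            end=float(r.end_s),
            peak_freq=float(r.peak_freq_hz),
            peak_freq_power=float(r.peak_power),
            mean_power=float(r.mean_power),
            n_pos_peaks=int(r.n_pos_peaks),
            accepted=bool(int(r.accepted)),
            reject_reason=str(r.reject_reason) or None,
        )
        for r in df.itertuples()
    ]


def accepted_events(events) -> list[SpindleEvent]:
    return [e for e in events if e.accepted]


def classical_events(events, cfg: DetectionConfig | None = None) -> list[SpindleEvent]:
    """Accepted events whose peak frequency lies in the classical band."""
    cfg = cfg or DetectionConfig()
    low, high = cfg.classical_band
    return [e for e in events if e.accepted and low <= e.peak_freq <= high]
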