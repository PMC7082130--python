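"""Synthetic multichannel EEG with known spindle / slow-wave ground truth.

The generator produces the study conditions every downstream stage is tested
against: per-channel 1/f background, stage-dependent slow-wave activity
(0.5-2 Hz, stronger in deep than light NREM), low-amplitude broadband noise
during wake, waxing-waning sinusoidal spindle bursts injected either locally
(one channel) or globally (>= 4 co-timed channels, coupled to a high-amplitude
slow wave), and occasional single-sample voltage spikes.  Every realization is
fully determined by the seed, and the injected event table is returned as
exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .eeg_io import (
    DEFAULT_LABELS,
    NREM_STAGES,
    REM_STAGES,
    WAKE_STAGES,
    Hypnogram,
    Recording,
)

DEEP_STAGES = frozenset({"S2", "U2"})
LIGHT_STAGES = frozenset({"S1", "U1"})

#: A night-like stage sequence (stage, duration s): three full sleep cycles
#: (wake -> light NREM -> deep NREM -> REM) of 18-20 min each, matching the
#: short cycles of ovine sleep, plus a truncated final cycle.  Durations are
#: multiples of the 10 s epoch length.
DEFAULT_STAGE_SEQUENCE = (
    ("W", 60.0), ("S1", 240.0), ("S2", 960.0), ("R", 120.0),
    ("W", 40.0), ("S1", 240.0), ("S2", 900.0), ("R", 90.0),
    ("W", 30.0), ("S1", 240.0), ("S2", 840.0), ("R", 60.0),
    ("W", 30.0), ("S1", 120.0), ("S2", 300.0),
)

#: Spindle rates per vigilance stage, events/min.  NREM-dominant with a small
#: wake rate, matching the qualitative picture of ovine recordings (deep NREM
#: densities of a few per minute, sparse wake spindles).
DEFAULT_SPINDLE_RATES = {
    "S2": 4.5, "U2": 4.5, "S1": 2.5, "U1": 2.5, "W": 0.3, "WU": 0.3, "R": 0.0,
}


@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected spindle burst (plus optional coupled slow wave)."""

    channels: tuple[str, ...]
    start: float          # s
    duration: float       # s
    freq: float           # Hz
    amplitude: float      # mV, peak of the Hann amplitude envelope
    sw_amplitude: float = 0.0  # mV, 0 when no slow wave is coupled
    truncated: bool = False

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.freq <= 0:
            raise ValueError("freq must be positive")
        if not self.channels:
            raise ValueError("channels must be non-empty")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def center(self) -> float:
        return self.start + self.duration / 2.0


@dataclass
class SimConfig:
    """Full parameterization of one synthetic study; the seed fixes it all."""

    n_channels: int = 8
    rate: float = 250.0
    stage_sequence: tuple = DEFAULT_STAGE_SEQUENCE
    spindle_rate_per_stage: dict = field(
        default_factory=lambda: dict(DEFAULT_SPINDLE_RATES))
    freq_range: tuple[float, float] = (10.0, 16.0)
    #: spindle durations: lognormal (median ``duration_median``, log-sd
    #: ``duration_log_sigma``) clipped to ``duration_range`` — the
    #: right-skewed, ~1 s-typical distribution reported for real spindles
    duration_range: tuple[float, float] = (0.5, 2.0)
    duration_median: float = 0.9
    duration_log_sigma: float = 0.35
    #: spindle amplitude as a multiple of the per-channel RMS of the 10-16 Hz
    #: band-passed background ("envelope SNR")
    amplitude_snr: float = 5.0
    sw_amplitude_range: tuple[float, float] = (0.03, 0.05)  # mV
    global_fraction: float = 0.4
    spike_rate: float = 0.2          # events/min, 20x local sigma excursions
    background_rms: float = 0.02     # mV, 1/f component, during NREM
    sw_rms_deep: float = 0.03        # mV, 0.5-2 Hz activity in S2/U2
    sw_rms_light: float = 0.012      # mV, 0.5-2 Hz activity in S1/U1
    wake_broadband_rms: float = 0.004  # mV, extra white noise in wake
    #: voltage scale of the 1/f background in wake / REM relative to NREM
    #: (low-voltage desynchronized EEG)
    wake_attenuation: float = 0.5
    rem_attenuation: float = 0.6
    alpha: float = 1.0               # background spectral exponent (1/f^alpha)
    #: lognormal amplitude modulation of the 1/f component (sigma of log
    #: amplitude; 0 disables).  Real EEG band power is right-skewed and
    #: burst-like on multi-second timescales; without this the background is
    #: an unrealistically steady Gaussian process.
    modulation_sigma: float = 0.6
    modulation_tau: float = 4.0      # s, correlation time of the modulation
    epoch_len: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("spike_rate", "global_fraction", "amplitude_snr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(r < 0 for r in self.spindle_rate_per_stage.values()):
            raise ValueError("spindle rates must be >= 0")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.n_channels <= len(DEFAULT_LABELS):
            return DEFAULT_LABELS[: self.n_channels]
        return tuple(f"CH{i}" for i in range(self.n_channels))

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.stage_sequence))

    def segments(self):
        """Yield (stage, t0, t1) for the stage sequence."""
        t = 0.0
        for stage, dur in self.stage_sequence:
            yield stage, t, t + dur
            t += dur


def _rngs(cfg: SimConfig):
    """Independent child generators for background vs. event placement."""
    ss = np.random.SeedSequence(cfg.seed)
    bg, ev = ss.spawn(2)
    return np.random.default_rng(bg), np.random.default_rng(ev)


def _colored_noise(rng, n, alpha, rate):
    """1/f^alpha noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / max(x.std(), 1e-30)


def _segment_window(n, rate, t0, t1, ramp_s=1.0):
    """Unit gain inside [t0, t1) with cosine ramps inside the segment."""
    w = np.zeros(n)
    i0, i1 = int(round(t0 * rate)), min(int(round(t1 * rate)), n)
    if i1 <= i0:
        return w
    seg = np.ones(i1 - i0)
    nr = min(int(ramp_s * rate), (i1 - i0) // 2)
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        seg[:nr] = ramp
        seg[-nr:] = ramp[::-1]
    w[i0:i1] = seg
    return w


def generate_background(cfg: SimConfig) -> Recording:
    """Spindle-free background EEG for the configured stage sequence."""
    if cfg.duration <= 0:
        raise ValueError("stage sequence has zero total duration")
    n = int(round(cfg.duration * cfg.rate))
    rng, _ = _rngs(cfg)
    data = np.empty((cfg.n_channels, n))

    sos = signal.butter(4, (0.5, 2.0), btype="band", fs=cfg.rate, output="sos")
    windows = []  # (gain array, kind)
    attenuation = np.ones(n)  # 1/f voltage scale: low-voltage wake / REM EEG
    for stage, t0, t1 in cfg.segments():
        w = _segment_window(n, cfg.rate, t0, t1)
        if stage in DEEP_STAGES or stage in {"N", "U"}:
            windows.append((w * cfg.sw_rms_deep, "sw"))
        elif stage in LIGHT_STAGES:
            windows.append((w * cfg.sw_rms_light, "sw"))
        elif stage in WAKE_STAGES:
            windows.append((w * cfg.wake_broadband_rms, "white"))
            attenuation -= (1.0 - cfg.wake_attenuation) * w
        elif stage in REM_STAGES:
            windows.append((w * cfg.wake_broadband_rms * 0.75, "white"))
            attenuation -= (1.0 - cfg.rem_attenuation) * w

    for c in range(cfg.n_channels):
        x = cfg.background_rms * _colored_noise(rng, n, cfg.alpha, cfg.rate)
        if cfg.modulation_sigma > 0:
            from scipy.ndimage import gaussian_filter1d

            z = gaussian_filter1d(rng.standard_normal(n),
                                  cfg.modulation_tau * cfg.rate,
                                  mode="reflect")
            z /= max(z.std(), 1e-30)
            # unit-mean-amplitude lognormal gain
            x = x * np.exp(cfg.modulation_sigma * z
                           - cfg.modulation_sigma ** 2 / 2.0)
        x = x * attenuation
        sw_src = signal.sosfiltfilt(sos, rng.standard_normal(n))
        sw_src /= max(sw_src.std(), 1e-30)
        white_src = rng.standard_normal(n)
        for gain, kind in windows:
            x = x + gain * (sw_src if kind == "sw" else white_src)
        data[c] = x

    # single-sample voltage spikes, 20x the local (1 s) standard deviation
    n_spikes = rng.poisson(cfg.spike_rate * cfg.duration / 60.0)
    half = int(0.5 * cfg.rate)
    for _ in range(n_spikes):
        c = int(rng.integers(cfg.n_channels))
        i = int(rng.integers(half, n - half))
        local_sigma = data[c, i - half:i + half].std()
        data[c, i] += 20.0 * local_sigma * rng.choice([-1.0, 1.0])

    return Recording(data, cfg.rate, cfg.labels)


def event_waveform(ev: GroundTruthEvent, rate: float, n_samples: int):
    """(sample slice, per-channel-added waveform) for one ground-truth event.

    The spindle is a sinusoid under a Hann amplitude envelope spanning the
    event; a coupled slow wave (1 Hz cosine under a 2.5 s Hann window, positive
    peak at the spindle center) is added when ``sw_amplitude > 0``.
    """
    sw_half = 1.25  # s
    lo = ev.start if ev.sw_amplitude == 0 else min(ev.start, ev.center - sw_half)
    hi = ev.end if ev.sw_amplitude == 0 else max(ev.end, ev.center + sw_half)
    i0 = max(int(np.floor(lo * rate)), 0)
    i1 = min(int(np.ceil(hi * rate)) + 1, n_samples)
    t = np.arange(i0, i1) / rate
    wave = np.zeros(i1 - i0)

    tau = t - ev.start
    in_sp = (tau >= 0) & (tau <= ev.duration)
    hann = 0.5 * (1 - np.cos(2 * np.pi * tau[in_sp] / ev.duration))
    wave[in_sp] += ev.amplitude * hann * np.sin(2 * np.pi * ev.freq * tau[in_sp])

    if ev.sw_amplitude > 0:
        ts = t - ev.center
        in_sw = np.abs(ts) <= sw_half
        env = 0.5 * (1 + np.cos(np.pi * ts[in_sw] / sw_half))
        wave[in_sw] += ev.sw_amplitude * env * np.cos(2 * np.pi * 1.0 * ts[in_sw])

    return slice(i0, i1), wave


def _band_rms(data, rate, band=(10.0, 16.0)):
    sos = signal.butter(4, band, btype="band", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1).std(axis=-1)


def inject_events(rec: Recording, cfg: SimConfig):
    """Add spindle (and coupled slow-wave) events to a background recording.

    Returns ``(recording, events)`` where ``recording - rec`` equals the sum
    of the per-event waveforms exactly.  Events that would extend past the
    recording end are truncated and flagged.
    """
    _, rng = _rngs(cfg)
    n = rec.n_samples
    sigma_band = _band_rms(rec.data, rec.rate)
    labels = list(rec.labels)

    events: list[GroundTruthEvent] = []
    occupied: dict[str, list[tuple[float, float]]] = {l: [] for l in labels}
    gap = 1.0  # s of clearance between same-channel events

    for stage, t0, t1 in cfg.segments():
        rate_per_min = cfg.spindle_rate_per_stage.get(stage, 0.0)
        if rate_per_min <= 0:
            continue
        n_ev = rng.poisson(rate_per_min * (t1 - t0) / 60.0)
        for _ in range(n_ev):
            freq = rng.uniform(*cfg.freq_range)
            dur = float(np.clip(
                cfg.duration_median
                * np.exp(cfg.duration_log_sigma * rng.standard_normal()),
                *cfg.duration_range))
            is_global = rng.random() < cfg.global_fraction
            if is_global and cfg.n_channels >= 4:
                k = int(rng.integers(4, cfg.n_channels + 1))
                chans = tuple(sorted(rng.choice(labels, size=k, replace=False)))
            else:
                chans = (labels[int(rng.integers(cfg.n_channels))],)
            lo, hi = t0 + dur / 2 + 1.0, t1 - dur / 2 - 1.0
            if hi <= lo:
                continue
            placed = False
            for _attempt in range(20):
                center = rng.uniform(lo, hi)
                a, b = center - dur / 2 - gap, center + dur / 2 + gap
                if all(
                    all(b <= s or a >= e for s, e in occupied[ch]) for ch in chans
                ):
                    placed = True
                    break
            if not placed:
                continue
            amp = cfg.amplitude_snr * float(
                np.mean([sigma_band[labels.index(ch)] for ch in chans])
            )
            sw_amp = rng.uniform(*cfg.sw_amplitude_range) if is_global else 0.0
            start = center - dur / 2
            truncated = start + dur > rec.duration
            ev = GroundTruthEvent(
                chans, start, dur, freq, amp, sw_amp, truncated=truncated
            )
            events.append(ev)
            for ch in chans:
                occupied[ch].append((start - gap, start + dur + gap))

    events.sort(key=lambda e: e.start)
    out = rec.copy()
    for ev in events:
        sl, wave = event_waveform(ev, rec.rate, n)
        for ch in ev.channels:
            out.data[labels.index(ch), sl] += wave
    return out, events


def generate_study(cfg: SimConfig):
    """Background + events + stage-accurate hypnogram (10 s epochs)."""
    background = generate_background(cfg)
    rec, events = inject_events(background, cfg)
    n_epochs = int(cfg.duration // cfg.epoch_len)
    stages = []
    for i in range(n_epochs):
        mid = (i + 0.5) * cfg.epoch_len
        stage = next(s for s, t0, t1 in cfg.segments() if t0 <= mid < t1)
        stages.append(stage)
    hyp = Hypnogram(tuple(stages), epoch_len=cfg.epoch_len)
    return rec, hyp, events


# ---------------------------------------------------------------------------
# ground-truth table I/O and truth matching
# ---------------------------------------------------------------------------


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channels": ["|".join(e.channels) for e in events],
            "start": [e.start for e in events],
            "duration": [e.duration for e in events],
            "freq": [e.freq for e in events],
            "amplitude": [e.amplitude for e in events],
            "sw_amp": [e.sw_amplitude for e in events],
        }
    )


def write_truth(events, path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_truth(path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path, comment="#")
    return [
        GroundTruthEvent(
            tuple(str(r.channels).split("|")),
            float(r.start),
            float(r.duration),
            float(r.freq),
            float(r.amplitude),
            float(r.sw_amp),
        )
        for r in df.itertuples()
    ]


def match_events(truth, detected, max_center_dist: float = 0.5):
    """Greedy 1-to-1 match of detections to ground truth, per channel.

    Each (event, channel) ground-truth instance is matched to the unused
    same-channel detection whose midpoint is nearest the truth center (within
    ``max_center_dist`` seconds), in order of increasing distance.

    Returns
    -------
    matches : list of (truth event, channel, detection)
    misses : list of (truth event, channel)
    """
    instances = [(ev, ch) for ev in truth for ch in ev.channels]
    pairs = []
    for ti, (ev, ch) in enumerate(instances):
        for di, det in enumerate(detected):
            if det.channel != ch:
                continue
            dist = abs(0.5 * (det.start + det.end) - ev.center)
            if dist <= max_center_dist:
                pairs.append((dist, ti, di))
    pairs.sort()
    used_t, used_d = set(), set()
    matches = []
    for dist, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        ev, ch = instances[ti]
        matches.append((ev, ch, detected[di]))
    misses = [instances[i] for i in range(len(instances)) if i not in used_t]
    return matches, misses
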