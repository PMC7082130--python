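"""Spindle / slow-wave coupling.

For every accepted spindle the EEG of its own channel is band-passed to
0.5-2 Hz (zero-phase).  Within a +-3 s window around the spindle center the
positive and negative peaks nearest in time to the center give the slow-wave
peak-to-peak amplitude, and the instantaneous phase of the analytic (Hilbert)
slow-wave signal at the center sample gives the coupling phase, with 0 at the
slow-wave positive peak and +-pi at the trough.  The phase method is a
package convention: the analytic-signal definition is one of several possible
readings of a "spindle-SW phase angle" and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .eeg_io import Recording
from .characterization import SpindleCatalog

SW_BAND = (0.5, 2.0)


@dataclass
class SwCoupling:
    """Slow-wave context of one spindle."""

    event: object                # the SpindleEvent
    sw_p2p: float                # signal units; NaN when undefined
    sw_phase: float              # radians in (-pi, pi]; NaN when undefined
    window: float = 3.0          # s each side of the spindle center
    truncated: bool = False      # window clipped at a recording edge

    @property
    def defined(self) -> bool:
        return np.isfinite(self.sw_p2p)


def filter_slow_wave(rec: Recording, channel: str | None = None,
                     band=SW_BAND) -> np.ndarray:
    """Zero-phase 0.5-2 Hz band-pass of one channel (or all channels)."""
    if rec.rate < 2 * band[1]:
        raise ValueError(f"rate {rec.rate} Hz too low for band {band}")
    sos = signal.butter(4, band, btype="band", fs=rec.rate, output="sos")
    data = rec.data if channel is None else rec.channel(channel)
    return signal.sosfiltfilt(sos, data, axis=-1)


def sw_peak_to_peak(trace: np.ndarray, rate: float, center: float,
                    window: float = 3.0) -> float:
    """Peak-to-peak amplitude of the nearest slow-wave extrema.

    Among the local maxima and local minima of ``trace`` within ``+-window``
    seconds of ``center`` (clipped at the trace edges), the maximum nearest in
    time and the minimum nearest in time are selected; the result is
    ``value(max) - value(min)``.  NaN when either kind of extremum is absent.
    """
    trace = np.asarray(trace, dtype=float)
    ci = int(round(center * rate))
    i0 = max(ci - int(round(window * rate)), 0)
    i1 = min(ci + int(round(window * rate)) + 1, len(trace))
    seg = trace[i0:i1]
    if len(seg) < 3:
        return float("nan")
    maxima, _ = signal.find_peaks(seg)
    minima, _ = signal.find_peaks(-seg)
    if len(maxima) == 0 or len(minima) == 0:
        return float("nan")
    pos = maxima[np.argmin(np.abs(maxima + i0 - ci))]
    neg = minima[np.argmin(np.abs(minima + i0 - ci))]
    return float(seg[pos] - seg[neg])


def sw_phase_at_center(trace: np.ndarray, rate: float, center: float) -> float:
    """Instantaneous slow-wave phase at the spindle center.

    Phase of the analytic representation of the filtered trace, so 0 falls at
    a slow-wave positive peak, -pi/2 at the ascending zero crossing and +-pi
    at the trough.  NaN for a degenerate (all-zero) trace.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.any(trace):
        return float("nan")
    analytic = signal.hilbert(trace)
    ci = int(round(center * rate))
    ci = min(max(ci, 0), len(trace) - 1)
    return float(np.angle(analytic[ci]))


def couple_events(rec: Recording, events, window: float = 3.0,
                  min_usable: float = 1.0) -> list[SwCoupling]:
    """Compute slow-wave coupling for every accepted event.

    Windows are clipped at the recording bounds and flagged; events with less
    than ``min_usable`` seconds of window on either side get NaN coupling.
    """
    filt: dict[str, np.ndarray] = {}
    phase_cache: dict[str, np.ndarray] = {}
    out = []
    for ev in events:
        if not ev.accepted:
            continue
        if ev.channel not in filt:
            trace = filter_slow_wave(rec, ev.channel)
            filt[ev.channel] = trace
            # one analytic transform per channel, reused for all its events
            phase_cache[ev.channel] = (
                np.angle(signal.hilbert(trace)) if np.any(trace)
                else np.full(len(trace), np.nan))
        trace = filt[ev.channel]
        center = ev.midpoint
        left = min(center, window)
        right = min(rec.duration - center, window)
        truncated = left < window or right < window
        if min(left, right) < min_usable:
            out.append(SwCoupling(ev, float("nan"), float("nan"),
                                  window, truncated))
            continue
        p2p = sw_peak_to_peak(trace, rec.rate, center, window)
        ci = min(max(int(round(center * rec.rate)), 0), len(trace) - 1)
        phase = float(phase_cache[ev.channel][ci])
        out.append(SwCoupling(ev, p2p, phase, window, truncated))
    return out


def circular_mean(phases) -> float:
    """Mean angle of a set of phases (radians)."""
    phases = np.asarray(phases, dtype=float)
    phases = phases[np.isfinite(phases)]
    if len(phases) == 0:
        return float("nan")
    return float(np.angle(np.exp(1j * phases).mean()))


def compare_local_vs_simultaneous(catalog: SpindleCatalog, couplings):
    """Group mean slow-wave p2p amplitudes for local vs simultaneous spindles.

    Returns a dict with the two group means and counts (NaN / 0 for an empty
    group).  No hypothesis test is performed.
    """
    by_event = {id(c.event): c for c in couplings}
    local = catalog.is_local()
    groups = {"local": [], "simultaneous": []}
    for ev, is_loc in zip(catalog.events, local):
        c = by_event.get(id(ev))
        if c is not None and c.defined:
            groups["local" if is_loc else "simultaneous"].append(c.sw_p2p)
    return {
        "mean_p2p_local": float(np.mean(groups["local"])) if groups["local"] else float("nan"),
        "mean_p2p_simultaneous": float(np.mean(groups["simultaneous"])) if groups["simultaneous"] else float("nan"),
        "n_local": len(groups["local"]),
        "n_simultaneous": len(groups["simultaneous"]),
    }
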