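"""Local/simultaneous spindle topography and per-stage summaries.

A spindle is "local" when no temporally overlapping spindle exists on any
other channel, and "simultaneous" otherwise; its multiplicity is one plus the
number of distinct partner channels.  Overlap is pairwise and half-open — no
transitive closure, so a chain A-B, B-C does not link A to C.  Connectivity
matrices tally co-occurring channel pairs for pair events (multiplicity
exactly 2) or widespread events (multiplicity >= 4), under either a global
normalization (unordered pairs sum to 1) or a per-channel row normalization
(each nonzero row sums to 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg_io import Hypnogram, NREM_STAGES, WAKE_STAGES
from .spindle_detection import SpindleEvent

NORMALIZATIONS = ("counts", "global", "per_channel_row")


@dataclass
class SpindleCatalog:
    """Accepted spindles annotated with their temporal-overlap partners."""

    events: list[SpindleEvent]
    partners: list[frozenset]  # per event: channel labels of overlapping events
    channels: tuple[str, ...]

    def __post_init__(self):
        if len(self.events) != len(self.partners):
            raise ValueError("events and partner sets must align")

    @property
    def multiplicity(self) -> np.ndarray:
        """1 + number of distinct partner channels, per event."""
        return np.array([1 + len(p) for p in self.partners])

    def is_local(self) -> np.ndarray:
        return self.multiplicity == 1

    @property
    def n_local(self) -> int:
        return int(self.is_local().sum())

    @property
    def n_simultaneous(self) -> int:
        return len(self.events) - self.n_local


def annotate_simultaneity(events, channels=None) -> SpindleCatalog:
    """Classify accepted events as local or simultaneous by pairwise overlap.

    Overlapping events on the *same* channel (which boundary refinement should
    preclude) are merged with a warning before annotation.
    """
    events = [e for e in events if e.accepted]
    merged: list[SpindleEvent] = []
    for ev in sorted(events, key=lambda e: (e.channel, e.start)):
        if merged and merged[-1].channel == ev.channel and merged[-1].overlaps(ev):
            warnings.warn(
                f"overlapping same-channel events on {ev.channel} merged")
            prev = merged[-1]
            prev.end = max(prev.end, ev.end)
        else:
            merged.append(ev)
    merged.sort(key=lambda e: e.start)

    partners: list[set] = [set() for _ in merged]
    for i, a in enumerate(merged):
        for j in range(i + 1, len(merged)):
            b = merged[j]
            if b.start >= a.end:
                break
            if a.overlaps(b) and a.channel != b.channel:
                partners[i].add(b.channel)
                partners[j].add(a.channel)
    if channels is None:
        channels = tuple(sorted({e.channel for e in merged}))
    return SpindleCatalog(merged, [frozenset(p) for p in partners],
                          tuple(channels))


def _overlap_pairs(catalog: SpindleCatalog, keep) -> np.ndarray:
    """Symmetric channel-pair co-occurrence counts over events passing ``keep``."""
    chans = catalog.channels
    idx = {c: i for i, c in enumerate(chans)}
    counts = np.zeros((len(chans), len(chans)))
    events = catalog.events
    mult = catalog.multiplicity
    for i, a in enumerate(events):
        if not keep(mult[i]):
            continue
        for j in range(i + 1, len(events)):
            b = events[j]
            if b.start >= a.end:
                break
            if a.overlaps(b) and a.channel != b.channel and keep(mult[j]):
                counts[idx[a.channel], idx[b.channel]] += 1
                counts[idx[b.channel], idx[a.channel]] += 1
    return counts


def _normalize(counts: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "counts":
        return counts
    if normalization == "global":
        total = counts.sum() / 2.0  # each unordered pair stored twice
        return counts / total if total > 0 else counts
    if normalization == "per_channel_row":
        out = counts.astype(float).copy()
        sums = out.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        out[nz] /= sums[nz]
        return out
    raise ValueError(f"unknown normalization {normalization!r}; "
                     f"choose from {NORMALIZATIONS}")


@dataclass
class ConnectivityMatrix:
    """Channel x channel co-occurrence counts or proportions."""

    values: pd.DataFrame
    normalization: str

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()


def pair_connectivity(catalog: SpindleCatalog,
                      normalization: str = "global") -> ConnectivityMatrix:
    """Connectivity over events occurring in exactly two channels."""
    counts = _overlap_pairs(catalog, keep=lambda m: m == 2)
    mat = _normalize(counts, normalization)
    df = pd.DataFrame(mat, index=catalog.channels, columns=catalog.channels)
    return ConnectivityMatrix(df, normalization)


def global_connectivity(catalog: SpindleCatalog, min_channels: int = 4,
                        normalization: str = "global") -> ConnectivityMatrix:
    """Connectivity over widespread events (multiplicity >= ``min_channels``)."""
    counts = _overlap_pairs(catalog, keep=lambda m: m >= min_channels)
    mat = _normalize(counts, normalization)
    df = pd.DataFrame(mat, index=catalog.channels, columns=catalog.channels)
    return ConnectivityMatrix(df, normalization)


# ---------------------------------------------------------------------------
# densities and summaries
# ---------------------------------------------------------------------------


def _event_epoch_ok(ev: SpindleEvent, hyp: Hypnogram, stage_set) -> bool:
    """Event midpoint lies in a non-artifact epoch of the stage set."""
    try:
        i = hyp.epoch_of(ev.midpoint)
    except IndexError:
        return False
    return hyp.stages[i] in stage_set and not hyp.artifact[i]


def stage_density(events, hyp: Hypnogram, stages, channel: str | None = None) -> float:
    """Accepted spindles per minute spent in the given stages.

    Artifact-flagged epochs are excluded from both numerator and denominator.
    Returns NaN when no time was spent in the stage set.
    """
    stages = {stages} if isinstance(stages, str) else set(stages)
    minutes = hyp.time_in(stages) / 60.0
    if minutes == 0:
        return float("nan")
    n = sum(
        1 for e in events
        if e.accepted and (channel is None or e.channel == channel)
        and _event_epoch_ok(e, hyp, stages)
    )
    return n / minutes


def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": [e.channel for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "duration": [e.duration for e in events],
            "peak_freq": [e.peak_freq for e in events],
            "peak_freq_power": [e.peak_freq_power for e in events],
            "mean_power": [e.mean_power for e in events],
            "accepted": [e.accepted for e in events],
        }
    )


def stage_summary(events, hyp: Hypnogram, day_mask=None) -> pd.DataFrame:
    """Per channel x stage (optionally x day/night) spindle summaries.

    ``day_mask`` is an optional boolean array over epochs (True = day).  The
    table reports spindle density (per min), mean peak frequency, duration and
    power, and the event count; groups with no stage time are omitted.
    """
    acc = [e for e in events if e.accepted]
    rows = []
    stages_present = sorted(set(hyp.stages))
    channels = sorted({e.channel for e in acc})
    periods = [("all", None)] if day_mask is None else [
        ("day", True), ("night", False)]
    day_mask = None if day_mask is None else np.asarray(day_mask, dtype=bool)

    for period, day_val in periods:
        for stage in stages_present:
            epoch_ok = np.array(
                [s == stage for s in hyp.stages]) & ~hyp.artifact
            if day_val is not None:
                epoch_ok &= day_mask == day_val
            minutes = epoch_ok.sum() * hyp.epoch_len / 60.0
            for ch in channels:
                sel = [
                    e for e in acc
                    if e.channel == ch and 0 <= e.midpoint < hyp.duration
                    and epoch_ok[hyp.epoch_of(e.midpoint)]
                ]
                rows.append(
                    {
                        "period": period,
                        "stage": stage,
                        "channel": ch,
                        "n": len(sel),
                        "density_per_min": len(sel) / minutes if minutes else np.nan,
                        "mean_freq": np.mean([e.peak_freq for e in sel]) if sel else np.nan,
                        "mean_duration": np.mean([e.duration for e in sel]) if sel else np.nan,
                        "mean_power": np.mean([e.mean_power for e in sel]) if sel else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def plot_connectivity(conn: ConnectivityMatrix, ax=None):
    """Heat-map helper for a connectivity matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(conn.matrix, cmap="viridis")
    ax.set_xticks(range(len(conn.values.columns)),
                  conn.values.columns, rotation=90)
    ax.set_yticks(range(len(conn.values.index)), conn.values.index)
    ax.figure.colorbar(im, ax=ax, label=conn.normalization)
    return ax
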