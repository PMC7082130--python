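"""Sleep macrostructure: NREM substaging, sleep cycles, density profiles.

A sleep cycle starts after at least 30 s of wake, requires a contiguous NREM
run of at least 2 min, and terminates at the first epoch of wake or of a REM
run lasting at least 1 min.  Light/deep NREM substaging splits epochs at 50%
of the maximum per-epoch delta (0.5-4 Hz) power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .eeg_io import (
    Hypnogram,
    NREM_STAGES,
    REM_STAGES,
    Recording,
    WAKE_STAGES,
)

DELTA_BAND = (0.5, 4.0)


@dataclass(frozen=True)
class SleepCycle:
    start: float       # s, start of the NREM period
    end: float         # s, start of the terminating wake/REM
    terminator: str    # "wake" or "rem"

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# delta-power substaging
# ---------------------------------------------------------------------------


def epoch_delta_power(rec: Recording, hyp: Hypnogram,
                      band=DELTA_BAND) -> np.ndarray:
    """Per-epoch delta band power, averaged over channels.

    Hann-windowed full-epoch FFT per channel; band power sums bins whose
    centers fall in the half-open band.
    """
    spe = int(round(hyp.epoch_len * rec.rate))
    freqs = np.fft.rfftfreq(spe, d=1.0 / rec.rate)
    in_band = (freqs >= band[0]) & (freqs < band[1])
    win = np.hanning(spe)
    out = np.full(hyp.n_epochs, np.nan)
    for i in range(hyp.n_epochs):
        i0 = i * spe
        if i0 + spe > rec.n_samples:
            break
        seg = rec.data[:, i0:i0 + spe] * win
        psd = np.abs(np.fft.rfft(seg, axis=-1)) ** 2
        out[i] = psd[:, in_band].sum(axis=-1).mean()
    return out


def substage_nrem(rec: Recording, hyp: Hypnogram,
                  band=DELTA_BAND) -> Hypnogram:
    """Resolve NREM epochs into light (S1/U1) vs deep (S2/U2).

    Epochs whose delta power is at least 50% of the maximum delta power over
    the (non-artifact) NREM epochs become deep; the rest become light.  The
    S (plain NREM) vs U (ruminating NREM) family of each epoch is preserved.
    """
    nrem = [i for i, s in enumerate(hyp.stages)
            if s in NREM_STAGES and not hyp.artifact[i]]
    if not nrem:
        raise ValueError("hypnogram contains no NREM epochs")
    delta = epoch_delta_power(rec, hyp, band)
    thr = 0.5 * np.nanmax(delta[nrem])
    stages = list(hyp.stages)
    for i in nrem:
        family = "U" if stages[i].startswith("U") else "S"
        stages[i] = f"{family}{'2' if delta[i] >= thr else '1'}"
    return Hypnogram(tuple(stages), hyp.artifact.copy(), hyp.epoch_len)


# ---------------------------------------------------------------------------
# sleep cycles
# ---------------------------------------------------------------------------


def _classify(stage: str) -> str:
    if stage in WAKE_STAGES:
        return "w"
    if stage in NREM_STAGES:
        return "n"
    if stage in REM_STAGES:
        return "r"
    raise ValueError(f"unclassifiable stage {stage!r}")


def find_sleep_cycles(hyp: Hypnogram, min_wake: float = 30.0,
                      min_nrem: float = 120.0,
                      min_rem: float = 60.0) -> list[SleepCycle]:
    """Identify sleep cycles from a hypnogram.

    The NREM run must directly follow the qualifying wake run and is read
    strictly: any interior non-NREM epoch ends it.  A REM terminator must
    itself last at least ``min_rem`` seconds; an under-length REM run
    invalidates the candidate cycle.
    """
    kinds = [_classify(s) for s in hyp.stages]
    el = hyp.epoch_len
    need_w = int(np.ceil(min_wake / el))
    need_n = int(np.ceil(min_nrem / el))
    need_r = int(np.ceil(min_rem / el))

    cycles: list[SleepCycle] = []
    i, n = 0, len(kinds)
    while i < n:
        if kinds[i] != "w":
            i += 1
            continue
        j = i
        while j < n and kinds[j] == "w":
            j += 1
        if j - i < need_w or j >= n or kinds[j] != "n":
            i = j
            continue
        k = j
        while k < n and kinds[k] == "n":
            k += 1
        if k - j < need_n:
            i = k
            continue
        if k >= n:          # recording ends inside NREM: no terminator
            break
        if kinds[k] == "w":
            cycles.append(SleepCycle(j * el, k * el, "wake"))
            i = k
        else:  # REM run must last >= min_rem
            r = k
            while r < n and kinds[r] == "r":
                r += 1
            if r - k >= need_r:
                cycles.append(SleepCycle(j * el, k * el, "rem"))
            i = r
    return cycles


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------


def cycle_density_profile(events, cycles, window: float = 180.0,
                          min_cycle: float = 1080.0, n_cycles: int = 3):
    """Spindle proportions per consecutive window of the first long cycles.

    The first ``n_cycles`` cycles lasting at least ``min_cycle`` seconds are
    split into ``window``-second periods; accepted-spindle counts per period
    are normalized so the proportions over all included periods sum to 1.

    Returns ``(table, n_qualifying)``; fewer qualifying cycles than requested
    is reported through ``n_qualifying`` (the available ones are used).
    """
    qualifying = [c for c in cycles if c.duration >= min_cycle][:n_cycles]
    rows = []
    acc = [e for e in events if e.accepted]
    for ci, cyc in enumerate(qualifying):
        n_win = int(cyc.duration // window)
        for w in range(n_win):
            t0 = cyc.start + w * window
            t1 = t0 + window
            count = sum(1 for e in acc if t0 <= e.midpoint < t1)
            rows.append({"cycle": ci, "window": w, "t0": t0, "count": count})
    df = pd.DataFrame(rows, columns=["cycle", "window", "t0", "count"])
    total = df["count"].sum()
    df["proportion"] = df["count"] / total if total > 0 else np.nan
    return df, len(qualifying)


def hourly_density(events, hyp: Hypnogram, n_hours: int | None = None) -> pd.Series:
    """NREM-normalized spindle density per hour.

    For each hour: accepted spindles whose midpoint lies in a non-artifact
    NREM epoch, divided by the NREM minutes in that hour.  Hours without NREM
    are NaN.
    """
    if n_hours is None:
        n_hours = int(np.ceil(hyp.duration / 3600.0))
    acc = [e for e in events if e.accepted]
    nrem_idx = set(hyp.epoch_indices(NREM_STAGES))
    values = []
    for h in range(n_hours):
        e0 = int(h * 3600 / hyp.epoch_len)
        e1 = min(int((h + 1) * 3600 / hyp.epoch_len), hyp.n_epochs)
        epochs = [i for i in range(e0, e1) if i in nrem_idx]
        minutes = len(epochs) * hyp.epoch_len / 60.0
        if minutes == 0:
            values.append(np.nan)
            continue
        epoch_set = set(epochs)
        count = sum(
            1 for e in acc
            if 0 <= e.midpoint < hyp.duration
            and hyp.epoch_of(e.midpoint) in epoch_set
        )
        values.append(count / minutes)
    return pd.Series(values, index=pd.RangeIndex(n_hours, name="hour"),
                     name="density_per_min")
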