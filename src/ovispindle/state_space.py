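"""State-space analysis of EEG spectral ratios.

Each 10 s epoch is summarized by two band-power ratios computed from
Hann-windowed full-epoch FFTs: SSR1 = power(6.5-9 Hz) / power(0.5-9 Hz) and
SSR2 = power(0.5-20 Hz) / power(0.5-100 Hz).  Because each numerator band is
nested in its denominator, both ratios lie in [0, 1].  Epoch ratios are
binned on a 41 x 41 grid of 0.025-wide cells (1681 cells; the 41st cell
closes the upper boundary), normalized per subject to total 1, and summed
across subjects so the combined map totals the subject count.  Contour
thresholds of 2.5x and 5x the uniform density (n_subjects / 1681) outline the
dominant-state regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import Hypnogram, NREM_STAGES, Recording, WAKE_STAGES
from .characterization import SpindleCatalog

SSR1_BANDS = ((6.5, 9.0), (0.5, 9.0))
SSR2_BANDS = ((0.5, 20.0), (0.5, 100.0))
GRID_UNIT = 0.025
GRID_SIZE = 41
SOURCES = ("all_channels_mean", "spindle_channel")


@dataclass(frozen=True)
class StateSpaceEpoch:
    ssr1: float
    ssr2: float
    stage: str | None = None
    source: str = "all_channels_mean"
    t0: float = float("nan")


@dataclass
class DensityMap:
    """Proportional epoch density over the (SSR1, SSR2) grid."""

    grid: np.ndarray              # (GRID_SIZE, GRID_SIZE), ssr1 x ssr2
    unit: float = GRID_UNIT
    n_subjects: int = 1

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be {GRID_SIZE} x {GRID_SIZE}")
        if (self.grid < 0).any():
            raise ValueError("grid weights must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.grid.size

    @property
    def total(self) -> float:
        return float(self.grid.sum())

    def above(self, level: float) -> np.ndarray:
        """Boolean mask of cells above a contour level."""
        return self.grid > level


def _band_power(psd: np.ndarray, freqs: np.ndarray, band) -> np.ndarray:
    """Sum of PSD bins whose centers fall in the half-open band [low, high)."""
    mask = (freqs >= band[0]) & (freqs < band[1])
    return psd[..., mask].sum(axis=-1)


def epoch_ssr(rec: Recording, t0: float, epoch_len: float = 10.0,
              source: str = "all_channels_mean",
              spindle_channel: str | None = None,
              stage: str | None = None) -> StateSpaceEpoch | None:
    """Spectral state-space ratios of one epoch.

    A Hann-windowed full-epoch FFT is taken per channel; with
    ``source="all_channels_mean"`` the spectra are averaged across channels
    before the ratios are formed, with ``source="spindle_channel"`` only the
    named channel's spectrum is used.  Returns None when a denominator band
    has zero power (degenerate epoch).
    """
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}")
    if rec.rate < 2 * SSR2_BANDS[1][1]:
        raise ValueError(
            f"rate {rec.rate} Hz too low for the "
            f"{SSR2_BANDS[1][1]} Hz band edge")
    i0 = int(round(t0 * rec.rate))
    n = int(round(epoch_len * rec.rate))
    if i0 < 0 or i0 + n > rec.n_samples:
        raise ValueError("epoch extends outside the recording")
    seg = rec.data[:, i0:i0 + n]
    if source == "spindle_channel":
        if spindle_channel is None:
            raise ValueError("spindle_channel source needs a channel name")
        seg = seg[rec.channel_index(spindle_channel):
                  rec.channel_index(spindle_channel) + 1]
    win = np.hanning(n)
    psd = np.abs(np.fft.rfft(seg * win, axis=-1)) ** 2
    psd = psd.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.rate)

    d1 = _band_power(psd, freqs, SSR1_BANDS[1])
    d2 = _band_power(psd, freqs, SSR2_BANDS[1])
    if d1 <= 0 or d2 <= 0:
        return None
    return StateSpaceEpoch(
        ssr1=float(_band_power(psd, freqs, SSR1_BANDS[0]) / d1),
        ssr2=float(_band_power(psd, freqs, SSR2_BANDS[0]) / d2),
        stage=stage, source=source, t0=t0,
    )


def stage_epochs_ssr(rec: Recording, hyp: Hypnogram,
                     stages=None) -> list[StateSpaceEpoch]:
    """Ratios for all (non-artifact) epochs scored wake or NREM.

    ``stages`` restricts the stage set (default: wake plus NREM, giving the
    all-epoch state map).  Undefined epochs are dropped.
    """
    if stages is None:
        stages = WAKE_STAGES | NREM_STAGES
    out = []
    for i in hyp.epoch_indices(stages):
        t0 = i * hyp.epoch_len
        if (i + 1) * hyp.epoch_len * rec.rate > rec.n_samples + 0.5:
            continue
        e = epoch_ssr(rec, t0, hyp.epoch_len, stage=hyp.stages[i])
        if e is not None:
            out.append(e)
    return out


def build_density_map(epochs) -> DensityMap:
    """Bin epoch ratios into the 41 x 41 grid and normalize to total 1.

    Cells are ``[k*0.025, (k+1)*0.025)`` for k = 0..40; a ratio of exactly 1
    falls in the last cell (closed upper boundary).
    """
    epochs = [e for e in epochs if e is not None]
    if not epochs:
        raise ValueError("no epochs with defined ratios")
    grid = np.zeros((GRID_SIZE, GRID_SIZE))
    for e in epochs:
        i = min(int(e.ssr1 / GRID_UNIT), GRID_SIZE - 1)
        j = min(int(e.ssr2 / GRID_UNIT), GRID_SIZE - 1)
        grid[i, j] += 1
    return DensityMap(grid / len(epochs))


def combine_maps(maps) -> DensityMap:
    """Cell-wise sum of per-subject maps; the total equals the subject count."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to combine")
    unit = maps[0].unit
    if any(m.unit != unit or m.grid.shape != maps[0].grid.shape for m in maps):
        raise ValueError("maps use different grids")
    grid = np.sum([m.grid for m in maps], axis=0)
    return DensityMap(grid, unit, n_subjects=sum(m.n_subjects for m in maps))


def contour_levels(n_subjects: int, n_cells: int = GRID_SIZE * GRID_SIZE,
                   low_mult: float = 2.5, high_mult: float = 5.0):
    """Lower/upper contour thresholds as multiples of the uniform density."""
    if n_subjects <= 0 or n_cells <= 0:
        raise ValueError("n_subjects and n_cells must be positive")
    base = n_subjects / n_cells
    return low_mult * base, high_mult * base


def spindle_epoch_map(rec: Recording, catalog: SpindleCatalog,
                      source: str = "all_channels_mean",
                      epoch_len: float = 10.0,
                      hyp: Hypnogram | None = None,
                      stages=None) -> DensityMap:
    """Density map over epochs centered on every local spindle.

    When a hypnogram is supplied, only spindles whose midpoint falls in a
    non-artifact epoch of ``stages`` (default: wake plus NREM, the stages the
    spindle-occurrence state map collates) are included.  Spindles whose
    centered epoch would extend past a recording edge are skipped.  Raises
    when no local spindle yields a usable epoch.
    """
    if stages is None:
        stages = WAKE_STAGES | NREM_STAGES
    epochs = []
    for ev, is_loc in zip(catalog.events, catalog.is_local()):
        if not is_loc:
            continue
        if hyp is not None:
            try:
                i = hyp.epoch_of(ev.midpoint)
            except IndexError:
                continue
            if hyp.stages[i] not in stages or hyp.artifact[i]:
                continue
        t0 = ev.midpoint - epoch_len / 2.0
        if t0 < 0 or t0 + epoch_len > rec.duration:
            continue
        e = epoch_ssr(rec, t0, epoch_len, source=source,
                      spindle_channel=ev.channel)
        if e is not None:
            epochs.append(e)
    if not epochs:
        raise ValueError("no local spindles with usable centered epochs")
    return build_density_map(epochs)


def map_to_frame(dmap: DensityMap):
    """Long-format ``ssr1_bin, ssr2_bin, weight`` table."""
    import pandas as pd

    i, j = np.nonzero(dmap.grid >= 0)
    return pd.DataFrame(
        {"ssr1_bin": i, "ssr2_bin": j, "weight": dmap.grid[i, j]}
    )


def plot_density_map(dmap: DensityMap, levels=None, ax=None, **contour_kw):
    """Static contour plot of a density map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [0, GRID_SIZE * dmap.unit, 0, GRID_SIZE * dmap.unit]
    ax.imshow(dmap.grid.T, origin="lower", extent=extent, aspect="auto",
              cmap="Greys")
    if levels is not None:
        centers = (np.arange(GRID_SIZE) + 0.5) * dmap.unit
        ax.contour(centers, centers, dmap.grid.T, levels=sorted(levels),
                   **contour_kw)
    ax.set_xlabel("SSR1 (6.5-9 / 0.5-9 Hz)")
    ax.set_ylabel("SSR2 (0.5-20 / 0.5-100 Hz)")
    return ax
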