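"""Recording / hypnogram containers and I/O.

EEG recordings are held as a channels-by-samples float array in millivolts
with a uniform sampling rate.  Hypnograms are epoch-indexed vigilance-stage
sequences (10 s epochs by default) with per-epoch artifact flags.

Supported on-disk formats: 16-bit EDF (read through :mod:`mne`, written by a
small built-in writer) and delimited text with one column per channel and a
header row of channel labels.  Hypnograms travel as ``epoch,stage,artifact``
CSV.  Time is expressed in seconds, sample indices are 0-based, and all
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

#: Vigilance stages: wake, wake+rumination, light/deep NREM, light/deep
#: NREM with rumination, REM.  "N"/"U" are unresolved NREM placeholders
#: accepted before light/deep substaging has been applied.
STAGES = ("W", "WU", "S1", "S2", "U1", "U2", "R")
UNRESOLVED_STAGES = ("N", "U")

WAKE_STAGES = frozenset({"W", "WU"})
NREM_STAGES = frozenset({"S1", "S2", "U1", "U2", "N", "U"})
REM_STAGES = frozenset({"R"})

#: Default montage: bilateral anterior (A1, A2), central and posterior sites.
DEFAULT_LABELS = ("A1-L", "A1-R", "A2-L", "A2-R", "C-L", "C-R", "P-L", "P-R")


@dataclass
class Recording:
    """Uniformly sampled multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in millivolts.
    rate : float
        Sampling rate in samples/s.
    labels : tuple of str
        Unique channel names.
    start_time : float
        Offset of the first sample, seconds.
    """

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]
    start_time: float = 0.0
    units: str = "mV"

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = tuple(self.labels)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


@dataclass
class Hypnogram:
    """Epoch-based vigilance-stage scoring with artifact flags."""

    stages: tuple[str, ...]
    artifact: np.ndarray = None
    epoch_len: float = 10.0

    def __post_init__(self):
        self.stages = tuple(self.stages)
        allowed = set(STAGES) | set(UNRESOLVED_STAGES)
        bad = sorted(set(self.stages) - allowed)
        if bad:
            raise ValueError(f"unknown vigilance stages: {bad}")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if self.artifact is None:
            self.artifact = np.zeros(len(self.stages), dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.artifact.shape != (len(self.stages),):
            raise ValueError("artifact flags must align with stages")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    def epoch_of(self, t: float) -> int:
        """Index of the epoch containing time ``t`` (seconds)."""
        i = int(t // self.epoch_len)
        if not 0 <= i < self.n_epochs:
            raise IndexError(f"time {t} s outside hypnogram")
        return i

    def epoch_indices(self, stages, include_artifact: bool = False) -> np.ndarray:
        """Indices of epochs whose stage is in ``stages``."""
        stages = {stages} if isinstance(stages, str) else set(stages)
        mask = np.array([s in stages for s in self.stages])
        if not include_artifact:
            mask &= ~self.artifact
        return np.flatnonzero(mask)

    def time_in(self, stages, include_artifact: bool = False) -> float:
        """Seconds spent in the given stages (artifact epochs excluded)."""
        return len(self.epoch_indices(stages, include_artifact)) * self.epoch_len


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_UNIT_TO_MV = {"mV": 1.0, "uV": 1e-3, "V": 1e3}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in {".csv", ".txt", ".tsv"}:
        return "text"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(path, format: str | None = None, rate: float | None = None,
                   units: str = "mV") -> Recording:
    """Read a multichannel recording from EDF or delimited text.

    Text files need a header row of channel labels and an explicit ``rate``
    (text carries no timing metadata).  Values are converted to millivolts
    using ``units``; EDF files declare their own physical units and ``units``
    is ignored for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e3  # mne returns volts
        return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))
    if fmt == "text":
        if rate is None:
            raise ValueError("text recordings need an explicit sampling rate")
        with open(path) as fh:
            header = fh.readline()
            while header.startswith("#"):
                header = fh.readline()
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, comment="#")
        if df.empty or df.shape[1] < 1:
            raise ValueError(f"{path} contains no channel data")
        try:
            scale = _UNIT_TO_MV[units]
        except KeyError:
            raise ValueError(f"unknown units {units!r}") from None
        data = df.to_numpy(dtype=float).T * scale
        if np.isnan(data).any():
            raise ValueError(f"{path} has missing values / ragged columns")
        return Recording(data, float(rate), tuple(str(c) for c in df.columns))
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write a recording as EDF (16-bit) or delimited text."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "text":
        df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal 16-bit EDF writer (one-second data records, µV physical units).

    The sample count is padded with zeros to a whole number of records.
    """
    if abs(rec.rate - round(rec.rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rec.rate))  # samples per 1 s record
    n_ch = rec.n_channels
    n_records = max(1, math.ceil(rec.n_samples / spr))

    data_uv = rec.data * 1e3  # mV -> µV
    phys_max = np.maximum(np.abs(data_uv).max(axis=1), 1.0)
    digital = np.round(data_uv / phys_max[:, None] * 32767.0).astype("<i2")
    pad = n_records * spr - rec.n_samples
    if pad:
        digital = np.pad(digital, ((0, 0), (0, pad)))

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X", 80))            # patient id
        fh.write(_edf_field("ovispindle", 80))   # recording id
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(256 * (1 + n_ch), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field("1", 8))             # record duration, s
        fh.write(_edf_field(n_ch, 4))
        for lab in rec.labels:
            fh.write(_edf_field(lab[:16], 16))
        fh.write(b" " * 80 * n_ch)               # transducer
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for pm in phys_max:
            fh.write(_edf_field(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            fh.write(_edf_field(f"{pm:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_edf_field(-32768, 8))
        for _ in range(n_ch):
            fh.write(_edf_field(32767, 8))
        fh.write(b" " * 80 * n_ch)               # prefiltering
        for _ in range(n_ch):
            fh.write(_edf_field(spr, 8))
        fh.write(b" " * 32 * n_ch)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_hypnogram(path, epoch_len: float = 10.0) -> Hypnogram:
    """Read an ``epoch,stage,artifact`` CSV hypnogram."""
    df = pd.read_csv(path, comment="#")
    required = {"epoch", "stage", "artifact"}
    if not required.issubset(df.columns):
        raise ValueError(f"hypnogram CSV needs columns {sorted(required)}")
    df = df.sort_values("epoch")
    return Hypnogram(
        tuple(df["stage"].astype(str)),
        df["artifact"].astype(int).to_numpy().astype(bool),
        epoch_len=epoch_len,
    )


def write_hypnogram(hyp: Hypnogram, path) -> None:
    pd.DataFrame(
        {
            "epoch": np.arange(hyp.n_epochs),
            "stage": list(hyp.stages),
            "artifact": hyp.artifact.astype(int),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Resample to ``target_rate`` with an anti-aliased polyphase FIR.

    ``downsample(rec, rec.rate)`` is the identity (up to a copy).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > rec.rate:
        raise ValueError("target_rate exceeds the recording rate")
    if abs(target_rate - rec.rate) < 1e-12:
        return rec.copy()
    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, rate=target_rate)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))
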