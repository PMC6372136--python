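"""Waveform containers and delimited-text I/O.

The package operates on uniformly sampled single-channel recordings
(arterial blood pressure, PPG, or any approximately periodic signal).
The only pre-editing supported is exclusion of non-physiological
artifact intervals via :class:`ArtifactMask`; there is deliberately no
detrending or filtering, because the downstream morphology features are
baseline-invariant by construction and any filtering would alter the
waveform shape the method quantifies.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd


def _read_table(path, header="infer") -> pd.DataFrame:
    """Delimited-text reader with exactly rounded float parsing."""
    with open(path) as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
    except csv.Error:
        sep = ","
    return pd.read_csv(
        path, sep=sep, header=header, comment="#", float_precision="round_trip"
    )

__all__ = [
    "Signal",
    "ArtifactMask",
    "WindowSpec",
    "read_signal",
    "write_signal",
    "samples_in_window",
    "apply_mask",
]

#: Relative tolerance on time-grid uniformity when inferring fs from a
#: time column.
TIME_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled waveform.

    Sample ``i`` covers the half-open time interval
    ``[t0 + i/fs, t0 + (i+1)/fs)``.

    Parameters
    ----------
    samples : array-like of float
        Sample values (e.g. pressure in mmHg, or arbitrary units).
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Start time in seconds of the first sample.
    units : str
        Free-text unit label carried through to feature output.
    meta : dict
        Optional provenance (e.g. per-beat ground truth from the
        synthetic generator). Not interpreted by the pipeline.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "a.u."
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.isfinite(samples).all():
            raise ValueError("samples contain non-finite values")
        if not (self.fs > 0):
            raise ValueError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (= n_samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + i/fs`` in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice_seconds(self, start_s: float, end_s: float) -> "Signal":
        """Extract the samples whose times fall in ``[start_s, end_s)``."""
        i0 = int(np.ceil((start_s - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end_s - self.t0) * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(self))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start_s}, {end_s}) s")
        return dataclasses.replace(
            self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs, meta={}
        )


@dataclass(frozen=True)
class ArtifactMask:
    """Half-open ``[start_s, end_s)`` time intervals to exclude.

    Intervals are normalized on construction: sorted and merged so the
    stored list is non-overlapping.
    """

    intervals: tuple = ()

    def __post_init__(self) -> None:
        norm = []
        for start, end in sorted((float(a), float(b)) for a, b in self.intervals):
            if not start < end:
                raise ValueError(f"invalid interval [{start}, {end})")
            if norm and start <= norm[-1][1]:
                norm[-1] = (norm[-1][0], max(norm[-1][1], end))
            else:
                norm.append((start, end))
        object.__setattr__(self, "intervals", tuple(norm))

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ArtifactMask":
        """Read a two-column (start_s, end_s) delimited file, header optional."""
        df = _read_table(path, header=None)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (start_s, end_s)")
        first = df.iloc[0]
        try:
            float(first.iloc[0]), float(first.iloc[1])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        arr = df.iloc[:, :2].astype(float).to_numpy()
        return cls(intervals=tuple(map(tuple, arr)))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``length_s`` window, ``step_s`` hop."""

    length_s: float
    step_s: float

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.length_s):
            raise ValueError(
                f"need 0 < step_s <= length_s, got step={self.step_s}, length={self.length_s}"
            )

    def count(self, duration_s: float) -> int:
        """Number of full windows fitting in ``duration_s`` seconds."""
        if duration_s < self.length_s:
            return 0
        return int(np.floor((duration_s - self.length_s) / self.step_s + 1e-9)) + 1


def samples_in_window(fs: float, duration_s: float) -> int:
    """Number of samples a monitor records in ``duration_s`` at rate ``fs``.

    E.g. a bedside monitor at 125 Hz stores 1250 points over a 10 s window.
    """
    if not (fs > 0 and duration_s > 0):
        raise ValueError("fs and duration_s must be positive")
    return int(round(fs * duration_s))


def read_signal(
    path: Union[str, Path],
    fs: Optional[float] = None,
    column: Optional[Union[str, int]] = None,
    units: str = "a.u.",
) -> Signal:
    """Read a delimited-text waveform.

    Accepts either a two-column (time, value) file — the sampling rate is
    then inferred from the median time step and the grid checked for
    uniformity — or a value-only file, in which case ``fs`` is required
    (never guessed: every rate-dependent feature would silently scale).

    Parameters
    ----------
    path : str or Path
        CSV/TSV file, optional header, '.' decimal point.
    fs : float, optional
        Sampling rate in Hz. Mandatory for value-only files; if given
        alongside a time column it overrides the inferred rate.
    column : str or int, optional
        Value column name or positional index; defaults to the last column.

    Raises
    ------
    ValueError
        If the time grid is non-uniform beyond 1 ppm (the worst gap is
        named), or a value-only file is given without ``fs``.
    """
    df = _read_table(path)
    # Header detection: if every column name parses as a number the file
    # had no header and pandas swallowed the first data row.
    try:
        [float(c) for c in df.columns]
        df = _read_table(path, header=None)
    except (TypeError, ValueError):
        pass
    df = df.dropna(axis=1, how="all")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns found")

    if column is not None:
        values = (df.iloc[:, column] if isinstance(column, int) else df[column]).to_numpy(float)
    else:
        values = df.iloc[:, -1].to_numpy(float)

    t0 = 0.0
    if df.shape[1] >= 2 and (column is None or (isinstance(column, int) and column != 0)):
        t = df.iloc[:, 0].to_numpy(float)
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError(f"{path}: need at least two samples to infer fs")
        med = float(np.median(dt))
        if med <= 0:
            raise ValueError(f"{path}: time column is not increasing")
        worst = int(np.argmax(np.abs(dt - med)))
        if abs(dt[worst] - med) > TIME_GRID_RTOL * med:
            raise ValueError(
                f"{path}: non-uniform time grid; worst gap {dt[worst]:.9g} s "
                f"between t={t[worst]:.9g} and t={t[worst + 1]:.9g} "
                f"(median step {med:.9g} s)"
            )
        inferred = 1.0 / med
        t0 = float(t[0])
        fs = fs if fs is not None else inferred
    elif fs is None:
        raise ValueError(f"{path}: value-only file requires an explicit sampling rate (fs)")

    return Signal(samples=values, fs=float(fs), t0=t0, units=units)


def write_signal(signal: Signal, path: Union[str, Path], time_column: bool = True) -> None:
    """Write a signal as CSV, round-tripping samples bit-exactly.

    Values are written with ``repr``-faithful precision so
    ``read_signal(write_signal(s))`` reproduces ``s.samples`` exactly and
    ``fs`` within 1 ppm.
    """
    path = Path(path)
    with path.open("w") as fh:
        if time_column:
            fh.write("time_s,value\n")
            for i, x in enumerate(signal.samples):
                fh.write(f"{signal.t0 + i / signal.fs:.12g},{float(x)!r}\n")
        else:
            fh.write("value\n")
            for x in signal.samples:
                fh.write(f"{float(x)!r}\n")


def apply_mask(signal: Signal, mask: ArtifactMask) -> list:
    """Split a signal into the contiguous segments outside the mask.

    Each returned segment is a valid :class:`Signal` with its own ``t0``.
    Masked sample counts are conserved: the segment lengths plus the
    number of masked samples equal the original length.

    Raises
    ------
    ValueError
        If any mask interval lies (partly) outside the signal's time span.
    """
    t_end = signal.t0 + signal.duration
    for start, end in mask.intervals:
        if start < signal.t0 - 1e-12 or end > t_end + 1e-12:
            raise ValueError(
                f"mask interval [{start}, {end}) outside signal span "
                f"[{signal.t0}, {t_end})"
            )
    # Sample i is masked iff its time t0 + i/fs falls in a masked interval.
    n = len(signal)
    masked = np.zeros(n, dtype=bool)
    for start, end in mask.intervals:
        i0 = int(np.ceil((start - signal.t0) * signal.fs - 1e-9))
        i1 = int(np.ceil((end - signal.t0) * signal.fs - 1e-9))
        masked[max(i0, 0) : min(i1, n)] = True

    segments = []
    keep = ~masked
    if keep.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], keep.view(np.int8), [0]))))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            segments.append(
                dataclasses.replace(
                    signal,
                    samples=signal.samples[i0:i1],
                    t0=signal.t0 + i0 / signal.fs,
                    meta={},
                )
            )
    return segments
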