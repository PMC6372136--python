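"""Cycle-length estimation and 3-D delay-coordinate embedding.

An approximately periodic scalar signal x(t) is embedded in three
dimensions via delay coordinates (x(t), x(t - tau), x(t - 2*tau)) with
the delay set to one third of the average cycle length T. Viewed along
the main diagonal (1,1,1) the trajectory collapses onto a triangular
planar attractor; the rotation into that viewing frame splits the
trajectory into a baseline coordinate

    u = (x + y + z)/sqrt(3)

which carries the mean signal level (and hence all baseline wander),
and the morphology plane

    v = (x + y - 2z)/sqrt(6),   w = (x - y)/sqrt(2),

which is invariant to any additive constant and carries the waveform
shape. The basis is orthonormal, so Euclidean norms are preserved and
(v, w) inherit the signal's physical units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.signal import argrelmax
from scipy.signal.windows import hann

from .io import Signal

__all__ = [
    "CycleEstimate",
    "Trajectory3",
    "UVWSeries",
    "estimate_cycle_length",
    "heart_rate_from_cycle",
    "bpm_from_beat_count",
    "delay_embed",
    "project_uvw",
]

SQRT3 = np.sqrt(3.0)
SQRT6 = np.sqrt(6.0)
SQRT2 = np.sqrt(2.0)

#: Fundamental-vs-harmonic guard: among autocorrelation local maxima in
#: the search range, the smallest lag scoring at least this fraction of
#: the in-range global maximum is taken as the fundamental period.
HARMONIC_GUARD = 0.8

#: Delay as a fraction of the average cycle length. One third gives the
#: three-fold symmetric triangular attractor this package quantifies.
TAU_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class CycleEstimate:
    """Average cycle length estimate from windowed autocorrelation."""

    T: float
    score: float
    search_range: Tuple[float, float]

    @property
    def heart_rate(self) -> float:
        """Heart rate in beats per minute (full precision)."""
        return heart_rate_from_cycle(self.T)


@dataclass(frozen=True)
class Trajectory3:
    """Delay-coordinate triples (x(t), x(t - tau), x(t - 2*tau))."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    tau: float
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class UVWSeries:
    """Trajectory rotated into the baseline (u) / morphology (v, w) frame."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    tau: float
    fs: float

    def __len__(self) -> int:
        return len(self.u)

    @property
    def vw(self) -> np.ndarray:
        """The (n, 2) morphology-plane point cloud."""
        return np.column_stack((self.v, self.w))


def estimate_cycle_length(
    signal: Signal,
    T_min: float,
    T_max: float,
    harmonic_guard: float = HARMONIC_GUARD,
) -> CycleEstimate:
    """Estimate the average waveform cycle length by autocorrelation.

    The normalized autocorrelation of the mean-removed, Hann-tapered
    window is scanned over lags in ``[T_min, T_max]``; candidate
    periods are
    local maxima, and the returned period is the smallest candidate
    scoring at least ``harmonic_guard`` times the in-range global
    maximum, so that a strong second harmonic cannot displace the
    fundamental. The peak lag is refined to sub-sample precision by
    quadratic interpolation through the peak and its two neighbours.

    This uses the entire waveform rather than detecting individual
    beats, which makes it robust to baseline wander that defeats peak
    detectors.

    Raises
    ------
    ValueError
        If the window is shorter than ``3 * T_max`` or no local maximum
        exists in the search range ("no periodicity detected").
    """
    if not (0 < T_min < T_max):
        raise ValueError("need 0 < T_min < T_max")
    if signal.duration < 3 * T_max:
        raise ValueError(
            f"window of {signal.duration:g} s too short; need >= 3*T_max = {3 * T_max:g} s"
        )
    n = len(signal)
    # Hann-tapered, taper-normalized autocorrelation via FFT. The
    # taper suppresses the incomplete-cycle edge ripple of a plain
    # finite-window estimator, and dividing by the taper's own
    # autocorrelation removes the overlap tilt; both effects would
    # otherwise bias the sub-sample peak position by a sizeable
    # fraction of a sample.
    w = hann(n, sym=False)
    x = w * (signal.samples - np.sum(w * signal.samples) / np.sum(w))
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[: n - 1]
    wspec = np.fft.rfft(w, nfft)
    wacf = np.fft.irfft(wspec * np.conj(wspec), nfft)[: n - 1]
    # Taper overlap sinks below FFT round-off at the last few lags;
    # those lags are far outside any usable search range.
    floor = 1e-12 * wacf[0]
    acf = np.where(wacf > floor, acf / np.maximum(wacf, floor), 0.0)
    n = acf.size
    if acf[0] <= 0:
        raise ValueError("no periodicity detected: constant window")
    acf = acf / acf[0]

    lag_min = max(int(np.ceil(T_min * signal.fs)), 1)
    lag_max = min(int(np.floor(T_max * signal.fs)), n - 2)
    if lag_max <= lag_min:
        raise ValueError("search range too narrow for this sampling rate")

    (peaks,) = argrelmax(acf[lag_min - 1 : lag_max + 2])
    peaks = peaks + lag_min - 1
    peaks = peaks[(peaks >= lag_min) & (peaks <= lag_max)]
    if peaks.size == 0:
        raise ValueError(
            f"no periodicity detected in [{T_min:g}, {T_max:g}] s"
        )
    best = acf[peaks].max()
    lag = int(peaks[acf[peaks] >= harmonic_guard * best][0])

    lag_f, peak_val = _refine_peak(acf, lag)
    score = float(min(peak_val, 1.0))

    # Multi-period refinement: the peak near m*T estimates m*T with the
    # same absolute lag error as the fundamental, so dividing by the
    # largest usable multiple m shrinks the period error by m. Accept a
    # multiple only while its peak stays comparable to the fundamental
    # (strong jitter washes long-lag peaks out, in which case the
    # fundamental estimate stands).
    m_max = min(int(0.6 * n / lag), 8)
    for m in range(m_max, 1, -1):
        center = int(round(m * lag_f))
        half = max(int(round(0.2 * lag)), 2)
        lo, hi = center - half, center + half
        if lo < 1 or hi > n - 2:
            continue
        j = lo + int(np.argmax(acf[lo : hi + 1]))
        if j in (lo, hi) or acf[j] < 0.5 * peak_val:
            continue
        lag_m, _ = _refine_peak(acf, j)
        lag_f = lag_m / m
        break
    T = lag_f / signal.fs
    return CycleEstimate(T=float(T), score=score, search_range=(T_min, T_max))


def _refine_peak(acf: np.ndarray, lag: int) -> Tuple[float, float]:
    """Sub-sample peak location and height by 3-point quadratic fit."""
    r0, r1, r2 = acf[lag - 1], acf[lag], acf[lag + 1]
    denom = r0 - 2 * r1 + r2
    delta = 0.5 * (r0 - r2) / denom if denom != 0 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    return lag + delta, float(r1 - 0.25 * (r0 - r2) * delta)


def heart_rate_from_cycle(T: float) -> float:
    """Heart rate in bpm: 60 seconds divided by the average cycle length."""
    if not T > 0:
        raise ValueError("cycle length must be > 0")
    return 60.0 / T


def bpm_from_beat_count(n_beats: float, duration_s: float) -> float:
    """Heart rate implied by counting beats over a window (manual method).

    E.g. 22.5 beats counted in a 2 s window is 675 bpm. Provided for
    cross-checking the autocorrelation estimate against manual counts.
    """
    if not duration_s > 0:
        raise ValueError("duration must be > 0")
    if n_beats < 0:
        raise ValueError("beat count must be >= 0")
    return 60.0 * n_beats / duration_s


def delay_embed(signal: Signal, tau: float) -> Trajectory3:
    """Build the 3-D delay-coordinate trajectory with delay ``tau``.

    For every sample time ``t_k >= t0 + 2*tau`` the triple
    ``(x(t_k), x(t_k - tau), x(t_k - 2*tau))`` is emitted; delayed
    values that fall between samples are obtained by linear
    interpolation (exact on locally linear segments, error bounded by
    curvature times the squared sample spacing).
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if signal.duration <= 2 * tau:
        raise ValueError(
            f"tau={tau:g} s too large for a {signal.duration:g} s signal"
        )
    n = len(signal)
    k0 = int(np.ceil(2 * tau * signal.fs - 1e-9))
    idx = np.arange(k0, n, dtype=float)
    x = signal.samples[k0:]
    y = np.interp(idx - tau * signal.fs, np.arange(n), signal.samples)
    z = np.interp(idx - 2 * tau * signal.fs, np.arange(n), signal.samples)
    return Trajectory3(x=x, y=y, z=z, tau=float(tau), fs=signal.fs)


def project_uvw(traj: Trajectory3) -> UVWSeries:
    """Rotate a trajectory into the baseline/morphology frame.

    u lies along the (1,1,1) diagonal; (v, w) span the orthogonal
    plane. The basis is orthonormal, so for every point
    ``u^2 + v^2 + w^2 = x^2 + y^2 + z^2``.
    """
    x, y, z = traj.x, traj.y, traj.z
    u = (x + y + z) / SQRT3
    v = (x + y - 2 * z) / SQRT6
    w = (x - y) / SQRT2
    return UVWSeries(u=u, v=v, w=w, tau=traj.tau, fs=traj.fs)
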