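"""Parametric in-silico pulse-train generator.

Emulates arterial-pressure-like waveforms with controllable morphology:
each beat rises from baseline to its peak over a fraction ``alpha`` of
the beat period along a half-cosine ramp, then decays back along a
power law ``(1 - s)**kappa`` in the normalized downstroke phase ``s``
(``kappa = 1`` is a straight downstroke; larger values make it more
concave, as seen in vivo when peripheral resistance and compliance
fall). Per-beat period, amplitude and upstroke-fraction jitter model
beat-to-beat physiological variability; a slow sinusoid plus linear
drift model baseline wander; white noise models the measurement chain.

Every realized per-beat parameter is stored in the returned signal's
``meta["beats"]`` table so that downstream estimators can be tested
against exact ground truth.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Signal

__all__ = ["PulseModelParams", "generate_pulse_train", "add_baseline_wander"]

#: Per-beat jitters are Gaussian truncated at this many standard deviations.
JITTER_TRUNCATION_SD = 4.0


@dataclass(frozen=True)
class PulseModelParams:
    """Parameters of the synthetic pulse-train model.

    Parameters
    ----------
    T : float
        Mean beat period in seconds.
    A : float
        Mean pulse amplitude (peak minus baseline), signal units.
    alpha : float
        Upstroke fraction of the beat, in (0, 1). The systolic rise
        occupies ``alpha * T_i`` of beat ``i``.
    kappa : float
        Downstroke concavity exponent, >= 1. 1 gives a straight
        (linear) decay; larger values give a more concave downstroke.
    sigma_T, sigma_A, sigma_alpha : float
        Relative standard deviations of per-beat period, amplitude and
        upstroke-fraction jitter (i.i.d. truncated Gaussian).
    wander_amp, wander_freq : float
        Amplitude (signal units) and frequency (Hz) of sinusoidal
        baseline wander.
    drift_rate : float
        Linear baseline drift in units per second.
    noise_sd : float
        Standard deviation of additive white measurement noise.
    offset : float
        Baseline (diastolic) level, signal units.
    seed : int
        RNG seed; generation is fully deterministic given the seed.
    """

    T: float = 1.0
    A: float = 40.0
    alpha: float = 0.2
    kappa: float = 1.0
    sigma_T: float = 0.0
    sigma_A: float = 0.0
    sigma_alpha: float = 0.0
    wander_amp: float = 0.0
    wander_freq: float = 0.0
    drift_rate: float = 0.0
    noise_sd: float = 0.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("T must be > 0")
        if not self.A > 0:
            raise ValueError("A must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        for name in ("sigma_T", "sigma_A", "sigma_alpha", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _truncated_normal(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Zero-mean Gaussian draws clipped at +/- JITTER_TRUNCATION_SD sigmas."""
    z = rng.standard_normal(n)
    np.clip(z, -JITTER_TRUNCATION_SD, JITTER_TRUNCATION_SD, out=z)
    return z * sd


def generate_pulse_train(
    params: PulseModelParams, duration_s: float, fs: float
) -> Signal:
    """Synthesize a pulse train of ``duration_s`` seconds at ``fs`` Hz.

    Beat ``i`` occupies the half-open interval ``[t_i, t_i + T_i)``:
    a half-cosine rise from ``offset`` to ``offset + A_i`` over
    ``alpha_i * T_i`` seconds followed by the power-law fall
    ``offset + A_i * (1 - s)**kappa`` with ``s`` the normalized
    downstroke phase. Baseline wander, drift and noise are added on top.

    The realized per-beat parameters are available as a DataFrame in
    ``signal.meta["beats"]`` with columns ``t_start, T, A, alpha``.

    Raises
    ------
    ValueError
        If ``duration_s < 3 T`` (too few beats) or ``fs * T < 20``
        (fewer than 20 samples per beat).
    """
    if duration_s < 3 * params.T:
        raise ValueError(f"duration_s must be >= 3*T = {3 * params.T:g} s")
    if fs * params.T < 20:
        raise ValueError(f"need fs*T >= 20 samples per beat, got {fs * params.T:g}")

    rng = np.random.default_rng(params.seed)

    # Draw beats until they cover the record. Relative jitters are
    # additionally clamped so every realized beat is physical.
    n_beats = int(np.ceil(duration_s / params.T * (1 + 5 * params.sigma_T))) + 3
    T_i = params.T * (1 + _truncated_normal(rng, n_beats, params.sigma_T))
    A_i = params.A * (1 + _truncated_normal(rng, n_beats, params.sigma_A))
    alpha_i = params.alpha * (1 + _truncated_normal(rng, n_beats, params.sigma_alpha))
    T_i = np.maximum(T_i, 0.05 * params.T)
    A_i = np.maximum(A_i, 0.05 * params.A)
    np.clip(alpha_i, 0.02, 0.98, out=alpha_i)

    starts = np.concatenate(([0.0], np.cumsum(T_i)))
    while starts[-1] < duration_s:  # pragma: no cover - generous pre-draw
        extra = params.T * (1 + _truncated_normal(rng, 8, params.sigma_T))
        extra = np.maximum(extra, 0.05 * params.T)
        T_i = np.concatenate((T_i, extra))
        A_i = np.concatenate((A_i, params.A * np.ones(8)))
        alpha_i = np.concatenate((alpha_i, params.alpha * np.ones(8)))
        starts = np.concatenate(([0.0], np.cumsum(T_i)))

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    beat = np.searchsorted(starts, t, side="right") - 1
    phase = t - starts[beat]
    Tb, Ab, ab = T_i[beat], A_i[beat], alpha_i[beat]

    rise_dur = ab * Tb
    x = np.empty(n)
    rising = phase < rise_dur
    x[rising] = 0.5 * (1 - np.cos(np.pi * phase[rising] / rise_dur[rising]))
    s = (phase[~rising] - rise_dur[~rising]) / ((1 - ab[~rising]) * Tb[~rising])
    x[~rising] = (1 - s) ** params.kappa
    x = params.offset + Ab * x

    if params.wander_amp != 0.0 and params.wander_freq != 0.0:
        x = x + params.wander_amp * np.sin(2 * np.pi * params.wander_freq * t)
    if params.drift_rate != 0.0:
        x = x + params.drift_rate * t
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=n)

    used = slice(0, int(beat.max()) + 1)
    beats = pd.DataFrame(
        {"t_start": starts[:-1][used], "T": T_i[used], "A": A_i[used], "alpha": alpha_i[used]}
    )
    return Signal(
        samples=x,
        fs=float(fs),
        units="a.u.",
        meta={"beats": beats, "params": dataclasses.asdict(params)},
    )


def add_baseline_wander(
    signal: Signal, wander_amp: float, wander_freq: float, drift_rate: float = 0.0
) -> Signal:
    """Add sinusoidal wander plus linear drift to an existing signal.

    Returns ``x(t) + wander_amp * sin(2*pi*wander_freq*t) + drift_rate*t``
    with length and sampling rate unchanged. Wander is meant to be slow
    relative to the pulse; a warning is issued if ``wander_freq``
    exceeds half the apparent pulse rate recorded by the generator.
    """
    beats = signal.meta.get("beats")
    if beats is not None and len(beats):
        T = float(beats["T"].mean())
        if wander_freq > 0.5 / T:
            warnings.warn(
                f"wander_freq={wander_freq:g} Hz is not slow relative to the "
                f"pulse period {T:g} s; baseline invariance may degrade",
                stacklevel=2,
            )
    t = signal.times - signal.t0
    wander = wander_amp * np.sin(2 * np.pi * wander_freq * t) + drift_rate * t
    return dataclasses.replace(signal, samples=signal.samples + wander)
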