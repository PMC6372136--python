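"""Analysis configuration and species presets."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .embedding import HARMONIC_GUARD, TAU_FRACTION

__all__ = ["AnalysisConfig", "SPECIES_PRESETS"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the attractor pipeline.

    Parameters
    ----------
    T_min, T_max : float
        Cycle-length search range in seconds. The defaults cover human
        heart rates (30-300 bpm); use the ``mouse`` preset (300-800
        bpm) for rodent recordings.
    tau_fraction : float
        Embedding delay as a fraction of the estimated cycle length.
        1/3 yields the three-fold symmetric triangular attractor all
        downstream features assume.
    harmonic_guard : float
        Fraction of the in-range autocorrelation maximum a shorter-lag
        local maximum must reach to be accepted as the fundamental.
    window_s, step_s : float
        Default sliding-window length and hop for tracking.
    grid_n : int
        Density-grid resolution (cells per axis).
    fixed_extent : float or None
        If set, every window's density grid spans ``[-B, B]^2`` with
        this B, making densities comparable across windows; otherwise
        the extent auto-scales per window (and is recorded in output).
    """

    T_min: float = 60.0 / 300.0
    T_max: float = 60.0 / 30.0
    tau_fraction: float = TAU_FRACTION
    harmonic_guard: float = HARMONIC_GUARD
    window_s: float = 10.0
    step_s: float = 5.0
    grid_n: int = 128
    fixed_extent: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.T_min < self.T_max):
            raise ValueError("need 0 < T_min < T_max")
        if not (0 < self.tau_fraction < 1):
            raise ValueError("tau_fraction must lie in (0, 1)")

    @classmethod
    def for_species(cls, species: str, **overrides) -> "AnalysisConfig":
        """Preset search range and window length for a species."""
        try:
            preset = SPECIES_PRESETS[species.lower()]
        except KeyError:
            raise ValueError(
                f"unknown species {species!r}; choose from {sorted(SPECIES_PRESETS)}"
            ) from None
        return replace(cls(**preset), **overrides)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        species = data.pop("species", None)
        if species:
            return cls.for_species(species, **data)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


SPECIES_PRESETS = {
    # Human resting-to-exercise heart rates, 10 s windows.
    "human": dict(T_min=60.0 / 300.0, T_max=60.0 / 30.0, window_s=10.0, step_s=5.0),
    # Mouse heart rates around 300-800 bpm, 2 s windows.
    "mouse": dict(T_min=60.0 / 800.0, T_max=60.0 / 300.0, window_s=2.0, step_s=1.0),
}
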