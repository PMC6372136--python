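"""Model/Results interface over the attractor pipeline.

:class:`AttractorModel` bundles a waveform with an artifact mask,
window geometry and analysis configuration; :meth:`AttractorModel.fit`
runs the sliding-window pipeline and returns an
:class:`AttractorResults` carrying the per-window feature table,
summary statistics and plotting helpers. For a quick single-window
analysis pass ``window=None``: the whole record becomes one window.

Example
-------
>>> from pulseattractor import PulseModelParams, generate_pulse_train
>>> from pulseattractor.model import AttractorModel
>>> sig = generate_pulse_train(PulseModelParams(T=1.0, A=40.0), 60.0, 250.0)
>>> res = AttractorModel(sig).fit()
>>> res.features.shape[0]
11
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .embedding import delay_embed, estimate_cycle_length, project_uvw
from .features import DensityGrid, UVWSeries, density2d
from .io import ArtifactMask, Signal, WindowSpec, read_signal
from .tracking import track

__all__ = ["AttractorModel", "AttractorResults"]


class AttractorModel:
    """Attractor-reconstruction analysis of one waveform record.

    Parameters
    ----------
    signal : Signal
        The uniformly sampled waveform to analyse.
    mask : ArtifactMask, optional
        Time intervals of non-physiological artifact to exclude.
    window : WindowSpec, optional
        Sliding-window geometry; defaults to the config's
        ``window_s`` / ``step_s`` (10 s / 5 s for human presets).
    config : AnalysisConfig, optional
        Cycle-search range, embedding and density parameters.
    """

    def __init__(
        self,
        signal: Signal,
        mask: Optional[ArtifactMask] = None,
        window: Optional[WindowSpec] = None,
        config: Optional[AnalysisConfig] = None,
    ) -> None:
        self.signal = signal
        self.mask = mask or ArtifactMask()
        self.config = config or AnalysisConfig()
        self.window = window or WindowSpec(
            length_s=min(self.config.window_s, signal.duration),
            step_s=min(self.config.step_s, signal.duration),
        )

    @classmethod
    def from_csv(
        cls,
        path,
        fs: Optional[float] = None,
        column: Optional[Union[str, int]] = None,
        species: Optional[str] = None,
        mask: Optional[ArtifactMask] = None,
        window: Optional[WindowSpec] = None,
        **config_overrides,
    ) -> "AttractorModel":
        """Build a model straight from a delimited-text waveform file."""
        signal = read_signal(path, fs=fs, column=column)
        if species is not None:
            config = AnalysisConfig.for_species(species, **config_overrides)
        else:
            config = AnalysisConfig(**config_overrides)
        return cls(signal, mask=mask, window=window, config=config)

    def fit(self) -> "AttractorResults":
        """Run the sliding-window pipeline; returns the results object."""
        features = track(self.signal, self.mask, self.window, self.config)
        return AttractorResults(self, features)


class AttractorResults:
    """Fitted feature series plus diagnostics for one record.

    Attributes
    ----------
    features : pandas.DataFrame
        One row per window (see ``tracking.FEATURE_COLUMNS``).
    model : AttractorModel
        The model this was fitted from.
    """

    def __init__(self, model: AttractorModel, features: pd.DataFrame) -> None:
        self.model = model
        self.features = features

    # -- access helpers -------------------------------------------------

    @property
    def n_windows(self) -> int:
        return len(self.features)

    @property
    def ok(self) -> pd.DataFrame:
        """The subset of windows whose pipeline succeeded."""
        return self.features[self.features["flag"] == "ok"]

    def window_signal(self, index: int) -> Signal:
        """The raw samples of window ``index``."""
        row = self.features.iloc[index]
        return self.model.signal.slice_seconds(
            row["window_start_s"], row["window_end_s"]
        )

    def window_uvw(self, index: int) -> UVWSeries:
        """Re-embed window ``index`` and return its (u, v, w) series."""
        window = self.window_signal(index)
        cfg = self.model.config
        est = estimate_cycle_length(window, cfg.T_min, cfg.T_max, cfg.harmonic_guard)
        return project_uvw(delay_embed(window, cfg.tau_fraction * est.T))

    def window_density(self, index: int) -> DensityGrid:
        """The normalized (v, w) density grid of window ``index``."""
        cfg = self.model.config
        return density2d(self.window_uvw(index), n=cfg.grid_n, B=cfg.fixed_extent)

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary across windows, statsmodels-style."""
        ok = self.ok
        sig = self.model.signal
        lines = [
            "Attractor reconstruction results",
            "=" * 58,
            f"record duration      {sig.duration:10.1f} s   fs {sig.fs:g} Hz",
            f"windows              {self.n_windows:10d}   "
            f"({self.n_windows - len(ok)} flagged)",
            f"window / step        {self.model.window.length_s:10.1f} / "
            f"{self.model.window.step_s:g} s",
            "-" * 58,
            f"{'feature':<16}{'mean':>12}{'sd':>12}{'units':>16}",
            "-" * 58,
        ]
        units = {
            "HR_bpm": "bpm",
            "size": sig.units,
            "rotation_deg": "deg",
            "arm1_width": sig.units,
            "arm2_width": sig.units,
            "arm3_width": sig.units,
            "periodicity": "-",
            "u_mean": sig.units,
            "u_trend": f"{sig.units}/s",
        }
        for col, unit in units.items():
            vals = ok[col].to_numpy(float)
            if len(vals) == 0 or np.isnan(vals).all():
                lines.append(f"{col:<16}{'-':>12}{'-':>12}{unit:>16}")
            else:
                lines.append(
                    f"{col:<16}{np.nanmean(vals):12.4g}"
                    f"{np.nanstd(vals):12.3g}{unit:>16}"
                )
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Write the feature table as CSV (one row per window)."""
        self.features.to_csv(path, index=False, float_format="%.10g")

    # -- plotting --------------------------------------------------------

    def plot_attractor(self, index: int = 0, ax=None, cmap: str = "inferno"):
        """Render window ``index``'s (v, w) density as an image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        den = self.window_density(index)
        B = den.extent
        ax.imshow(
            den.rho.T,
            origin="lower",
            extent=(-B, B, -B, B),
            cmap=cmap,
            interpolation="nearest",
        )
        ax.set_xlabel(f"v [{self.model.signal.units}]")
        ax.set_ylabel(f"w [{self.model.signal.units}]")
        ax.set_title(f"window {index}")
        return ax

    def plot_features(self, columns=("HR_bpm", "size", "rotation_deg", "periodicity")):
        """Feature trajectories against window start time."""
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(
            len(columns), 1, sharex=True, figsize=(8, 2 * len(columns))
        )
        axes = np.atleast_1d(axes)
        t = self.features["window_start_s"]
        for ax, col in zip(axes, columns):
            ax.plot(t, self.features[col], marker=".")
            ax.set_ylabel(col)
        axes[-1].set_xlabel("window start [s]")
        fig.tight_layout()
        return fig
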