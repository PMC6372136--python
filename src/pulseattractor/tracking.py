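"""Sliding-window feature tracking over long records.

A long recording is split into its unmasked segments, each segment is
covered by a sliding window, and every window is pushed through the
full pipeline: cycle-length estimation, delay embedding at
tau = tau_fraction * T, projection into the morphology plane, and the
complete feature bundle. Windows where no periodicity can be detected
are emitted with a failure flag rather than dropped, so the output row
count is always predictable from the window-count formula.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .embedding import delay_embed, estimate_cycle_length, project_uvw
from .features import MIN_POINTS_ARMS, compute_features
from .io import ArtifactMask, Signal, WindowSpec, apply_mask

__all__ = ["FEATURE_COLUMNS", "track", "window_features"]

logger = logging.getLogger(__name__)

#: Output columns, in order. Units: seconds for T and window bounds,
#: bpm for HR, signal units for size / widths / u_mean, degrees for
#: rotation, units/s for u_trend; edge CVs and periodicity are
#: dimensionless.
FEATURE_COLUMNS = [
    "window_start_s",
    "window_end_s",
    "T_s",
    "HR_bpm",
    "size",
    "rotation_deg",
    "arm1_width",
    "arm2_width",
    "arm3_width",
    "edge_cv1",
    "edge_cv2",
    "edge_cv3",
    "periodicity",
    "u_mean",
    "u_trend",
    "flag",
]


def window_features(window: Signal, config: AnalysisConfig):
    """Run the full pipeline on one window; returns (features, flag)."""
    try:
        est = estimate_cycle_length(
            window, config.T_min, config.T_max, config.harmonic_guard
        )
    except ValueError as exc:
        logger.info("cycle estimation failed at t=%.3f s: %s", window.t0, exc)
        return None, "no_cycle"
    tau = config.tau_fraction * est.T
    try:
        uvw = project_uvw(delay_embed(window, tau))
        if len(uvw) < MIN_POINTS_ARMS:
            return None, "too_few_points"
        feats = compute_features(
            uvw, est.T, n=config.grid_n, B=config.fixed_extent
        )
    except ValueError as exc:
        logger.info("feature extraction failed at t=%.3f s: %s", window.t0, exc)
        return None, "degenerate"
    return feats, "ok"


def track(
    signal: Signal,
    mask: Optional[ArtifactMask] = None,
    spec: Optional[WindowSpec] = None,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Track attractor features through a record with a moving window.

    Every window lying fully inside an unmasked segment produces one
    row; windows straddling a masked artifact are never formed because
    each segment is windowed independently. Per segment the number of
    rows is ``floor((segment_duration - length_s)/step_s) + 1``.

    Returns a DataFrame with :data:`FEATURE_COLUMNS`; rows where the
    pipeline failed carry NaN features and a non-``"ok"`` flag.

    Raises
    ------
    ValueError
        If the window is shorter than 3 * T_max of the configured
        search range, or longer than every unmasked segment.
    """
    config = config or AnalysisConfig()
    spec = spec or WindowSpec(length_s=config.window_s, step_s=config.step_s)
    if spec.length_s < 3 * config.T_max:
        raise ValueError(
            f"window of {spec.length_s:g} s cannot hold 3 cycles of "
            f"T_max = {config.T_max:g} s; shorten T_max or lengthen the window"
        )
    segments = apply_mask(signal, mask or ArtifactMask())
    if not segments or all(seg.duration < spec.length_s for seg in segments):
        raise ValueError(
            f"no unmasked segment is at least one window ({spec.length_s:g} s) long"
        )

    rows = []
    for seg in segments:
        for k in range(spec.count(seg.duration)):
            start = seg.t0 + k * spec.step_s
            end = start + spec.length_s
            window = seg.slice_seconds(start, end)
            feats, flag = window_features(window, config)
            if feats is None:
                rows.append(
                    dict.fromkeys(FEATURE_COLUMNS[2:-1], np.nan)
                    | {"window_start_s": start, "window_end_s": end, "flag": flag}
                )
            else:
                rows.append(
                    {
                        "window_start_s": start,
                        "window_end_s": end,
                        "T_s": feats.T,
                        "HR_bpm": feats.HR,
                        "size": feats.size,
                        "rotation_deg": feats.rotation,
                        "arm1_width": feats.arm_widths[0],
                        "arm2_width": feats.arm_widths[1],
                        "arm3_width": feats.arm_widths[2],
                        "edge_cv1": feats.edge_uniformity[0],
                        "edge_cv2": feats.edge_uniformity[1],
                        "edge_cv3": feats.edge_uniformity[2],
                        "periodicity": feats.periodicity,
                        "u_mean": feats.u_mean,
                        "u_trend": feats.u_trend,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
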