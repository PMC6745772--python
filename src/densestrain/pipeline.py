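"""End-to-end analysis: phase series + contours -> sector strain map + summary."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnatomicalContext, DensePhaseSeries, WallSegmentation
from .metrics import StrainSummary, summarize
from .smoothing import SmoothingConfig, spatial_smooth, temporal_smooth_positions
from .strain import SectorStrainMap, compute_strain_map
from .tracking import BackDisplacementField, TrajectoryField, decode_series, track_forward


@dataclass
class AnalysisResult:
    """Everything the pipeline produces for one scanned cross-section."""

    strain_map: SectorStrainMap
    summary: StrainSummary
    trajectories: TrajectoryField
    back_field: BackDisplacementField
    smoothing: SmoothingConfig


def reconstruct_trajectories(
    series: DensePhaseSeries,
    seg: WallSegmentation,
    smoothing: SmoothingConfig,
) -> tuple[TrajectoryField, BackDisplacementField]:
    """Decode, smooth and track: wrapped phases -> wall voxel trajectories."""
    back = decode_series(series, seg)
    back = spatial_smooth(back, smoothing.spatial_radius)
    traj = track_forward(back)
    traj = temporal_smooth_positions(traj, smoothing.temporal_window)
    return traj, back


def analyze(
    series: DensePhaseSeries,
    seg: WallSegmentation,
    ctx: AnatomicalContext,
    smoothing: SmoothingConfig | None = None,
) -> AnalysisResult:
    """Run the full strain analysis of one DENSE cross-section.

    Stages: masked phase unwrapping and displacement decoding per frame,
    spatial smoothing of the displacement vectors, forward tracking of the
    frame-1 wall voxels, temporal smoothing of the tracked positions,
    sector-wise Green strain via quadrilateral elements rotated to
    radial-circumferential axes, fifth-order polynomial time-smoothing,
    and the scalar summary (local systole, NCS, heterogeneity index, mean
    displacement angle, diastolic geometry).
    """
    if smoothing is None:
        smoothing = SmoothingConfig.for_location(ctx.location)
    traj, back = reconstruct_trajectories(series, seg, smoothing)
    smap = compute_strain_map(traj, seg, ctx)
    smap.frame_interval_ms = series.enc.frame_interval_ms
    summary = summarize(smap, traj, seg, ctx)
    return AnalysisResult(
        strain_map=smap,
        summary=summary,
        trajectories=traj,
        back_field=back,
        smoothing=smoothing,
    )
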