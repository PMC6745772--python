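"""Noise-reduction operators for thin-wall displacement data.

Three linear smoothers are applied at fixed points of the pipeline:

1. spatial averaging of the per-frame back-displacement vectors over the
   wall mask (radius 1 voxel-space by default, 2 for the infrarenal
   abdominal aorta, where signal is poorest);
2. a centred moving average of the tracked positions in time; and
3. an ordinary-least-squares fifth-order polynomial fit of each sector's
   circumferential strain time-course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy import ndimage

from .errors import ConfigurationError
from .tracking import BackDisplacementField, TrajectoryField

STRAIN_POLY_ORDER = 5


@dataclass(frozen=True)
class SmoothingConfig:
    """Noise-reduction settings.

    ``spatial_radius`` is in voxel-spaces (Chebyshev metric) and must be 1
    or 2 — 2 is the default for IAA scans; ``temporal_window`` is an odd
    moving-average width in frames; the strain polynomial order is fixed
    at 5 and requires more than 6 frames.
    """

    spatial_radius: int = 1
    temporal_window: int = 3
    strain_poly_order: int = STRAIN_POLY_ORDER

    def __post_init__(self) -> None:
        if self.spatial_radius not in (1, 2):
            raise ConfigurationError(
                f"spatial_radius must be 1 or 2 voxel-spaces, got {self.spatial_radius}"
            )
        if self.temporal_window < 1 or self.temporal_window % 2 == 0:
            raise ConfigurationError(
                f"temporal_window must be odd and >= 1, got {self.temporal_window}"
            )
        if self.strain_poly_order != STRAIN_POLY_ORDER:
            raise ConfigurationError(
                f"strain_poly_order is fixed at {STRAIN_POLY_ORDER}"
            )

    @classmethod
    def for_location(cls, location: str, **overrides) -> "SmoothingConfig":
        """Default config for an aortic location (radius 2 for IAA, else 1)."""
        overrides.setdefault("spatial_radius", 2 if location == "IAA" else 1)
        return cls(**overrides)


def spatial_smooth(back: BackDisplacementField, radius: int) -> BackDisplacementField:
    """Average each wall voxel's displacement over its masked neighbourhood.

    Every wall voxel's vector is replaced by the unweighted mean of all
    wall voxels within Chebyshev distance ``radius`` (itself included);
    voxels outside the wall mask never enter the average, so an isolated
    voxel simply averages with itself.
    """
    if radius not in (1, 2):
        raise ConfigurationError(f"radius must be 1 or 2 voxel-spaces, got {radius}")
    size = 2 * radius + 1
    out = np.full_like(back.d, np.nan)
    for t in range(back.n_frames):
        m = back.mask[t].astype(float)
        # counts are integers; rounding removes uniform_filter float residue
        count = np.round(ndimage.uniform_filter(m, size=size, mode="constant") * size**2)
        for c in range(2):
            vals = np.where(back.mask[t], back.d[t, :, :, c], 0.0)
            acc = ndimage.uniform_filter(vals, size=size, mode="constant") * size**2
            with np.errstate(invalid="ignore", divide="ignore"):
                sm = acc / count
            out[t, :, :, c] = np.where(back.mask[t], sm, np.nan)
    return BackDisplacementField(d=out, mask=back.mask.copy(), voxel_size=back.voxel_size)


def temporal_smooth_positions(traj: TrajectoryField, window: int) -> TrajectoryField:
    """Centred moving average of tracked positions along the frame axis.

    The window is truncated at the first and last frames (no padding —
    fabricating pre-trigger data would bias displacements near frame 1)
    and the result re-anchored so that ``u_1 = 0`` exactly: the frame-1
    smoothed offset is subtracted from frame 1, pinning it back to the
    measured reference positions.  (Subtracting that offset from *every*
    frame would instead shift the whole trajectory by half the frame-2
    displacement — a systematic underestimate of all later displacements —
    because the truncated edge average at frame 1 leans on frame 2.)
    """
    if window % 2 == 0 or window < 1:
        raise ConfigurationError(f"temporal window must be odd and >= 1, got {window}")
    if window > traj.n_frames:
        raise ConfigurationError(
            f"temporal window {window} exceeds frame count {traj.n_frames}"
        )
    if window == 1:
        return TrajectoryField(X=traj.X.copy(), voxel_size=traj.voxel_size)
    hw = window // 2
    n_t = traj.n_frames
    sm = np.empty_like(traj.X)
    for t in range(n_t):
        lo, hi = max(0, t - hw), min(n_t, t + hw + 1)
        sm[t] = traj.X[lo:hi].mean(axis=0)
    sm[0] = traj.X[0]
    return TrajectoryField(X=sm, voxel_size=traj.voxel_size)


def polynomial_smooth_strain(
    strain_series: np.ndarray, order: int = STRAIN_POLY_ORDER
) -> np.ndarray:
    """Least-squares degree-``order`` polynomial fit of strain time-courses.

    ``strain_series`` is ``(..., N_t)``; each row is replaced by its fitted
    values.  Rows containing NaN (invalid sectors) stay all-NaN.  Requires
    ``N_t >= order + 2`` (an interpolating fit would smooth nothing).
    """
    s = np.asarray(strain_series, dtype=float)
    n_t = s.shape[-1]
    if n_t < order + 2:
        raise ConfigurationError(
            f"polynomial smoothing of order {order} needs at least {order + 2} "
            f"frames, got {n_t}"
        )
    flat = s.reshape(-1, n_t)
    out = np.full_like(flat, np.nan)
    t = np.arange(1, n_t + 1, dtype=float)
    for i, row in enumerate(flat):
        if np.isnan(row).any():
            continue
        out[i] = Polynomial.fit(t, row, order)(t)
    return out.reshape(s.shape)
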