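"""Phase unwrapping, displacement decoding and Lagrangian forward tracking.

The DENSE observable stores, at each voxel *observed* inside the wall at
frame ``t``, the wrapped phase of the displacement of the tissue currently
occupying that voxel, measured from the reference configuration at the time
of encoding (frame 1):

    d_{i,t} = phi_{i,t} / (2*pi*ke_i),   i = x, y,

with ``phi`` the *unwrapped* phase.  These are "back" displacement vectors:
they point from an unknown reference origin to the observed voxel.  Forward
trajectories of the frame-1 wall voxels are reconstructed by back-projecting
every observation to its implied reference origin and interpolating among
the three closest origins.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .core import TWO_PI, DensePhaseSeries, EncodingParams, WallSegmentation, voxel_centers
from .errors import ConfigurationError, TrackingError, UnwrapError

logger = logging.getLogger(__name__)

# 4-connectivity for both component labelling and the flood fill
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

EXACT_HIT_TOL = 1e-9  # mm; back-projected origin coinciding with a reference voxel


def unwrap_masked(
    wrapped: np.ndarray,
    mask: np.ndarray,
    quality: np.ndarray | None = None,
    anchor: float | None = None,
) -> np.ndarray:
    """Quality-guided 2D phase unwrapping restricted to ``mask``.

    A flood fill grows from the highest-quality masked pixel (ties broken
    by row-major scan order), always expanding the highest-quality frontier
    pixel next and adding the multiple of 2*pi that removes any neighbour
    jump exceeding pi.  Each connected component (4-connectivity) is
    unwrapped independently; more than one component triggers a logged
    warning.  The seed keeps its wrapped value, leaving a per-component
    global offset ambiguity of a multiple of 2*pi; if ``anchor`` is given,
    each component is shifted by the multiple of 2*pi bringing its mean
    closest to ``anchor``.

    Returns the unwrapped phase with NaN outside the mask.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UnwrapError("wall mask is empty; nothing to unwrap")
    if quality is None:
        quality = np.ones_like(wrapped)
    out = np.full(wrapped.shape, np.nan)
    labels, n_comp = ndimage.label(mask, structure=_STRUCT4)
    if n_comp > 1:
        logger.warning(
            "wall mask has %d connected components; unwrapping each independently",
            n_comp,
        )
    h, w = wrapped.shape
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        q = np.where(comp_mask, quality, -np.inf)
        seed = np.unravel_index(int(np.argmax(q)), q.shape)
        done = np.zeros_like(mask)
        out[seed] = wrapped[seed]
        done[seed] = True
        counter = 0
        heap = [(-q[seed], counter, seed)]
        while heap:
            _, _, (i, j) = heapq.heappop(heap)
            for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if 0 <= ni < h and 0 <= nj < w and comp_mask[ni, nj] and not done[ni, nj]:
                    jump = wrapped[ni, nj] - out[i, j]
                    out[ni, nj] = wrapped[ni, nj] - TWO_PI * np.round(jump / TWO_PI)
                    done[ni, nj] = True
                    counter += 1
                    heapq.heappush(heap, (-q[ni, nj], counter, (ni, nj)))
        if anchor is not None:
            shift = TWO_PI * np.round((np.nanmean(out[comp_mask]) - anchor) / TWO_PI)
            out[comp_mask] -= shift
    return out


def unwrap_phase(
    series: DensePhaseSeries,
    seg: WallSegmentation,
    t: int,
    anchor_x: float | None = None,
    anchor_y: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unwrap both phase channels of frame ``t`` (1-based) on the wall mask.

    The DENSE magnitude image serves as the unwrapping quality map.
    Returns ``(phi_x, phi_y, mask)`` with NaN outside the mask.
    """
    mask = seg.wall_mask(t, series.shape, series.enc.voxel_size)
    if not mask.any():
        raise UnwrapError(f"frame {t}: rasterized wall mask is empty")
    quality = series.magnitude[t - 1]
    phi_x = unwrap_masked(series.phase_x[t - 1], mask, quality, anchor_x)
    phi_y = unwrap_masked(series.phase_y[t - 1], mask, quality, anchor_y)
    return phi_x, phi_y, mask


@dataclass
class BackDisplacementField:
    """Per-frame back displacement vectors of wall voxels on the image lattice.

    ``d`` has shape ``(N_t, H, W, 2)`` in mm with NaN outside ``mask``;
    ``mask`` is the per-frame rasterized wall.
    """

    d: np.ndarray
    mask: np.ndarray
    voxel_size: float

    @property
    def n_frames(self) -> int:
        return self.d.shape[0]

    def entries(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Observed positions and displacement vectors at frame ``t`` (1-based),
        in row-major voxel scan order."""
        m = self.mask[t - 1]
        pos = voxel_centers(m.shape, self.voxel_size)[m]
        return pos, self.d[t - 1][m]


def decode_displacement(
    phi_x: np.ndarray, phi_y: np.ndarray, enc: EncodingParams
) -> np.ndarray:
    """Decode unwrapped phase to displacement in mm: ``d_i = phi_i/(2*pi*ke_i)``."""
    ke_x, ke_y = enc.ke
    if ke_x <= 0 or ke_y <= 0:
        raise ConfigurationError(f"ke must be positive, got {enc.ke}")
    return np.stack(
        [np.asarray(phi_x) / (TWO_PI * ke_x), np.asarray(phi_y) / (TWO_PI * ke_y)],
        axis=-1,
    )


def decode_series(
    series: DensePhaseSeries,
    seg: WallSegmentation,
    temporal_anchor: bool = True,
) -> BackDisplacementField:
    """Unwrap and decode every frame of a series into a back-displacement field.

    Spatial unwrapping fixes phase only up to a per-component multiple of
    2*pi.  With ``temporal_anchor`` (default) that global multiple is
    resolved by continuity in time: frame 1 is anchored at zero phase (it is
    the reference configuration, encoded immediately after the ECG trigger)
    and each later frame at the previous frame's mean unwrapped phase,
    which is valid because the bulk phase change between 32-ms frames is
    well below pi.
    """
    if seg.n_frames != series.n_frames:
        raise ConfigurationError(
            f"segmentation has {seg.n_frames} frames, series has {series.n_frames}"
        )
    n_t = series.n_frames
    h, w = series.shape
    d = np.full((n_t, h, w, 2), np.nan)
    masks = np.zeros((n_t, h, w), dtype=bool)
    anchor_x = anchor_y = 0.0 if temporal_anchor else None
    for t in range(1, n_t + 1):
        phi_x, phi_y, mask = unwrap_phase(series, seg, t, anchor_x, anchor_y)
        d[t - 1] = decode_displacement(phi_x, phi_y, series.enc)
        masks[t - 1] = mask
        if temporal_anchor:
            anchor_x = float(np.nanmean(phi_x))
            anchor_y = float(np.nanmean(phi_y))
    return BackDisplacementField(d=d, mask=masks, voxel_size=series.enc.voxel_size)


@dataclass
class TrajectoryField:
    """Forward-tracked positions of the frame-1 wall voxels.

    ``X`` has shape ``(N_t, N, 2)``: ``X[0]`` are the reference positions
    and ``u_t = X_t - X_1`` the forward displacements (``u_1 = 0`` by
    construction).
    """

    X: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3 or self.X.shape[2] != 2:
            raise ConfigurationError("X must have shape (N_t, N, 2)")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.X.shape[1]

    @property
    def ref(self) -> np.ndarray:
        return self.X[0]

    @property
    def u(self) -> np.ndarray:
        return self.X - self.X[0]


def interpolate_three_nearest(
    targets: np.ndarray, origins: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Inverse-distance-weighted interpolation over the 3 nearest origins.

    For each target point the three closest ``origins`` are found (ties in
    distance broken by entry scan order) and ``values`` combined with
    weights 1/distance.  An origin coinciding with the target within
    ``EXACT_HIT_TOL`` supplies its value alone.
    """
    dist = cdist(targets, origins)
    # stable sort keeps scan order among exactly tied distances
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :3]
    rows = np.arange(len(targets))[:, None]
    nd = dist[rows, nearest]
    exact = nd[:, 0] < EXACT_HIT_TOL
    with np.errstate(divide="ignore"):
        wgt = 1.0 / nd
    wgt[exact] = 0.0
    wgt[exact, 0] = 1.0
    wgt /= wgt.sum(axis=1, keepdims=True)
    return np.einsum("nk,nkj->nj", wgt, values[nearest])


def track_forward(back: BackDisplacementField) -> TrajectoryField:
    """Reconstruct forward trajectories of frame-1 wall voxels.

    Every frame-``t`` observation is back-projected to its implied
    reference origin (observed position minus its back displacement); the
    forward displacement of each reference voxel is interpolated from the
    three closest back-projected origins by inverse-distance weighting.
    Frame 1 is the reference: ``u_1 = 0`` exactly.
    """
    ref = back.entries(1)[0]
    if len(ref) == 0:
        raise TrackingError("frame 1: no wall voxels to track")
    n_t = back.n_frames
    X = np.empty((n_t, len(ref), 2))
    X[0] = ref
    for t in range(2, n_t + 1):
        pos, d = back.entries(t)
        if len(pos) < 3:
            raise TrackingError(
                f"frame {t}: need >= 3 back-displacement entries, got {len(pos)}"
            )
        origins = pos - d
        u_t = interpolate_three_nearest(ref, origins, d)
        X[t - 1] = ref + u_t
    return TrajectoryField(X=X, voxel_size=back.voxel_size)
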