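"""Core containers and geometry helpers shared across the pipeline.

Coordinate convention (fixed once, converted at I/O boundaries):

* Positions are in millimetres in the imaging plane.  Image arrays are
  indexed ``[frame, row, col]``; the centre of voxel ``(row, col)`` sits at
  ``x = (col + 0.5) * voxel_size``, ``y = (row + 0.5) * voxel_size``.
* ``x`` is the left-lateral axis and ``y`` the anterior axis of the
  standard transverse display, so a displacement angle of 0 deg points
  left-lateral and +90 deg anterior.
* Angles are measured counterclockwise from +x; "counterclockwise" always
  means increasing angle in this frame.
* Frames are 1-based in user-facing indices (frame 1 is the reference
  configuration at the time of displacement encoding); arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import ConfigurationError, GeometryError

TWO_PI = 2.0 * np.pi

LOCATIONS = ("IAA", "DTA", "DAA")


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to the interval (-pi, pi], mapping the boundary to +pi."""
    return np.pi - np.mod(np.pi - np.asarray(phi), TWO_PI)


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Alias for :func:`wrap_phase` when the argument is a geometric angle."""
    return wrap_phase(theta)


@dataclass(frozen=True)
class EncodingParams:
    """Displacement-encoding parameters of a cine DENSE acquisition.

    Parameters
    ----------
    ke :
        In-plane displacement encoding frequency in cycles/mm.  A scalar
        applies to both axes; a pair is ``(ke_x, ke_y)``.  Phase relates to
        displacement as ``phi_i = 2*pi*ke_i*d_i``.
    voxel_size :
        Isotropic in-plane voxel dimension in mm.
    frame_interval_ms :
        Temporal spacing of the cine frames in ms.
    n_frames :
        Number of acquired temporal sets (>= 2); frame 1 is the reference.
    """

    ke: tuple[float, float]
    voxel_size: float = 1.0
    frame_interval_ms: float = 32.0
    n_frames: int = 18

    def __post_init__(self) -> None:
        ke = self.ke
        if np.isscalar(ke):
            ke = (float(ke), float(ke))
        else:
            ke = tuple(float(k) for k in ke)
            if len(ke) != 2:
                raise ConfigurationError("ke must be a scalar or a pair (ke_x, ke_y)")
        object.__setattr__(self, "ke", ke)
        if min(ke) <= 0:
            raise ConfigurationError(f"ke must be positive, got {ke}")
        if self.voxel_size <= 0:
            raise ConfigurationError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.frame_interval_ms <= 0:
            raise ConfigurationError("frame_interval_ms must be positive")
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2, got {self.n_frames}")

    @property
    def max_single_wrap_displacement(self) -> float:
        """Largest |d_i| (mm) recoverable by single-cycle unwrapping, 1/ke."""
        return 1.0 / min(self.ke)


def voxel_centers(shape: tuple[int, int], voxel_size: float) -> np.ndarray:
    """Return an ``(H, W, 2)`` array of voxel-centre positions (x, y) in mm."""
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    out = np.empty((h, w, 2))
    out[..., 0] = (cols + 0.5) * voxel_size
    out[..., 1] = (rows + 0.5) * voxel_size
    return out


def _as_polygon(points: np.ndarray, frame: int, name: str) -> Polygon:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError(f"frame {frame}: {name} contour must be an (N>=3, 2) point list")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError(f"frame {frame}: {name} contour is self-intersecting or degenerate")
    return poly


@dataclass
class WallSegmentation:
    """Per-frame luminal and adventitial wall contours (closed polygons, mm).

    Each contour is an ``(N, 2)`` array of vertices in image coordinates;
    the closing edge from last to first vertex is implicit.  Invariant: the
    adventitial polygon strictly contains the luminal polygon in every
    frame.
    """

    luminal: list[np.ndarray]
    adventitial: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.luminal) != len(self.adventitial):
            raise GeometryError(
                f"luminal ({len(self.luminal)}) and adventitial "
                f"({len(self.adventitial)}) frame counts differ"
            )
        self.luminal = [np.asarray(c, dtype=float) for c in self.luminal]
        self.adventitial = [np.asarray(c, dtype=float) for c in self.adventitial]
        for i, (lum, adv) in enumerate(zip(self.luminal, self.adventitial)):
            frame = i + 1
            lum_p = _as_polygon(lum, frame, "luminal")
            adv_p = _as_polygon(adv, frame, "adventitial")
            if not adv_p.contains(lum_p):
                raise GeometryError(
                    f"frame {frame}: adventitial contour does not strictly "
                    "contain the luminal contour (field: luminal/adventitial)"
                )

    @property
    def n_frames(self) -> int:
        return len(self.luminal)

    def wall_mask(self, t: int, shape: tuple[int, int], voxel_size: float) -> np.ndarray:
        """Rasterize the frame-``t`` (1-based) wall as a boolean ``(H, W)`` mask.

        A voxel belongs to the wall iff its centre lies strictly inside the
        adventitial polygon and not strictly inside the luminal polygon
        (even-odd rule; contour points themselves count as wall).
        """
        centers = voxel_centers(shape, voxel_size).reshape(-1, 2)
        adv = Polygon(self.adventitial[t - 1])
        lum = Polygon(self.luminal[t - 1])
        inside_adv = shapely.contains_xy(adv, centers[:, 0], centers[:, 1])
        inside_lum = shapely.contains_xy(lum, centers[:, 0], centers[:, 1])
        return (inside_adv & ~inside_lum).reshape(shape)


@dataclass
class DensePhaseSeries:
    """Raw observable of a DENSE scan: magnitude plus wrapped x/y phase stacks.

    All three stacks are ``(N_t, H, W)`` arrays; phases are radians wrapped
    to (-pi, pi].
    """

    magnitude: np.ndarray
    phase_x: np.ndarray
    phase_y: np.ndarray
    enc: EncodingParams

    def __post_init__(self) -> None:
        from .errors import FormatError

        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase_x = np.asarray(self.phase_x, dtype=float)
        self.phase_y = np.asarray(self.phase_y, dtype=float)
        shapes = {a.shape for a in (self.magnitude, self.phase_x, self.phase_y)}
        if len(shapes) != 1:
            raise FormatError(f"magnitude/phase stacks have mismatched shapes: {shapes}")
        if self.magnitude.ndim != 3:
            raise FormatError(f"stacks must be (N_t, H, W), got shape {self.magnitude.shape}")
        if self.magnitude.shape[0] != self.enc.n_frames:
            raise FormatError(
                f"stack frame count {self.magnitude.shape[0]} != "
                f"encoding n_frames {self.enc.n_frames}"
            )
        for name, ph in (("phase_x", self.phase_x), ("phase_y", self.phase_y)):
            if ph.size and (ph.min() <= -np.pi - 1e-12 or ph.max() > np.pi + 1e-12):
                raise FormatError(
                    f"{name} contains values outside (-pi, pi]; declare units "
                    "at read time if the file stores degrees or scaled integers"
                )

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape[1:]


@dataclass(frozen=True)
class AnatomicalContext:
    """Anatomical metadata attached to one scanned aortic cross-section.

    Parameters
    ----------
    location :
        One of ``IAA`` (infrarenal abdominal aorta), ``DTA`` (mid-descending
        thoracic aorta), ``DAA`` (distal aortic arch).  Selects the
        local-systole rule and the default spatial smoothing radius.
    avi_angle :
        Angular position (radians, CCW from +x about the wall centroid) of
        the aorto-vertebral interface; sector 1 is the first sector
        counterclockwise from this angle.
    bsa :
        Body surface area in m**2 (optional; needed for relative aortic size).
    group :
        Free-form group label (e.g. an age band); carried through unchanged.
    """

    location: str
    avi_angle: float = 0.0
    bsa: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ConfigurationError(
                f"location must be one of {LOCATIONS}, got {self.location!r}"
            )
        if self.bsa is not None and self.bsa <= 0:
            raise ConfigurationError(f"bsa must be positive, got {self.bsa}")


def resample_closed_contour(points: np.ndarray, n: int = 256) -> np.ndarray:
    """Resample a closed polygon to ``n`` points uniformly spaced by arc length."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("contour has zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, closed[:, 0])
    out[:, 1] = np.interp(target, s, closed[:, 1])
    return out


def midwall_centroid(seg: WallSegmentation, t: int = 1, n: int = 256) -> np.ndarray:
    """Centroid of the mid-wall contour at frame ``t`` (1-based).

    Computed as the midpoint of the arc-length-resampled luminal and
    adventitial contour centroids, which for concentric contours equals the
    mean of mid-wall points.
    """
    lum = resample_closed_contour(seg.luminal[t - 1], n).mean(axis=0)
    adv = resample_closed_contour(seg.adventitial[t - 1], n).mean(axis=0)
    return 0.5 * (lum + adv)


def radial_profile(points: np.ndarray, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Radius of a star-shaped closed contour at given angles about ``center``.

    The contour vertices are converted to polar coordinates about ``center``
    and the radius linearly interpolated in angle.  Valid for contours that
    are star-shaped about the centre, which holds for non-pathological
    aortic cross-sections.
    """
    pts = np.asarray(points, dtype=float) - center
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    r = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(theta)
    theta_s = theta[order]
    r_s = r[order]
    theta_ext = np.concatenate([theta_s, theta_s[:1] + TWO_PI])
    r_ext = np.concatenate([r_s, r_s[:1]])
    query = np.mod(np.asarray(angles) - theta_s[0], TWO_PI) + theta_s[0]
    return np.interp(query, theta_ext, r_ext)
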