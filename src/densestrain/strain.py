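"""Sector-wise 2D Green strain via bilinear quadrilateral finite elements.

The wall is divided into 16 equal angular sectors about the reference
mid-wall centroid, numbered counterclockwise with sector 1 the first sector
counterclockwise from the aorto-vertebral interface (AVI) angle; a point
exactly on a sector boundary belongs to the clockwise sector.

Within each sector the tracked voxels are pooled into four quadrants —
(inner, clockwise), (inner, counterclockwise), (outer, counterclockwise),
(outer, clockwise) — whose averaged reference positions form the nodes of a
bilinear quadrilateral element (reference point averaging); each node moves
with the mean trajectory of its constituent voxels (weighted spatial
averaging with weights implicit in the voxel counts).  The referential
displacement gradient ``H = du/dX`` is evaluated at the element centre with
bilinear shape functions on normalized coordinates (xi, eta) in [-1, 1]^2,
giving the Green-Lagrange tensor

    E = (H + H^T + H^T.H) / 2,

which is finally rotated into radial-circumferential axes using the local
wall tangent (central difference of adjacent sector centres in the
reference configuration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import TWO_PI, AnatomicalContext, WallSegmentation, midwall_centroid, wrap_angle
from .errors import ConfigurationError, DegenerateElementError, ScanQualityError
from .smoothing import polynomial_smooth_strain
from .tracking import TrajectoryField

logger = logging.getLogger(__name__)

N_SECTORS = 16
MIN_VALID_SECTORS = 12
MAX_JACOBIAN_COND = 1e6

# corner coordinates of the bilinear element: (cw,inner), (ccw,inner),
# (ccw,outer), (cw,outer) at (xi, eta) = (-1,-1), (1,-1), (1,1), (-1,1)
_XI = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA = np.array([-1.0, -1.0, 1.0, 1.0])


def shape_function_gradients(xi: float = 0.0, eta: float = 0.0) -> np.ndarray:
    """Gradients dN_a/d(xi, eta) of the four bilinear shape functions, (4, 2)."""
    dn = np.empty((4, 2))
    dn[:, 0] = 0.25 * _XI * (1.0 + _ETA * eta)
    dn[:, 1] = 0.25 * _ETA * (1.0 + _XI * xi)
    return dn


def green_strain_element(
    nodes_ref: np.ndarray,
    nodes_disp: np.ndarray,
    eval_point: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Green-Lagrange strain of one quadrilateral element, as a (2, 2) tensor.

    ``nodes_ref`` are the four reference-configuration node positions and
    ``nodes_disp`` their displacement vectors, ordered (cw-inner, ccw-inner,
    ccw-outer, cw-outer).  ``H = (sum_a u_a (grad N_a)^T) J^{-1}`` with
    ``J`` the reference Jacobian, evaluated at the element centre by
    default.
    """
    nodes_ref = np.asarray(nodes_ref, dtype=float)
    nodes_disp = np.asarray(nodes_disp, dtype=float)
    if nodes_ref.shape != (4, 2) or nodes_disp.shape != (4, 2):
        raise ConfigurationError("element needs 4 reference nodes and 4 displacements")
    dn = shape_function_gradients(*eval_point)
    jac = nodes_ref.T @ dn  # J[i, j] = dX_i/dxi_j
    det = np.linalg.det(jac)
    if abs(det) < 1e-12 or np.linalg.cond(jac) > MAX_JACOBIAN_COND:
        raise DegenerateElementError(
            f"element Jacobian is singular or ill-conditioned (det={det:.3e})"
        )
    h = (nodes_disp.T @ dn) @ np.linalg.inv(jac)
    return 0.5 * (h + h.T + h.T @ h)


def rotate_to_cylindrical(E: np.ndarray, tangent_angle: float) -> np.ndarray:
    """Rotate a Cartesian strain tensor into (radial, circumferential) axes.

    ``tangent_angle`` is the direction of the local circumferential tangent
    (counterclockwise sense).  Returns the (2, 2) tensor in the (r, theta)
    basis: ``out[0, 0] = E_rr``, ``out[0, 1] = E_rtheta``,
    ``out[1, 1] = E_thetatheta``.  Trace and determinant are preserved.
    """
    tangent = np.array([np.cos(tangent_angle), np.sin(tangent_angle)])
    radial = np.array([tangent[1], -tangent[0]])  # outward normal, tangent - 90 deg
    rot = np.column_stack([radial, tangent])
    return rot.T @ np.asarray(E, dtype=float) @ rot


@dataclass
class SectorElements:
    """Quadrilateral elements of the 16 sectors in the reference configuration.

    ``nodes_ref[s]`` are the four averaged node positions of sector ``s+1``;
    ``quadrant_members[s]`` holds four index arrays into the trajectory
    points; invalid sectors (too few voxels or degenerate geometry) are
    flagged rather than fatal.
    """

    centroid: np.ndarray
    avi_angle: float
    nodes_ref: np.ndarray  # (16, 4, 2)
    quadrant_members: list[list[np.ndarray]]
    valid: np.ndarray  # (16,) bool
    sector_center_angles: np.ndarray  # (16,)

    def node_displacements(self, traj: TrajectoryField, t: int) -> np.ndarray:
        """Mean displacement of each node's voxels at frame ``t`` (1-based), (16, 4, 2)."""
        u = traj.u[t - 1]
        out = np.full((N_SECTORS, 4, 2), np.nan)
        for s in range(N_SECTORS):
            if not self.valid[s]:
                continue
            for q in range(4):
                out[s, q] = u[self.quadrant_members[s][q]].mean(axis=0)
        return out


def sector_index(angles: np.ndarray, avi_angle: float, n_sectors: int = N_SECTORS) -> np.ndarray:
    """Sector number (1..n) of angular positions about the wall centroid.

    Sector ``s`` spans ``(avi + (s-1)*w, avi + s*w]`` with ``w = 2*pi/n``:
    numbering begins at the first sector counterclockwise from the AVI and a
    point exactly on a boundary belongs to the clockwise sector (an angle
    exactly at the AVI falls in sector ``n``).
    """
    width = TWO_PI / n_sectors
    rel = np.mod(np.asarray(angles, dtype=float) - avi_angle, TWO_PI)
    idx = np.ceil(rel / width).astype(int)
    idx[idx == 0] = n_sectors
    return idx


def build_sector_elements(
    traj: TrajectoryField,
    seg: WallSegmentation,
    avi_angle: float = 0.0,
) -> SectorElements:
    """Pool tracked voxels into per-sector quadrilateral elements.

    Voxels are assigned to sectors by their reference angle about the
    frame-1 mid-wall centroid, split radially at the sector's median radius
    and circumferentially at the sector centre.  A sector is flagged
    invalid (not fatal) if it has fewer than 4 usable voxels, an empty
    quadrant, or a near-collinear node set.
    """
    centroid = midwall_centroid(seg, t=1)
    rel = traj.ref - centroid
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    radius = np.hypot(rel[:, 0], rel[:, 1])
    sect = sector_index(theta, avi_angle)
    width = TWO_PI / N_SECTORS
    centers = wrap_angle(avi_angle + (np.arange(N_SECTORS) + 0.5) * width)

    nodes_ref = np.full((N_SECTORS, 4, 2), np.nan)
    members: list[list[np.ndarray]] = []
    valid = np.zeros(N_SECTORS, dtype=bool)
    for s in range(N_SECTORS):
        idx = np.flatnonzero(sect == s + 1)
        quads = [np.empty(0, dtype=int)] * 4
        if len(idx) < 4:
            members.append(quads)
            continue
        r = radius[idx]
        inner = r <= np.median(r)
        ccw = wrap_angle(theta[idx] - centers[s]) > 0
        quads = [
            idx[inner & ~ccw],   # (cw, inner)   -> (xi, eta) = (-1, -1)
            idx[inner & ccw],    # (ccw, inner)  -> (+1, -1)
            idx[~inner & ccw],   # (ccw, outer)  -> (+1, +1)
            idx[~inner & ~ccw],  # (cw, outer)   -> (-1, +1)
        ]
        members.append(quads)
        if any(len(q) == 0 for q in quads):
            continue
        nodes = np.stack([traj.ref[q].mean(axis=0) for q in quads])
        jac = nodes.T @ shape_function_gradients()
        if abs(np.linalg.det(jac)) < 1e-12 or np.linalg.cond(jac) > MAX_JACOBIAN_COND:
            continue
        nodes_ref[s] = nodes
        valid[s] = True
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning(
            "%d of %d sectors are invalid (too few voxels or degenerate geometry)",
            n_invalid,
            N_SECTORS,
        )
    return SectorElements(
        centroid=centroid,
        avi_angle=avi_angle,
        nodes_ref=nodes_ref,
        quadrant_members=members,
        valid=valid,
        sector_center_angles=centers,
    )


def _tangent_angles(elements: SectorElements) -> np.ndarray:
    """Local wall tangent per sector from adjacent sector centres.

    Central difference of the element reference centres along the wall
    (circular); falls back to the geometric tangent (sector centre angle
    + 90 deg) where a neighbour is invalid.
    """
    out = np.empty(N_SECTORS)
    element_centers = elements.nodes_ref.mean(axis=1)  # (16, 2)
    for s in range(N_SECTORS):
        prev_s, next_s = (s - 1) % N_SECTORS, (s + 1) % N_SECTORS
        if elements.valid[prev_s] and elements.valid[next_s]:
            vec = element_centers[next_s] - element_centers[prev_s]
            out[s] = np.arctan2(vec[1], vec[0])
        else:
            out[s] = wrap_angle(elements.sector_center_angles[s] + np.pi / 2)
    return out


def sector_tensor_series(
    elements: SectorElements, traj: TrajectoryField
) -> tuple[np.ndarray, np.ndarray]:
    """Cylindrical strain tensors per sector and frame.

    Returns ``(tensors, valid)`` with ``tensors`` of shape
    ``(16, N_t, 2, 2)`` in the (r, theta) basis (NaN where invalid).  A
    sector whose element turns degenerate at any frame is invalidated
    outright, mirroring the treatment of unusable data as missing rather
    than fatal.
    """
    n_t = traj.n_frames
    tensors = np.full((N_SECTORS, n_t, 2, 2), np.nan)
    valid = elements.valid.copy()
    tangents = _tangent_angles(elements)
    for t in range(1, n_t + 1):
        disp = elements.node_displacements(traj, t)
        for s in range(N_SECTORS):
            if not valid[s]:
                continue
            try:
                e_cart = green_strain_element(elements.nodes_ref[s], disp[s])
            except DegenerateElementError:
                logger.warning("sector %d degenerate at frame %d; flagged invalid", s + 1, t)
                valid[s] = False
                tensors[s] = np.nan
                continue
            tensors[s, t - 1] = rotate_to_cylindrical(e_cart, tangents[s])
    return tensors, valid


@dataclass
class SectorStrainMap:
    """16-sector circumferential Green strain map over all cine frames.

    ``strain`` is the polynomial-smoothed circumferential component
    ``E_thetatheta`` (shape ``(16, N_t)``, AVI-numbered rows, NaN for
    invalid sectors); the raw full tensor components are retained for
    future radial/shear analyses.
    """

    strain: np.ndarray          # (16, N_t) smoothed E_thetatheta
    strain_raw: np.ndarray      # (16, N_t) unsmoothed E_thetatheta
    e_rr: np.ndarray            # (16, N_t)
    e_rtheta: np.ndarray        # (16, N_t)
    valid: np.ndarray           # (16,) bool
    sector_center_angles: np.ndarray
    avi_angle: float
    location: str | None = None
    frame_interval_ms: float | None = None

    @property
    def n_frames(self) -> int:
        return self.strain.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def assemble_sector_map(
    tensors: np.ndarray,
    valid: np.ndarray,
    elements: SectorElements,
    ctx: AnatomicalContext | None = None,
    smooth: bool = True,
) -> SectorStrainMap:
    """Assemble the AVI-numbered sector strain map from per-sector tensors.

    Requires at least 12 of 16 valid sectors (scans below that quality were
    discarded in practice); each valid sector's circumferential series is
    time-smoothed with the fifth-order polynomial; invalid sectors carry
    NaN.
    """
    if int(valid.sum()) < MIN_VALID_SECTORS:
        raise ScanQualityError(
            f"only {int(valid.sum())} of {N_SECTORS} sectors are valid; "
            f"need >= {MIN_VALID_SECTORS}"
        )
    e_tt = tensors[:, :, 1, 1].copy()
    e_tt[~valid] = np.nan
    strain = polynomial_smooth_strain(e_tt) if smooth else e_tt.copy()
    return SectorStrainMap(
        strain=strain,
        strain_raw=e_tt,
        e_rr=tensors[:, :, 0, 0],
        e_rtheta=tensors[:, :, 0, 1],
        valid=valid.copy(),
        sector_center_angles=elements.sector_center_angles,
        avi_angle=elements.avi_angle,
        location=ctx.location if ctx is not None else None,
    )


def compute_strain_map(
    traj: TrajectoryField,
    seg: WallSegmentation,
    ctx: AnatomicalContext,
    smooth: bool = True,
) -> SectorStrainMap:
    """Convenience: elements -> tensors -> assembled map from trajectories."""
    elements = build_sector_elements(traj, seg, ctx.avi_angle)
    tensors, valid = sector_tensor_series(elements, traj)
    return assemble_sector_map(tensors, valid, elements, ctx, smooth=smooth)
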