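"""Summary analytics of a sector strain map.

Covers selection of local systole (with the distal-arch-specific rule),
normalized circumferential strain (NCS), the heterogeneity index, the mean
displacement angle, optional +-1-sector alignment of distal-arch maps, and
diastolic geometric indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import AnatomicalContext, WallSegmentation, midwall_centroid, radial_profile
from .errors import ConfigurationError, NormalizationError
from .strain import N_SECTORS, SectorStrainMap
from .tracking import TrajectoryField

#: mean strain below this is treated as rigid motion: NCS undefined
MEAN_STRAIN_FLOOR = 1e-6

#: fraction of the eventual maximum mean strain that marks the start of
#: local systole in the DAA rule (configurable, logged in the summary)
DAA_SYSTOLE_ONSET_FRACTION = 0.1

DAA_PEAKING_SECTORS = 6


def _mean_series(strain: np.ndarray) -> np.ndarray:
    """Mean strain over valid sectors at every frame."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(strain, axis=0)


def select_systole(
    smap: SectorStrainMap,
    location: str | None = None,
    onset_fraction: float = DAA_SYSTOLE_ONSET_FRACTION,
) -> int:
    """Frame (1-based) of local systole.

    IAA/DTA: the frame with the largest mean circumferential strain over
    the cross-section (ties broken toward the earliest frame).

    DAA: some sectors peak in local diastole, so systole is instead the
    mean peaking frame of the first six sectors to peak after the onset of
    local systole — onset being the first frame where the mean strain
    exceeds ``onset_fraction`` of its eventual maximum; each sector's peak
    is its argmax over frames from onset onward; the six sectors with the
    earliest peaks (ties toward the lower sector number) contribute their
    peak frames, and the mean is rounded half-up.
    """
    location = location or smap.location or "DTA"
    mean_series = _mean_series(smap.strain)
    if not np.isfinite(mean_series).any() or np.nanmax(np.abs(mean_series)) < MEAN_STRAIN_FLOOR:
        raise NormalizationError("strain series is identically zero; no systole to select")
    if location in ("IAA", "DTA"):
        return int(np.nanargmax(mean_series)) + 1
    # DAA rule
    peak_mean = np.nanmax(mean_series)
    onset_candidates = np.flatnonzero(mean_series > onset_fraction * peak_mean)
    onset = int(onset_candidates[0]) if len(onset_candidates) else 0
    peaks = []
    for s in range(smap.strain.shape[0]):
        row = smap.strain[s, onset:]
        if np.isnan(row).all():
            continue
        peaks.append((int(np.nanargmax(row)) + onset + 1, s))
    peaks.sort()  # by peak frame, then sector index
    first = [frame for frame, _ in peaks[:DAA_PEAKING_SECTORS]]
    return int(math.floor(np.mean(first) + 0.5))  # round half-up


def compute_ncs(smap: SectorStrainMap, systole_frame: int) -> tuple[np.ndarray, float]:
    """Normalized circumferential strain per sector, and the maximum NCS.

    ``ncs[s]`` is the sector strain at local systole divided by the mean
    strain over valid sectors at that frame (so the mean NCS is exactly 1);
    ``max_ncs`` is the highest value of strain/mean-systolic-strain over
    all sectors *and all frames* (the peak may fall in local diastole).
    """
    at_sys = smap.strain[:, systole_frame - 1]
    mean_sys = float(np.nanmean(at_sys))
    if not np.isfinite(mean_sys) or abs(mean_sys) <= MEAN_STRAIN_FLOOR:
        raise NormalizationError(
            f"mean strain at systole ({mean_sys:.2e}) too small to normalize "
            "(rigid motion produces no strain)"
        )
    ncs = at_sys / mean_sys
    with np.errstate(invalid="ignore"):
        max_ncs = float(np.nanmax(smap.strain / mean_sys))
    return ncs, max_ncs


def heterogeneity_index(smap: SectorStrainMap, systole_frame: int) -> float:
    """Sample SD of the 16 sector strains at systole divided by their mean."""
    at_sys = smap.strain[:, systole_frame - 1]
    vals = at_sys[np.isfinite(at_sys)]
    if len(vals) < 2:
        raise ConfigurationError("heterogeneity index needs >= 2 valid sectors")
    mean = float(vals.mean())
    if abs(mean) <= MEAN_STRAIN_FLOOR:
        raise NormalizationError("mean strain too small for heterogeneity index")
    return float(vals.std(ddof=1) / mean)


@dataclass(frozen=True)
class DisplacementAngle:
    """Mean wall displacement at systole: direction and magnitude.

    Angle convention: 0 deg points left-lateral, +90 deg anterior, in
    (-180, 180].  ``defined`` is False for vanishing mean displacement
    (angle is then NaN but the magnitude is still reported).
    """

    angle_deg: float
    magnitude_mm: float
    defined: bool


def mean_displacement_angle(
    traj: TrajectoryField, systole_frame: int, tol: float = 1e-12
) -> DisplacementAngle:
    """Direction of the mean forward displacement over all wall voxels."""
    u = traj.u[systole_frame - 1].mean(axis=0)
    mag = float(np.hypot(u[0], u[1]))
    if mag <= tol:
        return DisplacementAngle(angle_deg=float("nan"), magnitude_mm=mag, defined=False)
    return DisplacementAngle(
        angle_deg=float(np.degrees(np.arctan2(u[1], u[0]))), magnitude_mm=mag, defined=True
    )


def align_daa_map(
    ncs: np.ndarray, reference: np.ndarray
) -> tuple[int, np.ndarray, bool]:
    """Best +-1-sector rotation aligning a distal-arch map with a reference.

    Oblique arch cross-sections are non-parallel between subjects, so each
    16-sector map is allowed a rotation ``r`` in {-1, 0, +1} (applied as
    ``np.roll(ncs, r)``) maximizing the Pearson correlation with the
    reference map; ties prefer ``r = 0``, then the smaller ``|r|``.
    Returns ``(r, rotated_map, defined)``; a constant map leaves the
    correlation undefined and yields ``r = 0`` with ``defined=False``.
    """
    ncs = np.asarray(ncs, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if ncs.shape != reference.shape:
        raise ConfigurationError("maps must have identical shape")
    if np.nanstd(ncs) < 1e-15 or np.nanstd(reference) < 1e-15:
        return 0, ncs.copy(), False
    best_r, best_corr = 0, -np.inf
    for r in (0, -1, 1):  # preference order under exact ties
        rolled = np.roll(ncs, r)
        ok = np.isfinite(rolled) & np.isfinite(reference)
        corr = float(np.corrcoef(rolled[ok], reference[ok])[0, 1])
        if corr > best_corr:
            best_r, best_corr = r, corr
    return best_r, np.roll(ncs, best_r), True


def diastolic_geometry(
    seg: WallSegmentation, ctx: AnatomicalContext, n: int = 256
) -> tuple[float, float | None]:
    """Diastolic aortic diameter (cm) and relative aortic size (cm/m^2).

    The diameter is the average of the x- and y-extents of the frame-1
    (diastolic reference) mid-wall contour; relative size divides by the
    body surface area and is ``None`` (flagged) when BSA is missing.
    """
    centroid = midwall_centroid(seg, t=1, n=n)
    angles = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r_mid = 0.5 * (
        radial_profile(seg.luminal[0], centroid, angles)
        + radial_profile(seg.adventitial[0], centroid, angles)
    )
    pts = centroid + r_mid[:, None] * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    extent_mm = pts.max(axis=0) - pts.min(axis=0)
    diameter_cm = float(extent_mm.mean() / 10.0)
    relative = diameter_cm / ctx.bsa if ctx.bsa is not None else None
    return diameter_cm, relative


def _sector_offset_from_avi(sector: int) -> int:
    """Signed sectors counterclockwise from the AVI (sector 16 -> 0,
    sector 14 -> -2, sector 1 -> +1, range -7..8)."""
    return sector if sector <= 8 else sector - N_SECTORS


@dataclass
class StrainSummary:
    """Scalar summary of one analyzed cross-section."""

    systole_frame: int
    mean_strain_systole: float
    ncs: np.ndarray
    max_ncs: float
    het_index: float
    mean_disp_angle_deg: float
    mean_disp_magnitude_mm: float
    disp_angle_defined: bool
    peak_sector: int
    peak_sector_offset_from_avi: int
    n_valid_sectors: int
    diameter_cm: float | None = None
    relative_size_cm_per_m2: float | None = None
    location: str | None = None
    conventions: dict = field(
        default_factory=lambda: {
            "angle_zero": "left-lateral",
            "angle_positive": "counterclockwise (anterior at +90 deg)",
            "sector_numbering": "sector 1 first counterclockwise from the AVI; "
            "boundaries belong to the clockwise sector",
            "strain_gradient": "referential (with respect to frame-1 coordinates)",
            "sd": "sample (n-1)",
            "daa_systole_onset_fraction": DAA_SYSTOLE_ONSET_FRACTION,
        }
    )

    def to_dict(self) -> dict:
        return {
            "systole_frame": self.systole_frame,
            "mean_strain_systole": self.mean_strain_systole,
            "ncs": [None if not np.isfinite(v) else float(v) for v in self.ncs],
            "max_ncs": self.max_ncs,
            "het_index": self.het_index,
            "mean_disp_angle_deg": None
            if not self.disp_angle_defined
            else self.mean_disp_angle_deg,
            "mean_disp_magnitude_mm": self.mean_disp_magnitude_mm,
            "peak_sector": self.peak_sector,
            "peak_sector_offset_from_avi": self.peak_sector_offset_from_avi,
            "n_valid_sectors": self.n_valid_sectors,
            "diameter_cm": self.diameter_cm,
            "relative_size_cm_per_m2": self.relative_size_cm_per_m2,
            "location": self.location,
            "conventions": self.conventions,
        }


def summarize(
    smap: SectorStrainMap,
    traj: TrajectoryField,
    seg: WallSegmentation,
    ctx: AnatomicalContext,
    systole_frame: int | None = None,
) -> StrainSummary:
    """Compute the full scalar summary of an analyzed cross-section."""
    if systole_frame is None:
        systole_frame = select_systole(smap, ctx.location)
    ncs, max_ncs = compute_ncs(smap, systole_frame)
    het = heterogeneity_index(smap, systole_frame)
    disp = mean_displacement_angle(traj, systole_frame)
    diameter, relative = diastolic_geometry(seg, ctx)
    peak_sector = int(np.nanargmax(ncs)) + 1
    mean_sys = float(np.nanmean(smap.strain[:, systole_frame - 1]))
    return StrainSummary(
        systole_frame=systole_frame,
        mean_strain_systole=mean_sys,
        ncs=ncs,
        max_ncs=max_ncs,
        het_index=het,
        mean_disp_angle_deg=disp.angle_deg,
        mean_disp_magnitude_mm=disp.magnitude_mm,
        disp_angle_defined=disp.defined,
        peak_sector=peak_sector,
        peak_sector_offset_from_avi=_sector_offset_from_avi(peak_sector),
        n_valid_sectors=smap.n_valid,
        diameter_cm=diameter,
        relative_size_cm_per_m2=relative,
        location=ctx.location,
    )
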