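"""Readers and writers for every external artifact of the pipeline.

Image stacks are accepted as NIfTI (frame axis last, the conventional time
axis), multi-page TIFF (frame axis first) or raw ``.npy`` arrays of shape
``(N_t, H, W)``.  Contours travel as JSON (one polygon pair per frame, mm)
or long-format CSV; sector maps as a CSV table with a JSON summary sidecar.
All CSV is UTF-8 with '.' decimals and a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import DensePhaseSeries, EncodingParams, WallSegmentation, wrap_phase
from .errors import FormatError, GeometryError
from .metrics import StrainSummary
from .strain import SectorStrainMap


def _load_stack(path: str | Path) -> np.ndarray:
    """Load one image stack as a ``(N_t, H, W)`` float array."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(path).dataobj).astype(float)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D NIfTI volume, got shape {data.shape}")
        return np.transpose(data, (2, 0, 1))  # (H, W, N_t) -> (N_t, H, W)
    if suffixes.endswith((".tif", ".tiff")):
        data = tifffile.imread(path).astype(float)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a multi-page TIFF, got shape {data.shape}")
        return data
    if suffixes.endswith(".npy"):
        data = np.load(path).astype(float)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a (N_t, H, W) array, got shape {data.shape}")
        return data
    raise FormatError(f"{path}: unsupported image format (use .nii/.nii.gz/.tif/.npy)")


def _save_stack(arr: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(np.transpose(arr, (1, 2, 0)), affine=np.eye(4)), path)
    elif suffixes.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr.astype(np.float32))
    elif suffixes.endswith(".npy"):
        np.save(path, arr)
    else:
        raise FormatError(f"{path}: unsupported image format (use .nii/.nii.gz/.tif/.npy)")


def read_series(
    mag_path: str | Path,
    phase_x_path: str | Path,
    phase_y_path: str | Path,
    enc: EncodingParams,
    phase_units: str = "rad",
) -> DensePhaseSeries:
    """Read and validate a magnitude + x/y-phase series.

    ``phase_units`` declares how phase is stored: ``"rad"`` (default,
    values must already lie in (-pi, pi]) or ``"deg"`` (converted and
    re-wrapped).  Vendor-scaled integer phase should be converted by the
    caller; values outside (-pi, pi] without a unit declaration are
    rejected rather than silently rescaled.
    """
    mag = _load_stack(mag_path)
    phx = _load_stack(phase_x_path)
    phy = _load_stack(phase_y_path)
    if phase_units == "deg":
        phx = wrap_phase(np.deg2rad(phx))
        phy = wrap_phase(np.deg2rad(phy))
    elif phase_units != "rad":
        raise FormatError(f"phase_units must be 'rad' or 'deg', got {phase_units!r}")
    return DensePhaseSeries(magnitude=mag, phase_x=phx, phase_y=phy, enc=enc)


def write_series(series: DensePhaseSeries, out_dir: str | Path, fmt: str = "nii") -> dict:
    """Write the three stacks to ``out_dir`` as mag/phx/phy.<fmt>; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (
        ("mag", series.magnitude),
        ("phx", series.phase_x),
        ("phy", series.phase_y),
    ):
        p = out_dir / f"{name}.{fmt}"
        _save_stack(arr, p)
        paths[name] = p
    return paths


def read_contours(path: str | Path, n_frames: int) -> WallSegmentation:
    """Read per-frame luminal/adventitial contours from JSON or CSV.

    JSON schema: ``{"frames": [{"frame": 1, "luminal": [[x, y], ...],
    "adventitial": [[x, y], ...]}, ...]}`` with coordinates in mm.  CSV
    schema (long format): columns ``frame, boundary, x, y`` with boundary
    in {luminal, adventitial} and vertices in file order.
    Frames must cover 1..n_frames exactly; missing frames are listed in the
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    per_frame: dict[int, dict[str, list]] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for rec in payload.get("frames", []):
            per_frame[int(rec["frame"])] = {
                "luminal": rec["luminal"],
                "adventitial": rec["adventitial"],
            }
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        required = {"frame", "boundary", "x", "y"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: contour CSV needs columns {sorted(required)}")
        for (frame, boundary), grp in df.groupby(["frame", "boundary"], sort=True):
            per_frame.setdefault(int(frame), {})[str(boundary)] = grp[["x", "y"]].to_numpy()
    else:
        raise FormatError(f"{path}: unsupported contour format (use .json or .csv)")

    missing = [t for t in range(1, n_frames + 1) if t not in per_frame]
    extra = [t for t in per_frame if not 1 <= t <= n_frames]
    if missing or extra:
        raise FormatError(
            f"{path}: contour frames do not match n_frames={n_frames} "
            f"(missing: {missing}, unexpected: {extra})"
        )
    luminal, adventitial = [], []
    for t in range(1, n_frames + 1):
        rec = per_frame[t]
        if "luminal" not in rec or "adventitial" not in rec:
            raise GeometryError(f"frame {t}: needs both luminal and adventitial contours")
        luminal.append(np.asarray(rec["luminal"], dtype=float))
        adventitial.append(np.asarray(rec["adventitial"], dtype=float))
    return WallSegmentation(luminal=luminal, adventitial=adventitial)


def write_contours(seg: WallSegmentation, path: str | Path) -> None:
    """Write a segmentation as the JSON schema of :func:`read_contours`."""
    payload = {
        "frames": [
            {
                "frame": t + 1,
                "luminal": seg.luminal[t].tolist(),
                "adventitial": seg.adventitial[t].tolist(),
            }
            for t in range(seg.n_frames)
        ]
    }
    Path(path).write_text(json.dumps(payload))


def write_sector_table(
    smap: SectorStrainMap,
    summary: StrainSummary,
    path: str | Path,
) -> Path:
    """Write the sector strain map as CSV with a JSON summary sidecar.

    One row per sector (AVI-numbered): sector index, smoothed strain at
    every frame, strain at local systole, and NCS.  The sidecar (same stem,
    ``.json``) carries the scalar summary.  Returns the sidecar path.
    """
    path = Path(path)
    n_t = smap.n_frames
    cols = {"sector": np.arange(1, 17)}
    for t in range(1, n_t + 1):
        cols[f"strain_f{t:02d}"] = smap.strain[:, t - 1]
    cols["strain_systole"] = smap.strain[:, summary.systole_frame - 1]
    cols["ncs"] = summary.ncs
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(summary.to_dict(), indent=2))
    return sidecar


def read_sector_table(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    """Read back a sector table CSV (and its JSON sidecar if present)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "sector" not in df.columns or "ncs" not in df.columns:
        raise FormatError(f"{path}: not a sector table (needs 'sector' and 'ncs' columns)")
    sidecar = path.with_suffix(".json")
    summary = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return df, summary


def write_truth(truth, path: str | Path) -> None:
    """Serialize a synthetic ground truth (sector strains + parameters)."""
    payload = {
        "sector_strain_true": np.asarray(truth.sector_strain_true).tolist(),
        "systole_frame_true": int(truth.systole_frame_true),
        "avi_angle": float(truth.avi_angle),
        "double_wrap_warning": bool(truth.double_wrap_warning),
    }
    Path(path).write_text(json.dumps(payload))
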