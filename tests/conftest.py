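"""Shared fixtures: small synthetic scans reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import densestrain as ds


@pytest.fixture(scope="session")
def enc() -> ds.EncodingParams:
    return ds.EncodingParams(ke=0.25, voxel_size=1.0, frame_interval_ms=32.0, n_frames=18)


@pytest.fixture(scope="session")
def uniform_kin() -> ds.AnnulusKinematics:
    """Pure uniform inflation to lambda = 1.1 at the peak frame (no translation)."""
    return ds.make_kinematics(
        stretch_amplitude=0.1,
        heterogeneity=0.0,
        translation_amplitude=np.zeros(2),
    )


@pytest.fixture(scope="session")
def moving_kin() -> ds.AnnulusKinematics:
    """Inflation plus bulk translation large enough to wrap the phase."""
    return ds.make_kinematics(
        stretch_amplitude=0.1,
        heterogeneity=0.0,
        translation_amplitude=np.array([2.0, 1.0]),
    )


@pytest.fixture(scope="session")
def uniform_scan(uniform_kin, enc):
    """Noise-free render of the uniform-inflation annulus."""
    return ds.render_dense_series(uniform_kin, enc, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def moving_scan(moving_kin, enc):
    """Noise-free render of the translating annulus (wrapped phases)."""
    return ds.render_dense_series(moving_kin, enc, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def uniform_result(uniform_scan):
    series, seg, _ = uniform_scan
    return ds.analyze(series, seg, ds.AnatomicalContext(location="DTA"))


def make_map(strain: np.ndarray, location: str = "DTA") -> ds.SectorStrainMap:
    """Wrap a raw (16, N_t) strain array as an already-smoothed sector map."""
    strain = np.asarray(strain, dtype=float)
    n_sectors, n_t = strain.shape
    return ds.SectorStrainMap(
        strain=strain,
        strain_raw=strain.copy(),
        e_rr=np.zeros_like(strain),
        e_rtheta=np.zeros_like(strain),
        valid=np.ones(n_sectors, dtype=bool),
        sector_center_angles=(np.arange(n_sectors) + 0.5) * 2 * np.pi / n_sectors,
        avi_angle=0.0,
        location=location,
    )
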