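import numpy as np
import pytest

from ablashape import heatsim, imaging, profiles


@pytest.fixture(scope="session")
def study_programs():
    """The ten shipped study profiles keyed by name."""
    return profiles.study_profiles()


@pytest.fixture(scope="session")
def long_profile(study_programs):
    return study_programs["LONG-60W-600s"]


@pytest.fixture(scope="session")
def oval_profile(study_programs):
    return study_programs["OVAL-60W-120s"]


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast solver tests."""
    return heatsim.SimulationGrid(radial_extent=20.0, axial_extent=60.0, dr=1.0, dz=1.0)


@pytest.fixture(scope="session")
def default_params():
    return heatsim.ThermalParams()


def make_disc_scene(radius_mm: float, cell: float = 0.5, pad_mm: float = 6.0):
    """Boolean SceneMask of a centered disc, axis through its middle."""
    half = int(round((radius_mm + pad_mm) / cell))
    n = 2 * half + 1
    yy, xx = np.meshgrid(np.arange(n) - half, np.arange(n) - half, indexing="ij")
    mask = (xx * cell) ** 2 + (yy * cell) ** 2 <= radius_mm**2
    return imaging.SceneMask(
        values=mask, cell=cell, axis_index=half, start_index=half, trajectory_length=0.0
    )


def make_ellipse_mask(a_mm, b_mm, scale=0.2, pad_mm=5.0):
    """Pixel-grid boolean mask of an axis-aligned ellipse + metadata stub.

    ``a_mm`` is the semi-axis along the probe axis (image rows), ``b_mm``
    across.  Returns (mask, meta) where meta mimics CrossSectionImage
    with start_row at the ellipse center.
    """
    hr = int(round((a_mm + pad_mm) / scale))
    hc = int(round((b_mm + pad_mm) / scale))
    rows = np.arange(2 * hr + 1) - hr
    cols = np.arange(2 * hc + 1) - hc
    zz, xx = np.meshgrid(rows * scale, cols * scale, indexing="ij")
    mask = (zz / a_mm) ** 2 + (xx / b_mm) ** 2 <= 1.0

    class Meta:
        pass

    meta = Meta()
    meta.scale = scale
    meta.axis_column = hc
    meta.start_row = hr
    meta.sample_id = None
    return mask, meta
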