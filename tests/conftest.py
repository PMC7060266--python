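import numpy as np
import pytest

from depotmetry.io import BinaryMask


def digitize_sphere(radius_vox: float, spacing: tuple = (1.0, 1.0, 1.0), margin: int = 3) -> BinaryMask:
    """Sphere digitized by voxel-centre inclusion on an isotropic-index grid."""
    spacing = np.asarray(spacing, dtype=float)
    n = (np.ceil(2 * radius_vox * spacing.min() / spacing) + 2 * margin).astype(int)
    center = n * spacing / 2.0
    axes = [(np.arange(nn) + 0.5) * s - c for nn, s, c in zip(n, spacing, center)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    r_um = radius_vox * spacing.min()
    return BinaryMask(zz**2 + yy**2 + xx**2 <= r_um**2, tuple(spacing))


def digitize_ellipsoid_mask(semiaxes_um, spacing, margin: int = 3) -> BinaryMask:
    semiaxes = np.asarray(semiaxes_um, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    n = (np.ceil(2 * semiaxes / spacing) + 2 * margin).astype(int)
    center = n * spacing / 2.0
    axes = [(np.arange(nn) + 0.5) * s - c for nn, s, c in zip(n, spacing, center)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    a, b, c = semiaxes
    return BinaryMask((zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2 <= 1.0, tuple(spacing))


@pytest.fixture(scope="session")
def sphere_r40() -> BinaryMask:
    return digitize_sphere(40.0)
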