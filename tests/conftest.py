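import numpy as np
import pytest

from rtverify.dose_model import DoseGrid, Structure, VoxelMask


@pytest.fixture
def ramp_grid():
    """Dose linear in x: D(z, y, x) = 1 + 0.5 * x_mm, on a 2 mm grid."""
    nz, ny, nx = 8, 9, 10
    x = np.arange(nx) * 2.0
    values = np.broadcast_to(1.0 + 0.5 * x, (nz, ny, nx)).copy()
    return DoseGrid(values, origin=(0.0, 0.0, 0.0), spacing=(2.0, 2.0, 2.0))


@pytest.fixture
def uniform_grid():
    return DoseGrid(np.full((6, 6, 6), 2.0), origin=(0.0, 0.0, 0.0), spacing=(2.0, 2.0, 2.0))


def sphere_mask(radius_mm, spacing=(1.0, 1.0, 1.0), pad_mm=6.0):
    """Voxel-center sphere mask centred in its own grid."""
    spacing = np.asarray(spacing, float)
    half = radius_mm + pad_mm
    shape = (np.ceil(2 * half / spacing)).astype(int) + 1
    center = (shape - 1) / 2 * spacing
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    gz, gy, gx = np.meshgrid(*axes, indexing="ij")
    r2 = (gz - center[0]) ** 2 + (gy - center[1]) ** 2 + (gx - center[2]) ** 2
    return VoxelMask(r2 <= radius_mm**2, origin=(0, 0, 0), spacing=tuple(spacing))


def circle_polygon(cy, cx, radius, n=96):
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cy + radius * np.sin(ang), cx + radius * np.cos(ang)])


def sphere_structure(center_zyx, radius, z_positions, name="iGTV", role="iGTV", n=96):
    contours = []
    for z in z_positions:
        dz = z - center_zyx[0]
        if abs(dz) < radius:
            r = np.sqrt(radius**2 - dz**2)
            contours.append((float(z), circle_polygon(center_zyx[1], center_zyx[2], r, n)))
    return Structure(name, role, contours)


def smooth_random_field(rng, shape, sigma, lo=0.1, hi=2.0):
    """Strictly positive smooth field for comparison tests."""
    from scipy import ndimage

    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return lo + (hi - lo) * f
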