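import numpy as np
import pytest

import aortagrad as ag


def small_phantom_spec(**kwargs) -> ag.PhantomSpec:
    """A compact candy-cane phantom used where many phantoms are needed."""
    base = dict(
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        grid_shape=(76, 60, 96),
        arch_radius_mm=35.0,
        lumen_radius_mm=10.0,
        descending_length_mm=100.0,
    )
    base.update(kwargs)
    return ag.PhantomSpec(**base)


def cylinder_case(radius_mm=15.0, length_mm=120.0, spacing=1.0, hu_top=350.0, hu_bottom=350.0):
    """Axis-aligned cylinder volume + mask with a linear axial HU ramp."""
    n_xy = int(2 * radius_mm / spacing) + 9
    nz = int(length_mm / spacing) + 1
    c = (n_xy - 1) / 2 * spacing
    x = np.arange(n_xy) * spacing
    xx, yy = np.meshgrid(x, x, indexing="ij")
    disc = (xx - c) ** 2 + (yy - c) ** 2 <= radius_mm**2
    mask = np.repeat(disc[:, :, None], nz, axis=2)
    z = np.arange(nz) * spacing
    hu = hu_bottom + (hu_top - hu_bottom) * z / z[-1]
    vol = np.zeros((n_xy, n_xy, nz), dtype=np.float32)
    vol[mask] = np.broadcast_to(hu, (n_xy, n_xy, nz))[mask]
    affine = np.diag([spacing, spacing, spacing, 1.0])
    axis_vox = (int(round(c / spacing)), int(round(c / spacing)))
    return (
        ag.CtVolume(vol, affine),
        ag.SegmentationMask(mask, affine),
        axis_vox,
        nz,
    )


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-geometry phantom with no noise and no fluctuation."""
    spec = ag.PhantomSpec(noise_sd_hu=0.0, fluctuation_amplitude_hu=0.0, seed=11)
    volume, aorta, lung, truth = ag.generate_phantom(spec)
    return spec, volume, aorta, lung, truth


@pytest.fixture(scope="session")
def clean_phantom_analysis(clean_phantom):
    spec, volume, aorta, lung, truth = clean_phantom
    params, inter = ag.analyze_patient(volume, aorta, lung)
    return spec, truth, params, inter


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom including the periodic fluctuation and noise."""
    spec = ag.PhantomSpec(seed=5)
    volume, aorta, lung, truth = ag.generate_phantom(spec)
    return spec, volume, aorta, lung, truth
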