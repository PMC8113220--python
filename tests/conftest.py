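import numpy as np
import pytest

from stonevol.phantom import PhantomSpec, StoneSpec, render_phantom


def clean_phantom(
    diameters=(10.0, 10.0, 10.0),
    spacing=0.5,
    thickness=None,
    rotation=(0.0, 0.0, 0.0),
    margin_mm=4.0,
    seed=0,
):
    """Noise-free, blur-free phantom with one stone centred in the grid."""
    thickness = thickness if thickness is not None else spacing
    half = max(diameters) / 2.0 + margin_mm
    nz = int(np.ceil(2 * half / thickness))
    ny = nx = int(np.ceil(2 * half / spacing))
    # off-lattice offset so the digitization is generic, not a symmetry case
    center = (
        nz * thickness / 2.0 + 0.137,
        ny * spacing / 2.0 + 0.071,
        nx * spacing / 2.0 + 0.029,
    )
    spec = PhantomSpec(
        grid_shape=(nz, ny, nx),
        pixel_spacing=(spacing, spacing),
        slice_thickness=thickness,
        stones=(
            StoneSpec(
                center_mm=center,
                diameters_mm=diameters,
                rotation_deg=rotation,
                stone_hu_mean=800.0,
                stone_hu_sd=0.0,
            ),
        ),
        background_hu_mean=30.0,
        background_hu_sd=0.0,
        blur_sigma_mm=0.0,
        seed=seed,
    )
    return render_phantom(spec)


def mean_digitization_error(diameters, spacing, n_offsets=4, seed=0):
    """Mean |voxel volume - analytic| / analytic over random sub-voxel
    placements of the stone (digitization error depends on where the
    stone sits relative to the voxel lattice)."""
    import math

    from stonevol.morphometry import measure_stone
    from stonevol.segmentation import SegmentationParams, segment

    rng = np.random.default_rng(seed)
    analytic = math.pi / 6 * diameters[0] * diameters[1] * diameters[2]
    errs = []
    for _ in range(n_offsets):
        half = max(diameters) / 2.0 + 3.0
        n = int(np.ceil(2 * half / spacing))
        offset = rng.uniform(0, 0.5, size=3)
        center = tuple(n * spacing / 2.0 + o for o in offset)
        spec = PhantomSpec(
            grid_shape=(n, n, n),
            pixel_spacing=(spacing, spacing),
            slice_thickness=spacing,
            stones=(StoneSpec(center_mm=center, diameters_mm=diameters, stone_hu_sd=0.0),),
            background_hu_sd=0.0,
            blur_sigma_mm=0.0,
        )
        vol, _ = render_phantom(spec)
        labels = segment(vol, SegmentationParams(hu_threshold=415))
        m = measure_stone(vol, labels, 1)
        errs.append(abs(m.volume_mm3 - analytic) / analytic)
    return float(np.mean(errs))


@pytest.fixture
def sphere_phantom():
    """10 mm sphere at 0.5 mm isotropic voxels, no noise, no blur."""
    return clean_phantom(diameters=(10.0, 10.0, 10.0), spacing=0.5)


@pytest.fixture
def ellipsoid_phantom():
    """Axis-aligned 10 x 6 x 4 mm ellipsoid at 0.5 mm isotropic voxels."""
    # diameters (z, y, x): craniocaudal 4, vertical 6, horizontal 10
    return clean_phantom(diameters=(4.0, 6.0, 10.0), spacing=0.5)
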