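"""Synthetic CT KUB phantoms and simulated treatment cohorts.

Every downstream stage — segmentation, morphometry, outcome
classification, cohort statistics — is validated against data with
analytically known ground truth.  Two generators provide it:

* :func:`render_phantom` builds an axial CT stack containing
  high-attenuation ellipsoidal "stones" on a soft-tissue background,
  with configurable Gaussian noise and partial-volume blur.  The
  manifest records every stone's exact analytic volume
  (pi/6 * d1 * d2 * d3).
* :func:`simulate_cohort` draws a treatment cohort: per-case stone
  volumes from a log-normal, random ellipsoid axes of that volume,
  multiplicative measurement noise, and a binary stone-free outcome
  from a logistic model in true volume.

Neither generator attempts realistic anatomy or reconstruction physics;
stones sit on a homogeneous background.  Default HU values (background
30 +/- 15, stone 800 +/- 100, 0.4 mm blur) are typical renal-stone
contrast on non-contrast CT.

The inside-ellipsoid test uses voxel centers, matching the per-pixel
behaviour of the threshold segmentation being tested; an optional 3x
supersampling flag exists for convergence studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from stonevol.ct_io import CTVolume
from stonevol.errors import DomainError, GeometryError


@dataclass(frozen=True)
class StoneSpec:
    """An ellipsoidal stone with analytically known geometry.

    ``diameters_mm`` are full axis lengths ``(d1, d2, d3)`` along the
    ellipsoid's principal axes (z, y, x before rotation); ``rotation``
    is intrinsic Euler angles in degrees (z-y-x convention).
    """

    center_mm: tuple[float, float, float]  # (z, y, x)
    diameters_mm: tuple[float, float, float]
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stone_hu_mean: float = 800.0
    stone_hu_sd: float = 100.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameters_mm):
            raise DomainError(f"stone diameters must be positive, got {self.diameters_mm}")

    @property
    def analytic_volume_mm3(self) -> float:
        """Exact ellipsoid volume pi/6 * d1 * d2 * d3."""
        d1, d2, d3 = self.diameters_mm
        return math.pi / 6.0 * d1 * d2 * d3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model of one synthetic CT volume."""

    grid_shape: tuple[int, int, int] = (40, 96, 96)  # (slices, rows, cols)
    pixel_spacing: tuple[float, float] = (0.7, 0.7)
    slice_thickness: float = 2.0
    stones: tuple[StoneSpec, ...] = ()
    background_hu_mean: float = 30.0
    background_hu_sd: float = 15.0
    blur_sigma_mm: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stones", tuple(self.stones))
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0 or self.slice_thickness <= 0:
            raise DomainError("spacings must be positive")
        if self.blur_sigma_mm < 0 or self.background_hu_sd < 0:
            raise DomainError("blur sigma and noise SD must be non-negative")
        extent = (
            self.grid_shape[0] * self.slice_thickness,
            self.grid_shape[1] * self.pixel_spacing[0],
            self.grid_shape[2] * self.pixel_spacing[1],
        )
        for stone in self.stones:
            # bounding-sphere check: stone must lie inside the physical grid
            r = max(stone.diameters_mm) / 2.0
            for c, e in zip(stone.center_mm, extent):
                if c - r < 0 or c + r > e:
                    raise GeometryError(
                        f"stone at {stone.center_mm} mm (max radius {r} mm) "
                        f"exceeds grid extent {extent} mm"
                    )
            if stone.stone_hu_mean <= self.background_hu_mean:
                raise DomainError("stone HU mean must exceed background HU mean")


def _inside_fraction(spec: PhantomSpec, stone: StoneSpec, supersample: int = 1) -> np.ndarray:
    """Per-voxel inside-ellipsoid indicator (supersample=1) or occupancy fraction."""
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.slice_thickness, spec.pixel_spacing[0], spec.pixel_spacing[1]
    rot = Rotation.from_euler("zyx", stone.rotation_deg, degrees=True).as_matrix()
    radii = np.array(stone.diameters_mm) / 2.0
    center = np.array(stone.center_mm)

    if supersample == 1:
        offsets = [np.array([0.5]), np.array([0.5]), np.array([0.5])]
    else:
        s = supersample
        sub = (np.arange(s) + 0.5) / s
        offsets = [sub, sub, sub]

    acc = np.zeros(spec.grid_shape)
    for oz in offsets[0]:
        for oy in offsets[1]:
            for ox in offsets[2]:
                z = (np.arange(nz) + oz) * dz - center[0]
                y = (np.arange(ny) + oy) * dy - center[1]
                x = (np.arange(nx) + ox) * dx - center[2]
                zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
                pts = np.stack([zz, yy, xx])
                # rotate world coords into the ellipsoid frame
                local = np.einsum("ji,jabc->iabc", rot, pts)
                q = (
                    (local[0] / radii[0]) ** 2
                    + (local[1] / radii[1]) ** 2
                    + (local[2] / radii[2]) ** 2
                )
                acc += q <= 1.0
    return acc / (len(offsets[0]) * len(offsets[1]) * len(offsets[2]))


def render_phantom(
    spec: PhantomSpec, supersample: int = 1
) -> tuple[CTVolume, dict]:
    """Render a phantom CT volume and its ground-truth manifest.

    Voxels whose centers fall inside a stone take that stone's mean HU
    (plus per-voxel Gaussian noise at the stone SD); all others take the
    background mean (plus noise at the background SD).  Noise is added
    before the Gaussian partial-volume blur, mimicking reconstruction
    smoothing of detector noise.  Deterministic for a fixed seed.

    Returns the volume and a manifest listing every stone's diameters,
    center and exact analytic volume.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    hu = np.full(spec.grid_shape, spec.background_hu_mean, dtype=float)
    if spec.background_hu_sd > 0:
        hu += rng.normal(0.0, spec.background_hu_sd, size=spec.grid_shape)

    manifest_stones = []
    for stone in spec.stones:
        frac = _inside_fraction(spec, stone, supersample=supersample)
        inside = frac > 0.5 if supersample > 1 else frac >= 0.5
        stone_hu = np.full(spec.grid_shape, stone.stone_hu_mean)
        if stone.stone_hu_sd > 0:
            stone_hu += rng.normal(0.0, stone.stone_hu_sd, size=spec.grid_shape)
        hu = np.where(inside, stone_hu, hu)
        manifest_stones.append(
            {
                "center_mm": list(stone.center_mm),
                "diameters_mm": list(stone.diameters_mm),
                "rotation_deg": list(stone.rotation_deg),
                "analytic_volume_mm3": stone.analytic_volume_mm3,
                "inside_voxel_count": int(inside.sum()),
            }
        )

    if spec.blur_sigma_mm > 0:
        sigma_vox = (
            spec.blur_sigma_mm / spec.slice_thickness,
            spec.blur_sigma_mm / spec.pixel_spacing[0],
            spec.blur_sigma_mm / spec.pixel_spacing[1],
        )
        hu = gaussian_filter(hu, sigma=sigma_vox)

    volume = CTVolume(
        voxels=hu,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        slice_positions=tuple(
            (i + 0.5) * spec.slice_thickness for i in range(nz)
        ),
        series_id=f"phantom-{spec.seed}",
    )
    manifest = {"stones": manifest_stones, "seed": spec.seed}
    return volume, manifest


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated SWL treatment cohort.

    Defaults emulate a 72-case renal-stone cohort: log-normal stone
    volumes with median ~113 mm3 and quartiles ~62-276 mm3
    (log-mean 4.73, log-SD 1.1), a per-mm3 odds ratio of ~0.994 for a
    stone-free outcome (slope -0.006 per mm3) and ~44% stone-free rate
    at the median volume, with 5% multiplicative measurement noise.
    """

    n_cases: int = 72
    log_volume_mean: float = 4.73  # log mm3
    log_volume_sd: float = 1.1
    intercept: float = 0.45
    slope_per_mm3: float = -0.006
    measurement_noise_sd: float = 0.05  # fraction of the true value
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise DomainError("n_cases must be >= 1")
        if self.measurement_noise_sd < 0:
            raise DomainError("measurement_noise_sd must be >= 0")


def _axes_of_volume(volume_mm3: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random ellipsoid axes (a >= c >= b) with pi/6*a*b*c = volume.

    Axis ratios are drawn log-normally (log-SD 0.25) around a sphere,
    then rescaled so the scalene product matches the target volume.
    """
    n = len(volume_mm3)
    ratios = np.exp(rng.normal(0.0, 0.25, size=(n, 3)))
    prod = ratios.prod(axis=1)
    scale = (6.0 * volume_mm3 / (math.pi * prod)) ** (1.0 / 3.0)
    axes = ratios * scale[:, None]
    axes.sort(axis=1)  # ascending: b, c, a
    return axes[:, ::-1][:, [0, 2, 1]]  # columns (a, b, c)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a treatment cohort table.

    Columns: ``case_id``, ``true_volume_mm3``, measured ellipsoid axes
    ``axis_a_mm`` >= ``axis_c_mm`` >= ``axis_b_mm``, the noisy burden
    measures ``volume_mm3``, ``major_axis_mm``, ``vertical_axis_mm``,
    ``slice_area_mm2``, and the binary ``stone_free`` outcome (1 =
    stone-free) drawn with probability
    ``logistic(intercept + slope * true_volume)``.

    With ``measurement_noise_sd = 0`` measured values equal the truth
    exactly.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    true_volume = np.exp(
        rng.normal(spec.log_volume_mean, spec.log_volume_sd, size=spec.n_cases)
    )
    axes = _axes_of_volume(true_volume, rng)  # true (a, b, c)

    def noisy(x: np.ndarray) -> np.ndarray:
        if spec.measurement_noise_sd == 0:
            return x.copy()
        return x * (1.0 + rng.normal(0.0, spec.measurement_noise_sd, size=x.shape))

    # measured diameters are re-labelled after noise: the largest
    # measured value is reported as a, the smallest as b
    meas_axes = np.sort(noisy(axes), axis=1)[:, ::-1][:, [0, 2, 1]]  # (a, b, c)
    meas_volume = noisy(true_volume)
    # largest axial cross-section of the ellipsoid: pi/4 * a * c
    slice_area = noisy(math.pi / 4.0 * axes[:, 0] * axes[:, 2])

    eta = spec.intercept + spec.slope_per_mm3 * true_volume
    p_free = 1.0 / (1.0 + np.exp(-eta))
    stone_free = (rng.uniform(size=spec.n_cases) < p_free).astype(int)

    return pd.DataFrame(
        {
            "case_id": [f"case-{i:04d}" for i in range(spec.n_cases)],
            "true_volume_mm3": true_volume,
            "axis_a_mm": meas_axes[:, 0],
            "axis_b_mm": meas_axes[:, 1],
            "axis_c_mm": meas_axes[:, 2],
            "volume_mm3": meas_volume,
            "major_axis_mm": meas_axes[:, 0],
            "vertical_axis_mm": meas_axes[:, 2],
            "slice_area_mm2": slice_area,
            "stone_free": stone_free,
        }
    )


def write_phantom_dicom(volume: CTVolume, directory: str | Path) -> None:
    """Write a :class:`CTVolume` as a single-frame DICOM CT series.

    One file per slice with correct PixelSpacing, SliceThickness,
    ImagePositionPatient and rescale attributes (intercept -1024,
    slope 1); HU are stored as unsigned 16-bit with the inverse affine,
    so :func:`stonevol.ct_io.read_dicom_series` round-trips integer HU
    grids exactly.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    series_uid = generate_uid()
    study_uid = generate_uid()
    intercept = -1024.0
    stored = np.rint(volume.voxels - intercept)
    if stored.min() < 0 or stored.max() > 65535:
        raise DomainError("HU range not representable as 16-bit stored values")
    stored = stored.astype(np.uint16)

    for i in range(volume.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(volume.slice_positions[i])]
        ds.SliceLocation = float(volume.slice_positions[i])
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = volume.slice_thickness
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = 1.0
        ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[i].tobytes()
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)
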