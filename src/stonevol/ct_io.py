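"""Reading CT image stacks into calibrated Hounsfield-unit volumes.

A :class:`CTVolume` is the raw input to stone segmentation: a 3D grid of
HU values in ``(slice, row, col)`` order plus the physical metadata the
voxel-count volume formula needs (in-plane pixel spacing and slice
thickness, both in mm).  Two input routes produce identical volumes for
the same data: a single-frame DICOM series and a "raw bundle"
(platform-neutral ``.npy`` array plus a JSON metadata sidecar).

Axis convention: "horizontal" is the column direction and "vertical" is
the row direction of the axial image, matching radiological display.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

from stonevol.errors import AmbiguousSeriesError, GeometryError, NoInputError

logger = logging.getLogger(__name__)

METRICS_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CTVolume:
    """A physically calibrated CT volume.

    Parameters
    ----------
    voxels
        3D array of HU values, axis order ``(slice, row, col)``.  Stored
        as floating point after the DICOM rescale; never re-quantized.
    pixel_spacing
        In-plane spacing ``(row_mm, col_mm)`` in millimetres.
    slice_thickness
        Reconstruction slice thickness in millimetres.
    slice_positions
        Craniocaudal position of each slice in mm, strictly monotonic,
        one entry per slice.
    series_id
        Opaque identifier of the originating series.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    slice_positions: tuple[float, ...]
    series_id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(
            self, "pixel_spacing", (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        )
        object.__setattr__(self, "slice_thickness", float(self.slice_thickness))
        object.__setattr__(
            self, "slice_positions", tuple(float(p) for p in self.slice_positions)
        )
        if vox.ndim != 3 or vox.shape[0] < 1:
            raise GeometryError(f"voxel grid must be 3D with >= 1 slice, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise GeometryError("voxel grid contains non-finite HU values")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise GeometryError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        if self.slice_thickness <= 0:
            raise GeometryError(f"slice thickness must be positive, got {self.slice_thickness}")
        if len(self.slice_positions) != vox.shape[0]:
            raise GeometryError(
                f"{len(self.slice_positions)} slice positions for {vox.shape[0]} slices"
            )
        diffs = np.diff(self.slice_positions)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise GeometryError("slice positions are not strictly monotonic")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel: row_mm x col_mm x thickness."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] * self.slice_thickness


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read a single-frame DICOM CT series into a :class:`CTVolume`.

    Stored values are converted to HU with the per-image affine rescale
    ``HU = stored * RescaleSlope + RescaleIntercept``.  Slices are
    sorted by craniocaudal position (ImagePositionPatient z, falling
    back to SliceLocation, then InstanceNumber), so the result does not
    depend on file order on disk.

    Slice thickness is taken from the SliceThickness attribute; when it
    is absent, the median inter-slice position difference is used.  A
    warning is logged when the two disagree by more than 10%.
    """
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.iterdir()) if directory.is_dir() else []:
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError, struct.error):
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if not datasets:
        raise NoInputError(f"no readable single-frame CT images in {directory}")

    series_ids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_ids) > 1:
        raise AmbiguousSeriesError(
            f"directory {directory} mixes {len(series_ids)} series: {sorted(series_ids)}"
        )

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise GeometryError(f"inconsistent in-plane dimensions across slices: {sorted(shapes)}")

    def position(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        loc = getattr(ds, "SliceLocation", None)
        if loc is not None:
            return float(loc)
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=position)
    positions = [position(ds) for ds in datasets]

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(float) * slope + intercept)
    voxels = np.stack(slices, axis=0)

    ref = datasets[0]
    spacing = getattr(ref, "PixelSpacing", None)
    if spacing is None:
        raise GeometryError("series lacks PixelSpacing")
    pixel_spacing = (float(spacing[0]), float(spacing[1]))

    gap = float(np.median(np.abs(np.diff(positions)))) if len(positions) > 1 else None
    thickness_attr = getattr(ref, "SliceThickness", None)
    if thickness_attr is not None and float(thickness_attr) > 0:
        slice_thickness = float(thickness_attr)
        if gap and abs(gap - slice_thickness) > 0.1 * slice_thickness:
            logger.warning(
                "SliceThickness %.3f mm disagrees with inter-slice gap %.3f mm by > 10%%",
                slice_thickness,
                gap,
            )
    elif gap:
        slice_thickness = gap
    else:
        raise GeometryError("cannot determine slice thickness: no attribute and a single slice")

    return CTVolume(
        voxels=voxels,
        pixel_spacing=pixel_spacing,
        slice_thickness=slice_thickness,
        slice_positions=tuple(positions),
        series_id=series_ids.pop(),
    )


def read_raw_bundle(volume_file: str | Path, metadata_file: str | Path) -> CTVolume:
    """Read a raw-volume bundle: an ``.npy`` HU grid plus JSON metadata.

    The metadata document holds ``pixel_spacing`` ([row_mm, col_mm]),
    ``slice_thickness`` and ``slice_positions``.  Content is identical
    to what :func:`read_dicom_series` yields for the same phantom.
    """
    voxels = np.load(Path(volume_file))
    with open(metadata_file) as fh:
        meta = json.load(fh)
    positions = meta["slice_positions"]
    if voxels.ndim != 3 or len(positions) != voxels.shape[0]:
        raise GeometryError(
            f"metadata declares {len(positions)} slices but grid has shape {voxels.shape}"
        )
    return CTVolume(
        voxels=voxels.astype(float),
        pixel_spacing=tuple(meta["pixel_spacing"]),
        slice_thickness=meta["slice_thickness"],
        slice_positions=tuple(positions),
        series_id=str(meta.get("series_id", "")),
    )


def write_raw_bundle(volume: CTVolume, volume_file: str | Path, metadata_file: str | Path) -> None:
    """Write a :class:`CTVolume` as an ``.npy`` grid + JSON metadata."""
    np.save(Path(volume_file), volume.voxels)
    meta = {
        "pixel_spacing": list(volume.pixel_spacing),
        "slice_thickness": volume.slice_thickness,
        "slice_positions": list(volume.slice_positions),
        "series_id": volume.series_id,
    }
    with open(metadata_file, "w") as fh:
        json.dump(meta, fh, indent=2)


def write_metrics(metrics: Sequence, out: str | Path) -> None:
    """Write per-stone metrics as a versioned JSON document.

    One record per stone, in input order; all fields are in mm, mm² or
    mm³ as their names state.
    """
    records = []
    for m in metrics:
        records.append(
            {
                "stone_id": m.stone_id,
                "voxel_count": m.voxel_count,
                "volume_mm3": m.volume_mm3,
                "major_horizontal_axis_mm": m.major_horizontal_axis_mm,
                "major_vertical_axis_mm": m.major_vertical_axis_mm,
                "largest_slice_area_mm2": m.largest_slice_area_mm2,
                "largest_slice_index": m.largest_slice_index,
                "craniocaudal_extent_mm": m.craniocaudal_extent_mm,
            }
        )
    doc = {"schema_version": METRICS_SCHEMA_VERSION, "stones": records}
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_metrics(path: str | Path) -> list:
    """Read back a metrics JSON document written by :func:`write_metrics`."""
    from stonevol.morphometry import StoneMetrics

    with open(path) as fh:
        doc = json.load(fh)
    return [StoneMetrics(**rec) for rec in doc["stones"]]
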