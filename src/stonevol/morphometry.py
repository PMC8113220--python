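"""Per-stone burden measures and manual ellipsoid volume estimators.

The automated measures mirror what clinical stone-volumetry software
reports for each segmented stone: the total voxel (pixel) count, the
voxel-count volume

    V = N * row_spacing * col_spacing * slice_thickness,

the major horizontal and vertical axis lengths and cross-sectional
area on the largest axial slice, and the craniocaudal extent.  In-plane
axes are axis-aligned bounding-box extents in whole pixels
((max index - min index + 1) * spacing) — the manual protocol measures
maximum diameters along the image x and y axes, and automated and
manual measures must share that convention to be comparable.

The manual estimators are the three ellipsoid volume formulas applied
to three measured diameters a >= c >= b (a largest, b smallest):

    scalene  pi/6 * a * b * c
    oblate   pi/6 * a * a * c
    prolate  pi/6 * a * b * b

Under this ordering oblate >= scalene >= prolate is an algebraic
identity, matching the ordering observed empirically when all three
are applied to the same stones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from stonevol.ct_io import CTVolume
from stonevol.errors import DomainError, GeometryError, UnknownLabelError
from stonevol.segmentation import StoneLabelMap


@dataclass(frozen=True)
class StoneMetrics:
    """Burden measures for one stone (or residual fragment).

    All lengths in mm, areas in mm², volumes in mm³.  Records measured
    automatically carry every field; records transcribed from a manual
    protocol may carry only an axis and a volume, with the remaining
    fields ``None``.
    """

    stone_id: int | str
    major_horizontal_axis_mm: float
    volume_mm3: float
    voxel_count: int | None = None
    major_vertical_axis_mm: float | None = None
    largest_slice_area_mm2: float | None = None
    largest_slice_index: int | None = None
    craniocaudal_extent_mm: float | None = None

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0 or self.major_horizontal_axis_mm <= 0:
            raise DomainError("axis and volume must be positive for a non-empty stone")


@dataclass(frozen=True)
class AxisTriple:
    """Three measured stone diameters, ordered a >= c >= b > 0 (mm)."""

    a: float  # largest diameter
    b: float  # smallest diameter
    c: float  # middle diameter

    def __post_init__(self) -> None:
        if not (self.a >= self.c >= self.b > 0):
            raise DomainError(f"require a >= c >= b > 0, got a={self.a}, b={self.b}, c={self.c}")


@dataclass(frozen=True)
class EllipsoidEstimates:
    """The three manual ellipsoid volume estimates (mm³)."""

    scalene_mm3: float
    oblate_mm3: float
    prolate_mm3: float


def make_axis_triple(d1: float, d2: float, d3: float) -> AxisTriple:
    """Order three measured diameters into an :class:`AxisTriple`.

    ``a`` is the largest, ``b`` the smallest, ``c`` the middle value;
    permutation-invariant in the inputs.
    """
    if min(d1, d2, d3) <= 0:
        raise DomainError(f"diameters must be positive, got ({d1}, {d2}, {d3})")
    b, c, a = sorted((float(d1), float(d2), float(d3)))
    return AxisTriple(a=a, b=b, c=c)


def ellipsoid_volumes(axes: AxisTriple) -> EllipsoidEstimates:
    """Evaluate the scalene, oblate and prolate ellipsoid formulas."""
    k = math.pi / 6.0
    return EllipsoidEstimates(
        scalene_mm3=k * axes.a * axes.b * axes.c,
        oblate_mm3=k * axes.a * axes.a * axes.c,
        prolate_mm3=k * axes.a * axes.b * axes.b,
    )


def measure_stone(volume: CTVolume, labels: StoneLabelMap, stone_id: int) -> StoneMetrics:
    """Compute all automated burden measures for one labelled stone.

    The volume is the voxel count times the physical voxel volume.
    In-plane axes and cross-sectional area are taken on the largest
    slice (the axial slice with the most stone pixels; ties broken by
    the lowest slice index).
    """
    if labels.labels.shape != volume.voxels.shape:
        raise GeometryError("label map and volume shapes differ")
    stone = labels.labels == stone_id
    voxel_count = int(stone.sum())
    if stone_id not in labels.stone_ids or voxel_count == 0:
        raise UnknownLabelError(f"stone_id {stone_id} not present in label map")

    row_mm, col_mm = volume.pixel_spacing
    per_slice = stone.sum(axis=(1, 2))
    largest_slice = int(np.argmax(per_slice))  # argmax takes the lowest index on ties

    sl = stone[largest_slice]
    rows = np.flatnonzero(sl.any(axis=1))
    cols = np.flatnonzero(sl.any(axis=0))
    slices = np.flatnonzero(per_slice)

    return StoneMetrics(
        stone_id=int(stone_id),
        voxel_count=voxel_count,
        volume_mm3=voxel_count * volume.voxel_volume_mm3,
        major_horizontal_axis_mm=(cols[-1] - cols[0] + 1) * col_mm,
        major_vertical_axis_mm=(rows[-1] - rows[0] + 1) * row_mm,
        largest_slice_area_mm2=int(sl.sum()) * row_mm * col_mm,
        largest_slice_index=largest_slice,
        craniocaudal_extent_mm=(slices[-1] - slices[0] + 1) * volume.slice_thickness,
    )


def measure_all(volume: CTVolume, labels: StoneLabelMap) -> list[StoneMetrics]:
    """Measure every stone in a label map, in label order."""
    return [measure_stone(volume, labels, sid) for sid in labels.stone_ids]


def total_burden(metrics: Iterable[StoneMetrics]) -> tuple[float, int, float]:
    """Aggregate burden over stones: (total volume mm³, total voxels, max major axis mm).

    Summing the volumes of all stones to be treated gives the total
    burden of a multi-stone case; an empty list yields zeros.  Records
    without a voxel count contribute 0 to the voxel total.
    """
    metrics = list(metrics)
    total_volume = sum(m.volume_mm3 for m in metrics)
    total_voxels = sum(m.voxel_count or 0 for m in metrics)
    max_axis = max((m.major_horizontal_axis_mm for m in metrics), default=0.0)
    return (total_volume, total_voxels, max_axis)
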