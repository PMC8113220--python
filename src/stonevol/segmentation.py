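"""Semi-automated stone delineation: HU threshold + instance labelling.

The delineation step mirrors the semi-automated workflow of clinical
stone-volumetry software: the operator chooses a Hounsfield-unit
threshold separating stone from surrounding tissue and urine, the
software populates a region of interest (ROI) on every axial slice that
includes the stone, and connected voxels are grouped into individual
stones.

The threshold comparison is inclusive (``HU >= threshold``) so boundary
behaviour is deterministic, and no morphological post-processing is
applied — anything beyond pure thresholding would change the measured
volume.  Labelling is fully 3D (components may span slices); the
default 26-neighbourhood keeps a stone whose in-plane footprint shifts
by less than a voxel between slices as a single object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from stonevol.ct_io import CTVolume
from stonevol.errors import DomainError, GeometryError

#: calcification threshold conventional in CT; overridable per case
DEFAULT_HU_THRESHOLD = 130.0


@dataclass(frozen=True)
class SegmentationParams:
    """Operator-facing parameters of the delineation step.

    ``connectivity`` is 6 (face neighbours only) or 26 (face + edge +
    corner); components with fewer than ``min_voxels`` voxels are
    discarded as noise speckle (set 1 to disable).
    """

    hu_threshold: float = DEFAULT_HU_THRESHOLD
    connectivity: int = 26
    min_voxels: int = 2

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise DomainError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.min_voxels < 1:
            raise DomainError("min_voxels must be >= 1")


@dataclass(frozen=True)
class StoneLabelMap:
    """Instance labels congruent with the source volume.

    ``labels`` holds 0 for background and k for stone k; labels run
    1..n_stones by decreasing voxel count.
    """

    labels: np.ndarray
    n_stones: int
    params_used: SegmentationParams

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels).tolist())
        allowed = set(range(self.n_stones + 1))
        required = set(range(1, self.n_stones + 1))
        if not present <= allowed or not required <= present:
            raise GeometryError(
                f"labels must be exactly {{0..{self.n_stones}}} (each stone non-empty), "
                f"got {sorted(present)}"
            )

    def voxel_count(self, stone_id: int) -> int:
        return int(np.count_nonzero(self.labels == stone_id))

    @property
    def stone_ids(self) -> list[int]:
        return list(range(1, self.n_stones + 1))


def threshold_mask(volume: CTVolume, params: SegmentationParams) -> np.ndarray:
    """Binary mask of voxels that could represent stone: HU >= threshold."""
    return volume.voxels >= params.hu_threshold


def label_stones(mask: np.ndarray, params: SegmentationParams) -> StoneLabelMap:
    """Group a threshold mask into individual stones.

    Connected components under ``params.connectivity``; components
    smaller than ``min_voxels`` are discarded; survivors are relabelled
    1..n by decreasing voxel count, ties broken by the smallest
    ``(slice, row, col)`` of the component's first voxel.
    """
    structure = ndimage.generate_binary_structure(3, 1 if params.connectivity == 6 else 3)
    raw_labels, n_raw = ndimage.label(mask, structure=structure)

    keep: list[tuple[int, int, int]] = []  # (-count, first_flat_index, raw_label)
    if n_raw:
        counts = np.bincount(raw_labels.ravel(), minlength=n_raw + 1)
        flat = raw_labels.ravel()
        # first (smallest flat index == lexicographic (slice,row,col)) voxel per label
        order = np.argsort(flat, kind="stable")
        firsts = np.searchsorted(flat[order], np.arange(1, n_raw + 1))
        for lab in range(1, n_raw + 1):
            if counts[lab] >= params.min_voxels:
                keep.append((-int(counts[lab]), int(order[firsts[lab - 1]]), lab))
    keep.sort()

    relabelled = np.zeros_like(raw_labels)
    for new_id, (_, _, old) in enumerate(keep, start=1):
        relabelled[raw_labels == old] = new_id

    return StoneLabelMap(labels=relabelled, n_stones=len(keep), params_used=params)


def segment(volume: CTVolume, params: SegmentationParams | None = None) -> StoneLabelMap:
    """Threshold and label in one step."""
    params = params or SegmentationParams()
    return label_stones(threshold_mask(volume, params), params)
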