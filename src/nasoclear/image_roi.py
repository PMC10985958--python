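"""Semi-automatic ROI segmentation and mask-based TAC extraction.

The turbinate segmentation procedure mirrors a simple, reproducible reading
of the semi-automatic workflow: place a bounding box around a turbinate on a
structural volume, discard the lowest intensity quartile inside the box
(air-like voxels), then grow 6-connected regions from small spherical seeds
within the retained tissue, one voxel layer per cycle, up to 10,000 cycles.
A fixed-extent box ROI covers the cribriform plate, and per-frame mask means
extract regional TACs from 4D dynamic volumes.

Conventions: voxel indices are 0-based, bounding boxes are half-open
``[lower, upper)``, connectivity is the 6-neighborhood, and the quartile is
the nearest-rank 25th percentile with ties excluded by a strict ``>`` cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import nibabel as nib
import numpy as np
from scipy import ndimage

from .schedule import FrameSchedule
from .tac_processing import RegionTAC

__all__ = [
    "Volume3D",
    "BoundingBox",
    "Seed",
    "quartile_threshold",
    "region_grow",
    "box_roi",
    "extract_tac",
    "dice",
    "segment_turbinate",
    "load_volume",
    "save_mask",
]


@dataclass
class Volume3D:
    """A scalar 3D image with physical voxel spacing in mm."""

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel spacings must be positive")


@dataclass(frozen=True)
class BoundingBox:
    """Half-open voxel-index box ``[lower, upper)`` per axis."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(lo >= hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError("box must satisfy lower < upper on every axis")
        if any(lo < 0 for lo in self.lower):
            raise ValueError("box lower corner must be nonnegative")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))


@dataclass(frozen=True)
class Seed:
    """A spherical seed: center voxel index and physical radius in mm."""

    center: tuple[int, int, int]
    radius_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")


def _check_box(vol: Volume3D, box: BoundingBox) -> None:
    if any(hi > s for hi, s in zip(box.upper, vol.intensities.shape)):
        raise ValueError("bounding box extends outside the volume")


def nearest_rank_quartile(values: np.ndarray, q: float = 0.25) -> float:
    """Nearest-rank percentile: the ``ceil(q n)``-th smallest value."""
    v = np.sort(np.asarray(values).ravel())
    if v.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    rank = max(1, ceil(q * v.size))
    return float(v[rank - 1])


def quartile_threshold(vol: Volume3D, box: BoundingBox) -> np.ndarray:
    """High-pass mask: in-box voxels strictly above the in-box lowest
    quartile (nearest-rank convention), removing air-like voxels."""
    _check_box(vol, box)
    sub = vol.intensities[box.slices()]
    if sub.size == 0:
        raise ValueError("empty bounding box")
    q1 = nearest_rank_quartile(sub, 0.25)
    mask = np.zeros(vol.intensities.shape, dtype=bool)
    mask[box.slices()] = sub > q1
    return mask


def _seed_mask(shape, seeds, voxel_size_mm) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    spacing = np.asarray(voxel_size_mm, dtype=float)
    for seed in seeds:
        center = np.asarray(seed.center, dtype=int)
        if np.any(center < 0) or np.any(center >= np.array(shape)):
            raise ValueError(f"seed center {seed.center} outside the volume")
        half = np.ceil(seed.radius_mm / spacing).astype(int)
        lo = np.maximum(center - half, 0)
        hi = np.minimum(center + half + 1, shape)
        grids = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = sum(((grids[a] - center[a]) * spacing[a]) ** 2 for a in range(3))
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= seed.radius_mm**2
    return mask


def region_grow(allowed: np.ndarray, seeds, voxel_size_mm=(1.0, 1.0, 1.0),
                max_cycles: int = 10000) -> np.ndarray:
    """Seeded growth restricted to ``allowed``.

    Starts from the voxels of the seed spheres that lie inside ``allowed``
    and dilates by one 6-connected voxel layer per cycle, stopping at
    convergence or after ``max_cycles`` cycles.  Equivalent, at convergence,
    to the union of connected components of ``allowed`` touched by a seed.
    """
    allowed = np.asarray(allowed, dtype=bool)
    current = _seed_mask(allowed.shape, seeds, voxel_size_mm) & allowed
    if not current.any():
        warnings.warn("no seed voxel lies inside the allowed mask; "
                      "returning an empty mask", stacklevel=2)
        return current
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    for _ in range(max_cycles):
        grown = ndimage.binary_dilation(current, structure=struct,
                                        mask=allowed)
        if np.array_equal(grown, current):
            break
        current = grown
    return current


def box_roi(vol: Volume3D, center: tuple[int, int, int],
            extent_mm: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned box mask of at most the given physical extents,
    centered on ``center`` and clipped to the volume."""
    shape = vol.intensities.shape
    center = np.asarray(center, dtype=int)
    if np.any(center < 0) or np.any(center >= np.array(shape)):
        raise ValueError("center must lie inside the volume")
    if any(e <= 0 for e in extent_mm):
        raise ValueError("extents must be positive")
    spacing = np.asarray(vol.voxel_size_mm, dtype=float)
    n_vox = np.maximum(np.floor(np.asarray(extent_mm) / spacing), 1).astype(int)
    lo = np.maximum(center - (n_vox - 1) // 2, 0)
    hi = np.minimum(lo + n_vox, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return mask


def extract_tac(pet4d: np.ndarray, mask: np.ndarray,
                schedule: FrameSchedule, region: str = "roi",
                subject_id: str = "unknown") -> RegionTAC:
    """Per-frame unweighted mean over the mask voxels of a 4D volume."""
    pet4d = np.asarray(pet4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pet4d.ndim != 4:
        raise ValueError("pet4d must be a 4D (x, y, z, frame) array")
    if mask.shape != pet4d.shape[:3]:
        raise ValueError("mask shape must match the spatial dimensions")
    if pet4d.shape[3] != schedule.n_frames:
        raise ValueError("frame count must match the schedule")
    if not mask.any():
        raise ValueError("cannot extract a TAC from an empty mask")
    values = pet4d[mask].mean(axis=0)
    return RegionTAC(region=region, subject_id=subject_id,
                     frame_mid_s=schedule.midpoints_s, values=values)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|a n b| / (|a| + |b|)`` of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one volume domain")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def segment_turbinate(vol: Volume3D, box: BoundingBox, seeds,
                      max_cycles: int = 10000) -> np.ndarray:
    """Full semi-automatic pipeline: quartile high-pass inside the bounding
    box, then seeded region growing within the retained tissue."""
    allowed = quartile_threshold(vol, box)
    return region_grow(allowed, seeds, vol.voxel_size_mm, max_cycles)


# -- NIfTI I/O -----------------------------------------------------------

def load_volume(path) -> Volume3D:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(img.dataobj, dtype=float), spacing)


def save_mask(path, mask: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine), str(path))
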