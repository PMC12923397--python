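"""Contiguity filtering, voxel volumes, en-face projection and ETDRS regions.

Volumes are computed by counting mask voxels and multiplying by the known
physical voxel volume.  Regional assignment partitions the 3D mask by
A-scan column against an ETDRS grid (central subfield < 0.5 mm, inner ring
0.5-1.5 mm, outer ring 1.5-3 mm from the fovea center, half-open annuli);
depth-stacked foci within one column are therefore never collapsed.  The
scan corners outside the 3 mm radius count toward the total only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from hefq.core import HRFMask, ScanGeometry

__all__ = [
    "contiguity_filter",
    "mask_volume",
    "project_enface",
    "ProjectionMap",
    "ETDRSRegionMap",
    "build_etdrs_grid",
    "RegionalVolumeRecord",
    "regional_volumes",
    "regional_enface_areas",
]

# Region label codes in an ETDRSRegionMap.
CSF, IR, OR, OUTSIDE = 0, 1, 2, 3
REGION_NAMES = {CSF: "csf", IR: "ir", OR: "or", OUTSIDE: "outside"}

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def contiguity_filter(mask: HRFMask, min_size: int = 3, connectivity: int = 8) -> HRFMask:
    """Drop small connected components within each B-scan independently.

    Components are found in the 2D (axial, ascan) plane of each B-scan —
    never across B-scans — and those with fewer than ``min_size`` pixels are
    removed.  The default keeps runs of three or more contiguous
    hyper-reflective pixels, the standard criterion for calling a cluster a
    hyper-reflective focus.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    if min_size == 1:
        return HRFMask(mask=mask.mask.copy(), geometry=mask.geometry)
    structure = _STRUCTURES[connectivity]
    out = np.zeros_like(mask.mask)
    for b in range(mask.geometry.n_bscans):
        plane = mask.mask[b]
        if not plane.any():
            continue
        labels, n = ndimage.label(plane, structure=structure)
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        keep = counts >= min_size
        keep[0] = False
        out[b] = keep[labels]
    return HRFMask(mask=out, geometry=mask.geometry)


def mask_volume(mask: HRFMask) -> float:
    """Physical volume of a mask in mm^3: voxel count times voxel volume."""
    return mask.n_voxels * mask.geometry.voxel_volume_mm3


@dataclass
class ProjectionMap:
    """En-face map: per-(bscan, ascan) count of segmented voxels in the column."""

    counts: np.ndarray
    geometry: ScanGeometry

    @property
    def total_voxels(self) -> int:
        return int(self.counts.sum())


def project_enface(mask: HRFMask) -> ProjectionMap:
    """Collapse a 3D mask axially into a column-count map (count-conserving)."""
    return ProjectionMap(
        counts=mask.mask.sum(axis=1).astype(np.int32), geometry=mask.geometry
    )


@dataclass
class ETDRSRegionMap:
    """Per-column ETDRS region labels over the en-face plane."""

    labels: np.ndarray  # (n_bscans, n_ascans) of {CSF, IR, OR, OUTSIDE}
    geometry: ScanGeometry
    center_mm: tuple[float, float]  # (fast, slow) position of the fovea
    radii_mm: tuple[float, float, float] = (0.5, 1.5, 3.0)


def build_etdrs_grid(
    geometry: ScanGeometry,
    center_mm: tuple[float, float] | None = None,
    radii_mm: tuple[float, float, float] = (0.5, 1.5, 3.0),
) -> ETDRSRegionMap:
    """Label every A-scan column by its ETDRS region.

    Distance is measured from the column's center point (pixel-center
    convention) to the fovea center, which defaults to the geometric scan
    center.  Annuli are half-open: CSF is ``d < r0``, IR ``r0 <= d < r1``,
    OR ``r1 <= d < r2``, OUTSIDE ``d >= r2`` — every column gets exactly one
    label.
    """
    if center_mm is None:
        center_mm = (
            geometry.lateral_extent_fast_mm / 2.0,
            geometry.lateral_extent_slow_mm / 2.0,
        )
    cx, cy = center_mm
    if not (0 <= cx <= geometry.lateral_extent_fast_mm
            and 0 <= cy <= geometry.lateral_extent_slow_mm):
        raise ValueError(f"fovea center {center_mm} lies outside the scan extent")
    r0, r1, r2 = radii_mm
    if not (0 < r0 < r1 < r2):
        raise ValueError("radii must be strictly increasing and positive")
    x = (np.arange(geometry.n_ascans) + 0.5) * geometry.pitch_fast_mm
    y = (np.arange(geometry.n_bscans) + 0.5) * geometry.pitch_slow_mm
    dist = np.hypot(x[None, :] - cx, y[:, None] - cy)
    labels = np.full(dist.shape, OUTSIDE, dtype=np.int8)
    labels[dist < r2] = OR
    labels[dist < r1] = IR
    labels[dist < r0] = CSF
    return ETDRSRegionMap(
        labels=labels, geometry=geometry, center_mm=(cx, cy), radii_mm=radii_mm
    )


def region_areas_mm2(regions: ETDRSRegionMap) -> dict[str, float]:
    """Pixel-counted en-face area of each region in mm^2."""
    footprint = regions.geometry.column_footprint_mm2
    return {
        name: float((regions.labels == code).sum()) * footprint
        for code, name in REGION_NAMES.items()
    }


@dataclass
class RegionalVolumeRecord:
    """Hard-exudate volume (mm^3) per ETDRS region at one visit of one eye.

    ``total_mm3`` counts every segmented voxel of the scan regardless of
    region label, so ``csf + ir + or + outside == total`` exactly and
    ``csf + ir + or <= total``.  A region is flagged resolved when its
    volume is zero.
    """

    total_mm3: float
    csf_mm3: float
    ir_mm3: float
    or_mm3: float
    outside_mm3: float
    eye_id: str | None = None
    week: int | None = None
    resolved: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.resolved:
            self.resolved = {
                "csf": self.csf_mm3 == 0.0,
                "ir": self.ir_mm3 == 0.0,
                "or": self.or_mm3 == 0.0,
            }


def regional_volumes(
    mask: HRFMask,
    regions: ETDRSRegionMap,
    eye_id: str | None = None,
    week: int | None = None,
) -> RegionalVolumeRecord:
    """Partition a mask's volume over the ETDRS regions by A-scan column."""
    if regions.geometry != mask.geometry:
        raise ValueError("mask and region map geometries differ")
    col_counts = mask.mask.sum(axis=1)  # (n_bscans, n_ascans)
    vv = mask.geometry.voxel_volume_mm3
    per = {
        name: float(col_counts[regions.labels == code].sum()) * vv
        for code, name in REGION_NAMES.items()
    }
    return RegionalVolumeRecord(
        total_mm3=float(col_counts.sum()) * vv,
        csf_mm3=per["csf"],
        ir_mm3=per["ir"],
        or_mm3=per["or"],
        outside_mm3=per["outside"],
        eye_id=eye_id,
        week=week,
    )


def regional_enface_areas(mask: HRFMask, regions: ETDRSRegionMap) -> dict[str, float]:
    """Sensitivity variant: en-face footprint area (mm^2) of HRF per region.

    Collapses the mask axially to a binary en-face map first, so
    depth-stacked foci within one column count once; this is the
    flat-projection reading of regional burden and generally underestimates
    relative to the voxel-volume partition.
    """
    if regions.geometry != mask.geometry:
        raise ValueError("mask and region map geometries differ")
    hit = mask.mask.any(axis=1)
    footprint = mask.geometry.column_footprint_mm2
    return {
        name: float((hit & (regions.labels == code)).sum()) * footprint
        for code, name in REGION_NAMES.items()
    }
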