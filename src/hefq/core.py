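"""Core domain types for OCT hard-exudate quantification.

An OCT macular cube is a stack of B-scans; each B-scan is a row of A-scans
(axial depth profiles).  All 3D grids in this package are indexed
``(bscan, axial, ascan)`` — B-scan index along the slow raster axis, axial
pixel index increasing with depth, A-scan index along the fast raster axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Study visit schedule in weeks after treatment initiation.
WEEKS: tuple[int, ...] = (0, 4, 12, 24, 52)
FOLLOWUP_WEEKS: tuple[int, ...] = (4, 12, 24, 52)

#: ETDRS-grid regions used for regional hard-exudate volumes.
REGIONS: tuple[str, ...] = ("csf", "ir", "or")


@dataclass(frozen=True)
class ScanGeometry:
    """Physical raster description of an OCT volume.

    Defaults follow the Cirrus 512x128 macular cube: 512 A-scans per B-scan
    and 128 B-scans over a 6 x 6 mm field, with a 2 mm axial depth sampled at
    1024 pixels.  The axial pixel count is fully configurable; nothing
    downstream assumes a particular resolution.
    """

    n_ascans: int = 512
    n_bscans: int = 128
    n_axial: int = 1024
    lateral_extent_fast_mm: float = 6.0
    lateral_extent_slow_mm: float = 6.0
    axial_extent_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_ascans", "n_bscans", "n_axial"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("lateral_extent_fast_mm", "lateral_extent_slow_mm", "axial_extent_mm"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape in ``(bscan, axial, ascan)`` order."""
        return (self.n_bscans, self.n_axial, self.n_ascans)

    @property
    def pitch_fast_mm(self) -> float:
        return self.lateral_extent_fast_mm / self.n_ascans

    @property
    def pitch_slow_mm(self) -> float:
        return self.lateral_extent_slow_mm / self.n_bscans

    @property
    def pitch_axial_mm(self) -> float:
        return self.axial_extent_mm / self.n_axial

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return self.pitch_fast_mm * self.pitch_slow_mm * self.pitch_axial_mm

    @property
    def column_footprint_mm2(self) -> float:
        """En-face footprint of one A-scan column in mm^2."""
        return self.pitch_fast_mm * self.pitch_slow_mm

    def to_dict(self) -> dict:
        return {
            "n_ascans": self.n_ascans,
            "n_bscans": self.n_bscans,
            "n_axial": self.n_axial,
            "lateral_extent_fast_mm": self.lateral_extent_fast_mm,
            "lateral_extent_slow_mm": self.lateral_extent_slow_mm,
            "axial_extent_mm": self.axial_extent_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**{k: (int(v) if k.startswith("n_") else float(v)) for k, v in d.items()})


@dataclass
class SurfacePair:
    """ILM and RPE depth maps bounding the analysis band.

    ``ilm`` and ``rpe`` hold axial pixel indices per (bscan, ascan) column,
    with ``0 <= ilm < rpe < n_axial`` everywhere.  ``rpe`` marks the top of
    the RPE reflective complex; the hard-exudate analysis band is the tissue
    between the two surfaces.
    """

    ilm: np.ndarray
    rpe: np.ndarray

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=np.int32)
        self.rpe = np.asarray(self.rpe, dtype=np.int32)
        if self.ilm.shape != self.rpe.shape or self.ilm.ndim != 2:
            raise ValueError("ilm and rpe must be 2D arrays of identical shape")
        if np.any(self.ilm < 0):
            raise ValueError("ilm depths must be >= 0")
        if np.any(self.rpe <= self.ilm):
            raise ValueError("rpe must lie strictly below ilm everywhere")

    def validate_against(self, geometry: ScanGeometry) -> None:
        if self.ilm.shape != (geometry.n_bscans, geometry.n_ascans):
            raise ValueError("surface shape does not match geometry")
        if np.any(self.rpe >= geometry.n_axial):
            raise ValueError("rpe depths exceed axial extent")


@dataclass
class OCTVolume:
    """Intensity cube with its physical geometry and device signal strength."""

    geometry: ScanGeometry
    intensities: np.ndarray
    signal_strength: int = 10

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.shape != self.geometry.shape:
            raise ValueError(
                f"intensity grid shape {self.intensities.shape} does not match "
                f"geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.size and (
            self.intensities.min() < 0.0 or self.intensities.max() > 1.0
        ):
            raise ValueError("intensities must lie in [0, 1]")
        if not 0 <= int(self.signal_strength) <= 10:
            raise ValueError("signal_strength must be in 0..10")


@dataclass
class HRFMask:
    """Binary voxel mask of segmented hyper-reflective foci."""

    mask: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape does not match geometry")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.geometry.voxel_volume_mm3


@dataclass(frozen=True)
class Blob:
    """One planted hyper-reflective focus: ellipsoid in voxel index space."""

    center: tuple[int, int, int]  # (bscan, axial, ascan)
    radii: tuple[float, float, float]  # voxel radii along (bscan, axial, ascan)
    peak: float


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic volume."""

    hrf_mask: np.ndarray
    geometry: ScanGeometry
    blob_catalog: list[Blob] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hrf_mask = np.asarray(self.hrf_mask, dtype=bool)
        if self.hrf_mask.shape != self.geometry.shape:
            raise ValueError("truth mask shape does not match geometry")

    @property
    def n_hrf_voxels(self) -> int:
        return int(self.hrf_mask.sum())

    @property
    def true_volume_mm3(self) -> float:
        return self.n_hrf_voxels * self.geometry.voxel_volume_mm3


#: Columns required in the per-visit table of a cohort.
VISIT_COLUMNS = (
    "eye_id",
    "week",
    "va_letters",
    "cst_um",
    "he_total_mm3",
    "he_csf_mm3",
    "he_ir_mm3",
    "he_or_mm3",
)


@dataclass
class CohortTable:
    """Longitudinal per-eye records: one visit table plus baseline covariates.

    ``visits`` has one row per (eye_id, week) actually observed; a missing
    visit is simply an absent row.  ``covariates`` has one row per eye_id and
    is constant over time by construction.
    """

    visits: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VISIT_COLUMNS if c not in self.visits.columns]
        if missing:
            raise ValueError(f"visit table missing columns: {missing}")
        if self.visits.duplicated(subset=["eye_id", "week"]).any():
            raise ValueError("duplicate (eye_id, week) rows in visit table")
        if "eye_id" not in self.covariates.columns:
            raise ValueError("covariate table must carry eye_id")
        if self.covariates["eye_id"].duplicated().any():
            raise ValueError("duplicate eye_id rows in covariate table")

    @property
    def eye_ids(self) -> list:
        return list(self.covariates["eye_id"])

    @property
    def n_eyes(self) -> int:
        return len(self.covariates)

    def subset(self, eye_ids: Sequence) -> "CohortTable":
        keep = set(eye_ids)
        return CohortTable(
            visits=self.visits[self.visits["eye_id"].isin(keep)].reset_index(drop=True),
            covariates=self.covariates[self.covariates["eye_id"].isin(keep)].reset_index(
                drop=True
            ),
        )
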