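"""Readers and writers for volumes, masks, surfaces and cohort tables.

Volumes and masks are stored as multi-page TIFF (one page per B-scan;
16-bit grayscale for intensities, 8-bit {0, 1} for masks) with a JSON
sidecar holding the scan geometry, signal strength and provenance seed.
Cohorts are stored as a visit CSV (one row per eye and week) plus a
covariate CSV keyed by eye_id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from hefq.core import CohortTable, HRFMask, OCTVolume, ScanGeometry, SurfacePair

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_cohort",
    "read_cohort",
]

_SCALE = 65535.0


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def _read_sidecar(tiff_path: Path) -> dict:
    sidecar = _sidecar_path(tiff_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar: expected {sidecar}")
    with open(sidecar) as fh:
        return json.load(fh)


def _check_pages(pages: np.ndarray, geometry: ScanGeometry, path: Path) -> None:
    if pages.shape != geometry.shape:
        raise ValueError(
            f"{path}: TIFF stack shape {pages.shape} does not match sidecar "
            f"geometry {geometry.shape}"
        )


def write_volume(
    volume: OCTVolume,
    path: str | Path,
    surfaces: SurfacePair | None = None,
    seed: int | None = None,
) -> Path:
    """Write a volume as 16-bit multi-page TIFF + JSON sidecar.

    Intensities are quantized to uint16; a write/read/write cycle is
    bit-stable.  If ``surfaces`` is given, the ILM/RPE depth maps are stored
    in the sidecar.
    """
    path = Path(path)
    data = np.round(volume.intensities.astype(np.float64) * _SCALE).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "kind": "volume",
        "geometry": volume.geometry.to_dict(),
        "signal_strength": int(volume.signal_strength),
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    if surfaces is not None:
        sidecar["ilm"] = surfaces.ilm.tolist()
        sidecar["rpe"] = surfaces.rpe.tolist()
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)
    return path


def read_volume(path: str | Path) -> tuple[OCTVolume, SurfacePair | None]:
    """Read a volume written by :func:`write_volume`.

    Raises
    ------
    FileNotFoundError
        If the JSON sidecar is missing (the error names the expected file).
    ValueError
        If the TIFF page stack is inconsistent with the sidecar geometry.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    geometry = ScanGeometry.from_dict(meta["geometry"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    _check_pages(pages, geometry, path)
    volume = OCTVolume(
        geometry=geometry,
        intensities=(pages.astype(np.float32) / _SCALE),
        signal_strength=int(meta.get("signal_strength", 10)),
    )
    surfaces = None
    if "ilm" in meta and "rpe" in meta:
        surfaces = SurfacePair(ilm=np.asarray(meta["ilm"]), rpe=np.asarray(meta["rpe"]))
    return volume, surfaces


def write_mask(mask: HRFMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit {0,1} multi-page TIFF + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"kind": "mask", "geometry": mask.geometry.to_dict()}, fh)
    return path


def read_mask(path: str | Path) -> HRFMask:
    path = Path(path)
    meta = _read_sidecar(path)
    geometry = ScanGeometry.from_dict(meta["geometry"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    _check_pages(pages, geometry, path)
    return HRFMask(mask=pages.astype(bool), geometry=geometry)


def write_cohort(cohort: CohortTable, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the visit and covariate tables as CSV files under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    visits_path = out_dir / "visits.csv"
    cov_path = out_dir / "covariates.csv"
    cohort.visits.to_csv(visits_path, index=False)
    cohort.covariates.to_csv(cov_path, index=False)
    return visits_path, cov_path


def read_cohort(out_dir: str | Path) -> CohortTable:
    out_dir = Path(out_dir)
    visits = pd.read_csv(out_dir / "visits.csv")
    covariates = pd.read_csv(out_dir / "covariates.csv")
    return CohortTable(visits=visits, covariates=covariates)
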