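"""Synthetic OCT volume generator with planted hyper-reflective foci.

The phantom emulates the features of a macular B-scan stack that the
segmentation pipeline depends on: a dark vitreous above a smoothly varying
ILM surface, a mid-reflective retinal band, a bright RPE complex below the
band, optional hypo-reflective fluid pockets inside the band, additive
speckle-like noise, and bright ellipsoidal HRF blobs planted strictly
between the ILM and RPE with an exact voxel-level ground-truth mask.

It deliberately does not model device optics, motion artifacts or vendor
file formats; it exists so that every downstream stage (surface
delineation, thresholding, contiguity filtering, regional volumes) has a
quantitative oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from hefq.core import Blob, OCTVolume, ScanGeometry, SurfacePair, SyntheticTruth

__all__ = ["VolumeParams", "generate_volume"]


@dataclass(frozen=True)
class VolumeParams:
    """Settings for :func:`generate_volume`.

    Reflectance levels are on the [0, 1] grayscale.  Blob contrast is
    expressed in units of the speckle noise SD above the retinal band level;
    the default of 6 keeps the foci unambiguously bright (the floor for a
    well-posed thresholding task is about 4), while 8 is the high-contrast
    stress setting.
    """

    n_blobs: int = 12
    blob_radius_axial: tuple[float, float] = (2.0, 5.0)
    blob_radius_ascan: tuple[float, float] = (1.5, 3.5)
    blob_radius_bscan: tuple[float, float] = (0.0, 1.0)
    blob_contrast_sd: float = 6.0
    #: Explicit blob catalog; overrides random placement when given.
    blobs: tuple[Blob, ...] | None = None

    noise_sd: float = 0.04
    vitreous_level: float = 0.05
    retina_level: float = 0.40
    sub_rpe_level: float = 0.12
    rpe_level: float = 0.78
    rpe_band_px: int = 2

    #: ILM mean depth and retinal band thickness as fractions of n_axial.
    ilm_depth_frac: float = 0.18
    band_thickness_frac: float = 0.38
    surface_wobble_frac: float = 0.02

    n_fluid: int = 2
    fluid_level: float = 0.08
    #: Fluid pocket radii as fractions of (n_bscans, n_axial, n_ascans).
    fluid_radius_frac: tuple[float, float, float] = (0.04, 0.06, 0.05)

    signal_strength: int = 9

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_blobs < 0 or self.n_fluid < 0:
            raise ValueError("counts must be >= 0")
        if self.blob_contrast_sd <= 0:
            raise ValueError("blob_contrast_sd must be > 0")


def _ellipsoid_voxels(
    center: tuple[int, int, int],
    radii: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices of an axis-aligned ellipsoid clipped to the grid."""
    cb, cz, ca = center
    rb, rz, ra = radii
    b0, b1 = max(0, int(np.floor(cb - rb))), min(shape[0] - 1, int(np.ceil(cb + rb)))
    z0, z1 = max(0, int(np.floor(cz - rz))), min(shape[1] - 1, int(np.ceil(cz + rz)))
    a0, a1 = max(0, int(np.floor(ca - ra))), min(shape[2] - 1, int(np.ceil(ca + ra)))
    bb, zz, aa = np.meshgrid(
        np.arange(b0, b1 + 1), np.arange(z0, z1 + 1), np.arange(a0, a1 + 1), indexing="ij"
    )
    # radius 0 along an axis means the blob occupies a single index there
    rb_, rz_, ra_ = max(rb, 0.5), max(rz, 0.5), max(ra, 0.5)
    inside = ((bb - cb) / rb_) ** 2 + ((zz - cz) / rz_) ** 2 + ((aa - ca) / ra_) ** 2 <= 1.0
    return bb[inside], zz[inside], aa[inside]


def _smooth_surface(
    rng: np.random.Generator, geometry: ScanGeometry, base: float, amp: float
) -> np.ndarray:
    """Low-frequency 2D depth map: base level plus two random sinusoids."""
    a = np.arange(geometry.n_ascans) / geometry.n_ascans
    b = np.arange(geometry.n_bscans) / geometry.n_bscans
    fa, fb = rng.integers(1, 3, size=2)
    pa, pb = rng.uniform(0, 2 * np.pi, size=2)
    surf = (
        base
        + amp * np.sin(2 * np.pi * fa * a[None, :] + pa)
        + amp * np.sin(2 * np.pi * fb * b[:, None] + pb)
    )
    return surf


def generate_volume(
    geometry: ScanGeometry | None = None,
    params: VolumeParams | None = None,
    seed: int = 0,
) -> tuple[OCTVolume, SurfacePair, SyntheticTruth]:
    """Generate one synthetic OCT volume with exact HRF ground truth.

    Returns the intensity volume, the exact ILM/RPE surfaces used to render
    it, and the planted HRF mask.  Identical ``(geometry, params, seed)``
    reproduce the output bit-identically.

    Raises
    ------
    ValueError
        If the geometry has fewer than 8 axial pixels, or an explicitly
        requested blob does not fit strictly inside the ILM-RPE band.
    """
    geometry = geometry or ScanGeometry()
    params = params or VolumeParams()
    if geometry.n_axial < 8:
        raise ValueError("geometry must have at least 8 axial pixels")
    rng = np.random.default_rng(seed)
    nb, nz, na = geometry.shape

    amp = params.surface_wobble_frac * nz
    ilm_f = _smooth_surface(rng, geometry, params.ilm_depth_frac * nz, amp)
    thick_f = _smooth_surface(rng, geometry, params.band_thickness_frac * nz, 0.5 * amp)
    ilm = np.clip(np.round(ilm_f), 1, nz - 6).astype(np.int32)
    rpe = np.clip(
        np.round(ilm_f + thick_f), ilm + 3, nz - params.rpe_band_px - 1
    ).astype(np.int32)
    surfaces = SurfacePair(ilm=ilm, rpe=rpe)
    surfaces.validate_against(geometry)

    z = np.arange(nz)[None, :, None]
    ilm3, rpe3 = ilm[:, None, :], rpe[:, None, :]
    intensities = np.full(geometry.shape, params.vitreous_level, dtype=np.float32)
    intensities[(z >= ilm3) & (z < rpe3)] = params.retina_level
    intensities[(z >= rpe3) & (z < rpe3 + params.rpe_band_px)] = params.rpe_level
    intensities[z >= rpe3 + params.rpe_band_px] = params.sub_rpe_level

    # hypo-reflective fluid pockets inside the band
    for _ in range(params.n_fluid):
        cb = int(rng.integers(0, nb))
        ca = int(rng.integers(0, na))
        lo, hi = ilm[cb, ca] + 2, rpe[cb, ca] - 2
        if hi <= lo:
            continue
        cz = int(rng.integers(lo, hi))
        rb = params.fluid_radius_frac[0] * nb
        rz = params.fluid_radius_frac[1] * nz
        ra = params.fluid_radius_frac[2] * na
        fb, fz, fa = _ellipsoid_voxels((cb, cz, ca), (rb, rz, ra), geometry.shape)
        keep = (fz >= ilm[fb, fa] + 1) & (fz < rpe[fb, fa] - 1)
        intensities[fb[keep], fz[keep], fa[keep]] = params.fluid_level

    peak = min(params.retina_level + params.blob_contrast_sd * max(params.noise_sd, 1e-3), 0.98)
    truth_mask = np.zeros(geometry.shape, dtype=bool)
    catalog: list[Blob] = []

    if params.blobs is not None:
        blobs = list(params.blobs)
        for blob in blobs:
            cb, cz, ca = blob.center
            rb, rz, ra = blob.radii
            bb, zz, aa = _ellipsoid_voxels((cb, cz, ca), (rb, rz, ra), geometry.shape)
            if np.any(zz <= ilm[bb, aa]) or np.any(zz >= rpe[bb, aa]):
                raise ValueError(
                    f"blob at {blob.center} extends outside the ILM-RPE band"
                )
            intensities[bb, zz, aa] = blob.peak
            truth_mask[bb, zz, aa] = True
            catalog.append(blob)
    else:
        placed = 0
        attempts = 0
        while placed < params.n_blobs and attempts < 50 * max(params.n_blobs, 1):
            attempts += 1
            cb = int(rng.integers(0, nb))
            ca = int(rng.integers(0, na))
            rz = rng.uniform(*params.blob_radius_axial)
            ra = rng.uniform(*params.blob_radius_ascan)
            rb = rng.uniform(*params.blob_radius_bscan)
            lo = int(np.ceil(ilm[cb, ca] + rz + 2))
            hi = int(np.floor(rpe[cb, ca] - rz - 2))
            if hi <= lo:
                continue
            cz = int(rng.integers(lo, hi))
            bb, zz, aa = _ellipsoid_voxels((cb, cz, ca), (rb, rz, ra), geometry.shape)
            keep = (zz > ilm[bb, aa]) & (zz < rpe[bb, aa])
            bb, zz, aa = bb[keep], zz[keep], aa[keep]
            if bb.size == 0:
                continue
            intensities[bb, zz, aa] = peak
            truth_mask[bb, zz, aa] = True
            catalog.append(Blob(center=(cb, cz, ca), radii=(rb, rz, ra), peak=peak))
            placed += 1

    if params.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, params.noise_sd, geometry.shape)
    intensities = np.clip(intensities, 0.0, 1.0).astype(np.float32)

    volume = OCTVolume(
        geometry=geometry, intensities=intensities, signal_strength=params.signal_strength
    )
    truth = SyntheticTruth(hrf_mask=truth_mask, geometry=geometry, blob_catalog=catalog)
    return volume, surfaces, truth


def high_contrast(params: VolumeParams | None = None) -> VolumeParams:
    """The high-contrast stress variant of a parameter set (peak at 8x noise SD)."""
    return replace(params or VolumeParams(), blob_contrast_sd=8.0)
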