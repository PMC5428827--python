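"""Synthetic 3D tumor image series: textured ellipsoid in lung-like background.

Each scan is a 64^3 HU grid at (2.5, 1, 1) mm spacing (axis order z, y, x:
2.5 mm slices, ~1 mm in-plane). The tumor is a (optionally anisotropic)
ellipsoid whose interior carries a spatially correlated noise texture around
soft-tissue densities (~ -50..150 HU); the background sits at lung-like
densities far below the -100 HU threshold. From week to week the ellipsoid
shrinks concentrically and its texture amplitude decays, both at rates
proportional to cumulative dose x the patient's latent response score.
Scanner "B" scans receive a configured additive HU offset plus extra noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import CohortConfig, PatientRecord

GRID_SHAPE = (64, 64, 64)
SPACING = (2.5, 1.0, 1.0)  # mm per voxel along (z, y, x)

_TUMOR_MEAN_HU = 40.0
_TUMOR_TEXTURE_SD_HU = 35.0
_TEXTURE_CORR_VOXELS = 1.5
_LUNG_HU = -800.0
_ACQ_NOISE_SD_HU = 4.0
_SCANNER_B_EXTRA_NOISE = 5.0


class ImageGenerationError(ValueError):
    pass


@dataclass
class ImageSeries:
    patient: str
    weeks: list
    images: list  # HU arrays, one per week
    masks: list   # boolean arrays aligned with images
    spacing: tuple
    params: dict  # generation parameters, logged for reproducibility


def _ellipsoid_mask(semi_axes_mm, scale, shape=GRID_SHAPE, spacing=SPACING):
    center = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.indices(shape).astype(float)
    coords = np.stack([zz, yy, xx])
    d2 = np.zeros(shape)
    for ax in range(3):
        d2 += ((coords[ax] - center[ax]) * spacing[ax] / (semi_axes_mm[ax] * scale)) ** 2
    return d2 <= 1.0


def generate_image_series(record: PatientRecord, score: float, config: CohortConfig,
                          seed=None) -> ImageSeries:
    """Weekly (image, mask) pairs for one patient.

    The base texture field is drawn once per patient, so week-to-week change
    is pure signal (shrinkage + homogenization) plus fresh acquisition noise.
    A latent score of 0 therefore leaves weekly images identical up to the
    noise realization. Masks are nested (concentric shrinkage), so the voxel
    count is non-increasing whenever the shrink rate is positive.
    """
    if len(record.weeks) < 2:
        raise ImageGenerationError("need at least two weekly scans")
    if seed is None:
        # stable per-patient substream (string hashes are process-randomized)
        from zlib import crc32

        seed = np.random.SeedSequence([config.seed, crc32(record.patient.encode())])
    rng = np.random.default_rng(seed)

    sp = record.shape_params
    # semi-axes along (z, y, x); the long axis lies in-plane
    semi = (sp["axis_a_mm"] * sp["ratio_c"], sp["axis_a_mm"], sp["axis_a_mm"] * sp["ratio_b"])
    base_mask = _ellipsoid_mask(semi, 1.0)
    if base_mask.sum() < 1:
        raise ImageGenerationError(f"tumor smaller than 1 voxel ({record.patient})")

    texture = ndimage.gaussian_filter(rng.normal(size=GRID_SHAPE), _TEXTURE_CORR_VOXELS)
    texture /= texture.std()

    images, masks = [], []
    offset = config.scanner_offset_hu if record.scanner == "B" else 0.0
    extra_sd = _SCANNER_B_EXTRA_NOISE if record.scanner == "B" else 0.0
    for week in record.weeks:
        dose = record.cumulative_dose[week]
        lin_scale = float(np.exp(-config.shrink_rate_per_gy * score * dose / 3.0))
        amp = _TUMOR_TEXTURE_SD_HU * float(np.exp(-config.homogenize_rate_per_gy * score * dose))
        mask = _ellipsoid_mask(semi, lin_scale)
        if mask.sum() < 1:
            raise ImageGenerationError(f"tumor shrank below 1 voxel ({record.patient} wk{week})")
        img = np.full(GRID_SHAPE, _LUNG_HU)
        img[mask] = np.clip(_TUMOR_MEAN_HU + amp * texture[mask], -50.0, 150.0)
        noise_sd = np.hypot(_ACQ_NOISE_SD_HU, extra_sd)
        img = img + offset + rng.normal(0.0, noise_sd, size=GRID_SHAPE)
        images.append(img)
        masks.append(mask)

    return ImageSeries(
        patient=record.patient,
        weeks=list(record.weeks),
        images=images,
        masks=masks,
        spacing=SPACING,
        params={
            "semi_axes_mm": [float(s) for s in semi],
            "score": float(score),
            "scanner_offset_hu": float(offset),
            "shrink_rate_per_gy": config.shrink_rate_per_gy,
            "homogenize_rate_per_gy": config.homogenize_rate_per_gy,
            "texture_sd_hu": _TUMOR_TEXTURE_SD_HU,
            "tumor_mean_hu": _TUMOR_MEAN_HU,
        },
    )


def save_series_nifti(series: ImageSeries, directory):
    """Write each weekly image/mask pair as NIfTI files; returns the paths."""
    import nibabel as nib
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(series.spacing) + [1.0])
    paths = []
    for week, img, mask in zip(series.weeks, series.images, series.masks):
        ip = directory / f"{series.patient}_wk{week}_image.nii"
        mp = directory / f"{series.patient}_wk{week}_mask.nii"
        nib.save(nib.Nifti1Image(img.astype(np.float32), affine), ip)
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), mp)
        paths += [str(ip), str(mp)]
    return paths
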