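"""Loading and preprocessing of co-registered PET/CT volumes and lesion masks.

The rest of the pipeline assumes a canonical representation: PET in
standardized uptake value (SUV) units, CT windowed in Hounsfield units,
and all three grids (PET, CT, mask) voxel-aligned at 1 x 1 x 1 mm
isotropic spacing.  Internal axis order is (z, y, x), 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Standard CT display windows as (width, level) in HU.  The custom window
#: spans the union of the lung and mediastinal windows, so lung parenchyma
#: and mediastinal soft tissue are both retained while extreme values
#: (dense bone, air outside the thorax) are clipped away.
CT_WINDOWS: dict[str, tuple[float, float]] = {
    "lung": (700.0, -600.0),
    "mediastinal": (300.0, 40.0),
    "custom": (1140.0, -380.0),
}


@dataclass
class CtVolume:
    """A CT volume in Hounsfield units with physical-space metadata."""

    voxels: np.ndarray  # (z, y, x) float array, HU
    spacing: tuple[float, float, float]  # mm per voxel along (z, y, x)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("CT voxel grid must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")


@dataclass
class PetVolume:
    """A PET volume, in activity concentration (Bq/mL) or SUV.

    ``units`` states what the voxels currently hold; :func:`convert_to_suv`
    flips it.  ``injected_dose_bq`` is assumed decay-corrected to scan
    start upstream.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    units: Literal["activity", "suv"] = "activity"
    injected_dose_bq: float | None = None
    patient_weight_kg: float | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("PET voxel grid must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")


@dataclass
class VoiMask:
    """Binary lesion mask on the same grid as its paired volumes."""

    voxels: np.ndarray  # binary (z, y, x)
    spacing: tuple[float, float, float]
    lesion_id: str = "lesion"
    label: str = "NSCLC"  # NSCLC | BID
    subtype: str = "none"  # ADC | SCC | ASC | none
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("mask must be a non-empty 3-D array")
        uniq = np.unique(self.voxels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        self.voxels = self.voxels.astype(np.uint8)
        if self.voxels.sum() == 0:
            raise ValueError(f"mask for {self.lesion_id!r} has no foreground voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class VoiPair:
    """Preprocessed, voxel-aligned PET (SUV) + windowed CT + mask at 1 mm."""

    ct: CtVolume
    pet: PetVolume
    mask: VoiMask
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.ct.voxels.shape, self.pet.voxels.shape, self.mask.voxels.shape}
        if len(shapes) != 1:
            raise ValueError(f"PET/CT/mask grids are not aligned: {shapes}")
        for vol in (self.ct, self.pet, self.mask):
            if not np.allclose(vol.spacing, 1.0):
                raise ValueError(f"VoiPair requires 1 mm isotropic spacing, got {vol.spacing}")
        if self.pet.units != "suv":
            raise ValueError("VoiPair requires PET in SUV units")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct.voxels.shape


def convert_to_suv(pet: PetVolume) -> PetVolume:
    """Convert an activity-concentration PET volume to body-weight SUV.

    SUV = activity (Bq/mL) * body weight (g) / injected dose (Bq).  With
    ~1 g/mL tissue density the result is dimensionless.  A volume already
    in SUV units is returned unchanged.
    """
    if pet.units == "suv":
        return pet
    if pet.injected_dose_bq is None:
        raise ValueError("SUV conversion requires injected_dose_bq")
    if pet.patient_weight_kg is None:
        raise ValueError("SUV conversion requires patient_weight_kg")
    if pet.injected_dose_bq <= 0:
        raise ValueError("injected_dose_bq must be > 0")
    if pet.patient_weight_kg <= 0:
        raise ValueError("patient_weight_kg must be > 0")
    suv = pet.voxels * (pet.patient_weight_kg * 1000.0) / pet.injected_dose_bq
    logger.info(
        "SUV conversion: dose=%.3g Bq, weight=%.1f kg", pet.injected_dose_bq, pet.patient_weight_kg
    )
    return replace(pet, voxels=suv, units="suv")


def apply_ct_window(ct: CtVolume, width: float, level: float) -> CtVolume:
    """Clip CT intensities to the window [level - width/2, level + width/2].

    Clipping (rather than rescaling to display gray levels) preserves HU
    semantics, which the fixed 25-HU discretization bin width downstream
    relies on.  Idempotent.
    """
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo, hi = level - width / 2.0, level + width / 2.0
    return replace(ct, voxels=np.clip(ct.voxels, lo, hi))


def resample_isotropic(
    voxels: np.ndarray,
    spacing: tuple[float, float, float],
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: Literal["linear", "nearest"] = "linear",
) -> np.ndarray:
    """Resample a (z, y, x) grid to the target spacing.

    Intensity volumes use trilinear interpolation ("bilinear" extended to
    3-D); masks use nearest-neighbour so labels stay binary.  The output
    grid samples physical positions ``i * target_spacing`` so original
    grid points are reproduced exactly when spacings are integer multiples.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim != 3 or min(voxels.shape) == 0:
        raise ValueError("expected a non-empty 3-D volume")
    if any(s <= 0 for s in spacing) or any(t <= 0 for t in target_spacing):
        raise ValueError("spacings must be positive")
    zoom = [s / t for s, t in zip(spacing, target_spacing)]
    if np.allclose(zoom, 1.0):
        return voxels.astype(np.float64 if mode == "linear" else voxels.dtype)
    new_shape = [max(1, int(round((n - 1) * z)) + 1) for n, z in zip(voxels.shape, zoom)]
    # sample at physical coords j*target along each axis -> index j/zoom
    grids = np.meshgrid(
        *[np.arange(n) / z for n, z in zip(new_shape, zoom)], indexing="ij", sparse=True
    )
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        voxels.astype(np.float64), np.broadcast_arrays(*grids), order=order, mode="nearest"
    )
    return out


def _resample_volume(vol, target=(1.0, 1.0, 1.0)):
    """Resample a Ct/Pet/VoiMask dataclass, dispatching interpolation mode."""
    mode = "nearest" if isinstance(vol, VoiMask) else "linear"
    out = resample_isotropic(vol.voxels, vol.spacing, target, mode=mode)
    if isinstance(vol, VoiMask):
        out = out.astype(np.uint8)
    return replace(vol, voxels=out, spacing=tuple(target))


def save_nifti(path, voxels: np.ndarray, spacing: tuple[float, float, float]) -> None:
    """Write a (z, y, x) array as NIfTI-1 with the given mm spacing."""
    # nibabel stores (x, y, z); transpose and encode spacing in the affine
    data = np.asarray(voxels).transpose(2, 1, 0)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI-1 file into a (z, y, x) array plus per-axis mm spacing."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def load_voi_pair(
    pet_path,
    ct_path,
    mask_path,
    *,
    window: tuple[float, float] | str = "custom",
    lesion_id: str = "lesion",
    label: str = "NSCLC",
    subtype: str = "none",
    pet_units: Literal["activity", "suv"] = "suv",
    injected_dose_bq: float | None = None,
    patient_weight_kg: float | None = None,
    min_mask_voxels: int = 2,
) -> VoiPair:
    """Load PET/CT/mask NIfTI files and return a fully preprocessed VoiPair.

    Applies, in order: SUV conversion (if needed), CT windowing, isotropic
    1 mm resampling of all three grids.  ``window`` is a named window from
    :data:`CT_WINDOWS` or an explicit (width, level) pair.
    """
    if isinstance(window, str):
        window = CT_WINDOWS[window]
    width, level = window

    pet_vox, pet_sp = load_nifti(pet_path)
    ct_vox, ct_sp = load_nifti(ct_path)
    mask_vox, mask_sp = load_nifti(mask_path)

    pet = PetVolume(
        pet_vox,
        pet_sp,
        units=pet_units,
        injected_dose_bq=injected_dose_bq,
        patient_weight_kg=patient_weight_kg,
    )
    pet = convert_to_suv(pet)
    ct = apply_ct_window(CtVolume(ct_vox, ct_sp), width, level)
    mask = VoiMask(
        (mask_vox > 0.5).astype(np.uint8), mask_sp, lesion_id=lesion_id, label=label, subtype=subtype
    )

    pet = _resample_volume(pet)
    ct = _resample_volume(ct)
    mask = _resample_volume(mask)
    if mask.voxels.sum() < min_mask_voxels:
        raise ValueError(
            f"lesion {lesion_id!r}: mask has {int(mask.voxels.sum())} voxels after "
            f"resampling (minimum {min_mask_voxels})"
        )
    if not (pet.voxels.shape == ct.voxels.shape == mask.voxels.shape):
        raise ValueError(
            f"lesion {lesion_id!r}: grid mismatch after resampling "
            f"(pet {pet.voxels.shape}, ct {ct.voxels.shape}, mask {mask.voxels.shape})"
        )
    prep = {
        "window_width_hu": width,
        "window_level_hu": level,
        "suv_normalization": "body_weight",
        "decay_correction": "assumed_upstream",
        "target_spacing_mm": (1.0, 1.0, 1.0),
    }
    logger.info("loaded %s: shape=%s, preprocessing=%s", lesion_id, pet.voxels.shape, prep)
    return VoiPair(ct=ct, pet=pet, mask=mask, preprocessing=prep)


def load_manifest(manifest_path):
    """Read a cohort manifest CSV into a DataFrame.

    Required columns: lesion_id, pet_path, ct_path, mask_path, label;
    optional: subtype.
    """
    import pandas as pd

    df = pd.read_csv(manifest_path)
    required = {"lesion_id", "pet_path", "ct_path", "mask_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "subtype" not in df.columns:
        df["subtype"] = "none"
    return df
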