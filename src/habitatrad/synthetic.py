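"""Synthetic dual-channel PET/CT phantom cohorts with planted habitats.

Each synthetic lesion is an ellipsoidal mask partitioned into contiguous
subregions (concentric shells, randomly seeded blobs, or a mix), each
carrying its own PET-SUV / CT-HU intensity signature plus spatially
correlated noise whose smoothing scale ("roughness") differentiates the
local-entropy channels.  Two lesion classes differ in their distribution
over subregion compositions, emulating a tumor class whose
highest-uptake habitat is present while it is nearly absent from the
benign class.  Everything is deterministic given the master seed.

The generated cohorts use the same representation and on-disk contract
(NIfTI volumes + CSV manifest) that the preprocessing module consumes,
so every downstream module can be exercised without real patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import CtVolume, PetVolume, VoiMask, VoiPair, save_nifti


@dataclass
class HabitatSignature:
    """Intensity/texture signature of one planted subregion type."""

    name: str
    pet_mean: float
    pet_sd: float
    ct_mean: float
    ct_sd: float
    roughness: float = 1.0  # Gaussian smoothing sigma of the noise field, voxels

    def __post_init__(self) -> None:
        if self.pet_sd <= 0 or self.ct_sd <= 0:
            raise ValueError("signature standard deviations must be > 0")


def default_signatures(separation: float = 6.0) -> list[HabitatSignature]:
    """Four habitat signatures separated by ``separation`` noise SDs.

    The signatures occupy the corners of a PET x CT grid — the two
    modalities carry complementary contrast, as in necrotic (cold/low
    attenuation), fibrotic-stromal (cold/dense), inflamed-intermediate
    (hot/low attenuation) and hypermetabolic (hot/dense) tissue — with a
    texture-roughness ramp differentiating the local-entropy channels.
    SUV and HU scales sit in the plausible FDG lung-lesion range.
    """
    pet_sd, ct_sd = 0.5, 40.0
    pet_lo, ct_lo = 1.0, -400.0
    pet_hi = pet_lo + separation * pet_sd
    ct_hi = ct_lo + separation * ct_sd
    grid = [
        ("necrotic", pet_lo, ct_lo, 0.8),
        ("stromal", pet_lo, ct_hi, 1.2),
        ("intermediate", pet_hi, ct_lo, 1.6),
        ("hypermetabolic", pet_hi, ct_hi, 2.0),
    ]
    return [
        HabitatSignature(name=n, pet_mean=p, pet_sd=pet_sd, ct_mean=c, ct_sd=ct_sd, roughness=r)
        for n, p, c, r in grid
    ]


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``compositions`` maps each class label to a list of candidate habitat
    compositions (signature-name -> size proportion); a lesion samples
    one candidate uniformly.  Defaults plant a 4-signature structure in
    which the high-uptake signature appears only in the NSCLC-like class.
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: {"NSCLC": 20, "BID": 20})
    signatures: list[HabitatSignature] = field(default_factory=default_signatures)
    compositions: dict[str, list[dict[str, float]]] = field(
        default_factory=lambda: {
            "NSCLC": [
                {"intermediate": 0.85, "hypermetabolic": 0.15},
                {"hypermetabolic": 0.7, "necrotic": 0.3},
                {"hypermetabolic": 1.0},
            ],
            "BID": [
                {"necrotic": 1.0},
                {"stromal": 0.85, "necrotic": 0.15},
                {"stromal": 0.7, "intermediate": 0.3},
            ],
        }
    )
    radius_range_mm: tuple[float, float] = (8.0, 12.0)
    geometry: str = "blobs"  # shells | blobs
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, candidates in self.compositions.items():
            for comp in candidates:
                if abs(sum(comp.values()) - 1.0) > 1e-9:
                    raise ValueError(f"composition for {cls!r} does not sum to 1: {comp}")


def _ellipsoid_mask(radii_vox: np.ndarray, margin: int) -> np.ndarray:
    shape = tuple(int(np.ceil(2 * r)) + 2 * margin + 1 for r in radii_vox)
    center = np.array([(s - 1) / 2 for s in shape])
    grid = np.indices(shape).reshape(3, -1).T - center
    inside = ((grid / radii_vox) ** 2).sum(axis=1) <= 1.0
    return inside.reshape(shape)


def _partition_mask(
    mask: np.ndarray, proportions: list[float], geometry: str, rng: np.random.Generator
) -> np.ndarray:
    """Split a mask into contiguous parts with approximately the given sizes.

    ``shells`` cuts concentric distance-from-center shells (innermost part
    is listed last, mimicking a central high-uptake core); ``blobs`` grows
    parts from random seed voxels by nearest-seed assignment.
    """
    coords = np.argwhere(mask)
    n = coords.shape[0]
    part = np.zeros(mask.shape, dtype=np.int32)
    if geometry == "shells":
        center = coords.mean(axis=0)
        d = np.linalg.norm(coords - center, axis=1)
        order = np.argsort(d)  # outermost shells get the first proportions
        bounds = np.cumsum(proportions) * n
        labels = np.searchsorted(bounds, np.arange(n), side="right")
        labels = np.clip(labels, 0, len(proportions) - 1)
        # innermost voxels -> last listed component
        ranks = np.empty(n, dtype=np.int64)
        ranks[order[::-1]] = np.arange(n)
        part[tuple(coords.T)] = labels[ranks] + 1
    elif geometry == "blobs":
        k = len(proportions)
        seeds = coords[rng.choice(n, size=k, replace=False)]
        d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
        # weight distances so target proportions are approached
        w = np.asarray(proportions) ** (1 / 3)
        labels = (d / w[None, :]).argmin(axis=1)
        part[tuple(coords.T)] = labels + 1
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return part


def _correlated_noise(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length ``sigma`` voxels."""
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_lesion(
    spec: CohortSpec, class_label: str, lesion_id: str, seed: int
) -> tuple[VoiPair, np.ndarray, dict]:
    """One synthetic lesion: preprocessed VoiPair + planted habitat truth.

    Returns the VoiPair, the ground-truth subregion label volume (values
    index ``spec.signatures`` + 1, 0 outside the mask), and a small
    ground-truth record (composition, signature names).
    """
    rng = np.random.default_rng(seed)
    composition = spec.compositions[class_label][
        rng.integers(len(spec.compositions[class_label]))
    ]
    sig_by_name = {s.name: s for s in spec.signatures}
    names = list(composition)
    proportions = [composition[nm] for nm in names]

    lo, hi = spec.radius_range_mm
    radii_mm = rng.uniform(lo, hi, size=3)
    radii_vox = radii_mm / np.asarray(spec.spacing)
    mask = _ellipsoid_mask(radii_vox, spec.margin)
    if mask.sum() < 2 * 27:  # at least two minimal supervoxels' worth of voxels
        raise ValueError("lesion too small: below two supervoxel volumes")
    part = _partition_mask(mask, proportions, spec.geometry, rng)

    pet = np.zeros(mask.shape)
    ct = np.full(mask.shape, -800.0)  # lung-like background
    truth = np.zeros(mask.shape, dtype=np.int32)
    for j, nm in enumerate(names):
        sig = sig_by_name[nm]
        region = part == j + 1
        pet[region] = sig.pet_mean + sig.pet_sd * _correlated_noise(mask.shape, sig.roughness, rng)[region]
        ct[region] = sig.ct_mean + sig.ct_sd * _correlated_noise(mask.shape, sig.roughness, rng)[region]
        truth[region] = [s.name for s in spec.signatures].index(nm) + 1
    pet = np.clip(pet, 0.0, None)

    voi = VoiPair(
        ct=CtVolume(ct, spec.spacing),
        pet=PetVolume(pet, spec.spacing, units="suv"),
        mask=VoiMask(mask.astype(np.uint8), spec.spacing, lesion_id=lesion_id, label=class_label),
    )
    record = {
        "lesion_id": lesion_id,
        "label": class_label,
        "composition": dict(composition),
        "signature_names": [s.name for s in spec.signatures],
        "seed": seed,
    }
    return voi, truth, record


def generate_cohort_in_memory(spec: CohortSpec) -> tuple[list[VoiPair], list[np.ndarray], list[dict]]:
    """All lesions of a cohort, deterministically derived from the master seed."""
    master = np.random.default_rng(spec.seed)
    vois, truths, records = [], [], []
    for class_label, n in spec.n_per_class.items():
        for i in range(n):
            lesion_seed = int(master.integers(2**31 - 1))
            lesion_id = f"{class_label}_{i:03d}"
            voi, truth, rec = generate_lesion(spec, class_label, lesion_id, lesion_seed)
            vois.append(voi)
            truths.append(truth)
            records.append(rec)
    return vois, truths, records


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write a cohort to disk: NIfTI volumes, CSV manifest, truth JSON.

    The manifest has the exact columns the preprocessing loader expects
    (lesion_id, pet_path, ct_path, mask_path, label, subtype), so the
    synthetic cohort is a drop-in replacement for a real one.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vois, truths, records = generate_cohort_in_memory(spec)
    rows = []
    for voi, truth, rec in zip(vois, truths, records):
        lid = rec["lesion_id"]
        paths = {k: out / f"{lid}_{k}.nii.gz" for k in ("pet", "ct", "mask", "truth")}
        save_nifti(paths["pet"], voi.pet.voxels, voi.pet.spacing)
        save_nifti(paths["ct"], voi.ct.voxels, voi.ct.spacing)
        save_nifti(paths["mask"], voi.mask.voxels, voi.mask.spacing)
        save_nifti(paths["truth"], truth, voi.mask.spacing)
        rows.append(
            {
                "lesion_id": lid,
                "pet_path": str(paths["pet"]),
                "ct_path": str(paths["ct"]),
                "mask_path": str(paths["mask"]),
                "label": rec["label"],
                "subtype": "none",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
    return manifest


def recovery_cohort_spec(
    separation: float = 6.0, n_per_class: int = 20, seed: int = 0
) -> CohortSpec:
    """Canonical conditions for planted-habitat recovery studies.

    A 4-signature cohort whose lesions are dominated by one signature
    with a minority second blob: every signature is well represented and
    interface voxels (whose 9x9x9-neighbourhood texture mixes two
    signatures) stay a small fraction of the cohort.  ``separation``
    scales the inter-signature distance in noise SDs.
    """
    return CohortSpec(
        n_per_class={"NSCLC": n_per_class, "BID": n_per_class},
        signatures=default_signatures(separation),
        compositions={
            "NSCLC": [
                {"intermediate": 0.85, "hypermetabolic": 0.15},
                {"hypermetabolic": 1.0},
            ],
            "BID": [
                {"necrotic": 1.0},
                {"stromal": 0.85, "necrotic": 0.15},
            ],
        },
        geometry="blobs",
        seed=seed,
    )


def make_feature_cohort(
    n_per_class: int = 20,
    n_features: int = 30,
    n_informative: int = 5,
    effect_size: float = 3.0,
    habitats_per_lesion: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Habitat-level feature rows with a controllable class signal.

    A lightweight companion to the image phantoms for exercising the
    selection/modeling stack directly: each lesion contributes one row
    per habitat; informative columns are shifted by ``effect_size`` SDs
    in one class, the rest are pure noise.  Returns (table, lesion
    labels per row, lesion ids per row).
    """
    rng = np.random.default_rng(seed)
    rows, labels, lesions = [], [], []
    for cls, offset in (("NSCLC", effect_size), ("BID", 0.0)):
        for i in range(n_per_class):
            lid = f"{cls}_{i:03d}"
            lesion_shift = rng.normal(0, 0.3, size=n_features)  # shared within lesion
            for _ in range(rng.integers(habitats_per_lesion[0], habitats_per_lesion[1] + 1)):
                x = rng.normal(0, 1, size=n_features) + lesion_shift
                x[:n_informative] += offset
                rows.append(x)
                labels.append(cls)
                lesions.append(lid)
    table = pd.DataFrame(np.asarray(rows), columns=[f"f{j:03d}" for j in range(n_features)])
    return table, pd.Series(labels, name="label"), pd.Series(lesions, name="lesion_id")
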