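"""Radiomics feature extraction for whole lesions and habitat subregions.

Per region and modality the extractor produces exactly 929 named values
(107 base + 390 CoLIAGe + 432 wavelet-LBP); with both PET and CT this is
the full 1,858-column feature table.  Columns are named
``{modality}/{family}/{feature}`` and their order is stable across runs.
Family extractors that cannot run on a region (too small, degenerate)
contribute missing values, never missing columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..habitats import HabitatLabelMap, bounding_box
from ..io_preprocess import VoiPair
from .base import base_feature_names, extract_base_features
from .coliage import coliage_feature_names, extract_coliage_features
from .wavelet_lbp import extract_wavelet_lbp_features, wavelet_lbp_feature_names

logger = logging.getLogger(__name__)

MODALITIES = ("PET", "CT")
#: Fixed discretization bin widths: 25 HU for CT, 0.25 SUV for PET.
BIN_WIDTHS = {"PET": 0.25, "CT": 25.0}

N_BASE = 107
N_COLIAGE = 390
N_WAVELET_LBP = 432
N_PER_MODALITY = N_BASE + N_COLIAGE + N_WAVELET_LBP  # 929
N_TOTAL = 2 * N_PER_MODALITY  # 1858


@dataclass
class RegionSpec:
    """One extraction region: a whole lesion or one habitat of it."""

    lesion_id: str
    region_kind: str  # "whole" | "habitat"
    mask: np.ndarray  # binary, on the lesion grid
    habitat_index: int = 0
    label: str = "NSCLC"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.sum() == 0:
            raise ValueError(f"region for {self.lesion_id!r} is empty")

    @property
    def row_key(self) -> tuple[str, str, int]:
        return (self.lesion_id, self.region_kind, self.habitat_index)


def feature_columns(modalities=MODALITIES, families=("base", "coliage", "wavelet_lbp")) -> list[str]:
    """All column names, modality-major, in the canonical stable order."""
    by_family = {
        "base": base_feature_names,
        "coliage": coliage_feature_names,
        "wavelet_lbp": wavelet_lbp_feature_names,
    }
    cols = []
    for m in modalities:
        for fam in ("base", "coliage", "wavelet_lbp"):
            if fam in families:
                cols += [f"{m}/{fam}/{n}" for n in by_family[fam]()]
    return cols


ALL_FAMILIES = ("base", "coliage", "wavelet_lbp")


def extract_region_modality(
    volume: np.ndarray,
    region_mask: np.ndarray,
    modality: str,
    spacing=(1.0, 1.0, 1.0),
    families=ALL_FAMILIES,
) -> dict[str, float]:
    """929 named features of one region in one modality.

    The volume is cropped to the region bounding box before extraction.
    Family failures are logged and reported as NaN for that family.
    ``families`` restricts extraction to a subset of the three families.
    """
    if modality not in BIN_WIDTHS:
        raise ValueError(f"unknown modality {modality!r}")
    box = bounding_box(region_mask)
    vol = np.asarray(volume, dtype=np.float64)[box]
    msk = np.asarray(region_mask).astype(bool)[box]
    out: dict[str, float] = {}

    extractors = (
        ("base", base_feature_names, lambda: extract_base_features(vol, msk, BIN_WIDTHS[modality], spacing)),
        ("coliage", coliage_feature_names, lambda: extract_coliage_features(vol, msk)),
        ("wavelet_lbp", wavelet_lbp_feature_names, lambda: extract_wavelet_lbp_features(vol, msk)),
    )
    for family, names_fn, run in extractors:
        if family not in families:
            continue
        try:
            values = run()
        except Exception as exc:  # family failure -> missing values, not a crash
            logger.warning("%s extraction failed (%s); values set missing", family, exc)
            values = {n: np.nan for n in names_fn()}
        out.update({f"{modality}/{family}/{k}": float(v) for k, v in values.items()})
    return out


def regions_from_habitat_map(habitat_map: HabitatLabelMap, label: str = "NSCLC") -> list[RegionSpec]:
    """One RegionSpec per habitat present in a lesion's label map."""
    regions = []
    for h in sorted(habitat_map.counts):
        regions.append(
            RegionSpec(
                lesion_id=habitat_map.lesion_id,
                region_kind="habitat",
                mask=habitat_map.labels == h,
                habitat_index=h,
                label=label,
            )
        )
    return regions


def whole_lesion_region(mask: np.ndarray, lesion_id: str, label: str = "NSCLC") -> RegionSpec:
    return RegionSpec(lesion_id=lesion_id, region_kind="whole", mask=np.asarray(mask) > 0, label=label)


def extract_all(
    voi: VoiPair,
    regions: list[RegionSpec],
    modalities=MODALITIES,
    crop_to_voi: bool = True,
    families=ALL_FAMILIES,
) -> pd.DataFrame:
    """Feature table for a list of regions of one lesion.

    Rows are keyed by (lesion_id, region_kind, habitat_index); columns
    are the full modality x family x feature grid (1,858 for both
    modalities).  Region masks must live on the same grid as the volumes
    or, when ``crop_to_voi`` is set and shapes differ, on the lesion's
    bounding box.
    """
    volumes = {"PET": voi.pet.voxels, "CT": voi.ct.voxels}
    if crop_to_voi:
        box = bounding_box(voi.mask.voxels)
        box_shape = tuple(s.stop - s.start for s in box)
        cropped = {m: v[box] for m, v in volumes.items()}
    rows = {}
    for region in regions:
        if crop_to_voi and region.mask.shape == box_shape:
            vols = cropped
        elif region.mask.shape == voi.shape:
            vols = volumes
        else:
            raise ValueError(
                f"region mask shape {region.mask.shape} matches neither the VOI grid "
                f"{voi.shape} nor its bounding box"
            )
        row: dict[str, float] = {}
        for m in modalities:
            row.update(
                extract_region_modality(vols[m], region.mask, m, voi.mask.spacing, families)
            )
        rows[region.row_key] = row
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["lesion_id", "region_kind", "habitat_index"])
    table = pd.DataFrame(list(rows.values()), index=index)
    return table[feature_columns(modalities, families)]


def feature_schema() -> list[dict]:
    """Sidecar schema: feature name -> modality, family, parameters."""
    schema = []
    for col in feature_columns():
        modality, family, name = col.split("/", 2)
        entry = {"column": col, "modality": modality, "family": family, "feature": name}
        if family == "base":
            entry["bin_width"] = BIN_WIDTHS[modality]
        schema.append(entry)
    return schema
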