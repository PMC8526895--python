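"""Wavelet-LBP features: first-order statistics of LBP-encoded sub-bands.

The region volume is decomposed by a single-level 3-D Haar discrete
wavelet transform into 8 sub-bands (LLL..HHH).  Each sub-band is encoded
by a rotation-invariant 3-D local binary pattern: for a Chebyshev radius
r, the code of a voxel is the number of its 26 shell neighbours whose
value is >= the centre (0..26) — invariant to any rotation of the
neighbourhood by construction.  The 18 standard first-order statistics
of the codes over the (downsampled) region give:

    8 sub-bands x 3 LBP radii (1, 2, 3) x 18 statistics = 432.

A constant region yields the all-equal code everywhere, so code entropy
is exactly 0.
"""

from __future__ import annotations

import numpy as np
import pywt
from skimage.measure import block_reduce

from .base import FIRSTORDER_NAMES, firstorder_features

LBP_RADII = (1, 2, 3)
#: Sub-band order: pywt uses 'a' (approximation/low-pass) and 'd'
#: (detail/high-pass) per axis; presented as L/H.
SUBBAND_KEYS = ("aaa", "aad", "ada", "add", "daa", "dad", "dda", "ddd")
_OFFSETS_UNIT = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _band_name(key: str) -> str:
    return key.upper().replace("A", "L").replace("D", "H")


def wavelet_lbp_feature_names() -> list[str]:
    names = [
        f"{_band_name(key)}_r{r}_{stat}"
        for key in SUBBAND_KEYS
        for r in LBP_RADII
        for stat in FIRSTORDER_NAMES
    ]
    assert len(names) == 432
    return names


def lbp_code_volume(volume: np.ndarray, radius: int) -> np.ndarray:
    """Rotation-invariant 3-D LBP: count of shell neighbours >= centre.

    Neighbours are the 26 offsets at Chebyshev radius ``radius``; values
    beyond the boundary are edge-replicated.
    """
    vol = np.asarray(volume, dtype=np.float64)
    padded = np.pad(vol, radius, mode="edge")
    code = np.zeros(vol.shape, dtype=np.int64)
    core = tuple(slice(radius, radius + s) for s in vol.shape)
    for dz, dy, dx in _OFFSETS_UNIT:
        o = (dz * radius, dy * radius, dx * radius)
        shifted = padded[
            tuple(slice(radius + c, radius + c + s) for c, s in zip(o, vol.shape))
        ]
        code += shifted >= vol
    return code


def extract_wavelet_lbp_features(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 432 wavelet-LBP features for one region.

    Regions too small for one wavelet decomposition level (any axis < 2)
    return every feature as NaN.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty region")
    names = wavelet_lbp_feature_names()
    if min(volume.shape) < 2:
        return {n: np.nan for n in names}

    coeffs = pywt.dwtn(np.asarray(volume, dtype=np.float64), "haar")
    band_shape = coeffs["aaa"].shape
    mask_ds = block_reduce(mask, (2, 2, 2), np.max)[
        : band_shape[0], : band_shape[1], : band_shape[2]
    ].astype(bool)
    if mask_ds.sum() == 0:
        return {n: np.nan for n in names}

    out: dict[str, float] = {}
    for key in SUBBAND_KEYS:
        band = coeffs[key]
        for r in LBP_RADII:
            codes = lbp_code_volume(band, r)[mask_ds]
            # codes are integers in 0..26: unit bin width for the
            # histogram-based statistics
            stats = firstorder_features(codes.astype(np.float64), bin_width=1.0)
            for stat in FIRSTORDER_NAMES:
                out[f"{_band_name(key)}_r{r}_{stat}"] = stats[stat]
    return out
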