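"""Co-occurrence of local anisotropic gradient orientations (CoLIAGe).

Each voxel is assigned its locally dominant gradient orientation — the
principal eigenvector of the structure tensor accumulated over a sliding
window — expressed as a polar angle (theta) and an azimuth (phi).  The
orientations are quantized and their within-window co-occurrence matrix
summarized by 13 Haralick-type measures per voxel, producing 13 feature
maps per orientation angle and window size.  Five summary statistics of
each map over the region give the feature vector:

    13 measures x 2 angles (theta, phi) x 3 windows (3, 5, 7)
    x 5 statistics (mean, median, std, skewness, kurtosis) = 390.

Constant regions have zero gradient everywhere; all voxels then share a
single orientation symbol and entropy-type measures are exactly 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

WINDOW_SIZES = (3, 5, 7)
ANGLE_NAMES = ("theta", "phi")
STAT_NAMES = ("mean", "median", "std", "skewness", "kurtosis")
HARALICK_NAMES = (
    "Energy", "Contrast", "Correlation", "Variance", "InverseDifferenceMoment",
    "SumAverage", "SumVariance", "SumEntropy", "Entropy", "DifferenceVariance",
    "DifferenceEntropy", "Imc1", "Imc2",
)
N_ORIENTATION_BINS = 8
_CO_OFFSETS = ((0, 0, 1), (0, 1, 0), (1, 0, 0))


def coliage_feature_names() -> list[str]:
    names = []
    for angle in ANGLE_NAMES:
        for w in WINDOW_SIZES:
            for h in HARALICK_NAMES:
                for s in STAT_NAMES:
                    names.append(f"{angle}_w{w}_{h}_{s}")
    assert len(names) == 390
    return names


def dominant_orientation_maps(volume: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantized polar/azimuth maps of the locally dominant gradient.

    The structure tensor (outer product of the central-difference
    gradient, box-summed over the window) is diagonalized per voxel; the
    top eigenvector's polar angle is folded to [0, pi/2] and the azimuth
    to [0, pi) since eigenvectors carry no sign.  Zero-gradient voxels
    map to bin 0.
    """
    vol = np.asarray(volume, dtype=np.float64)
    gz, gy, gx = np.gradient(vol)
    size = (window,) * 3
    # 6 unique structure-tensor components, window-summed
    comps = {}
    for (a, ga), (b, gb) in [
        ((0, gz), (0, gz)), ((0, gz), (1, gy)), ((0, gz), (2, gx)),
        ((1, gy), (1, gy)), ((1, gy), (2, gx)), ((2, gx), (2, gx)),
    ]:
        comps[(a, b)] = ndimage.uniform_filter(ga * gb, size=size, mode="nearest")
    n = vol.size
    tensor = np.empty((n, 3, 3))
    for (a, b), v in comps.items():
        tensor[:, a, b] = tensor[:, b, a] = v.ravel()
    vals, vecs = np.linalg.eigh(tensor)
    principal = vecs[:, :, -1]  # eigenvector of the largest eigenvalue
    energy = vals[:, -1]
    vz, vy, vx = principal[:, 0], principal[:, 1], principal[:, 2]
    norm = np.sqrt(vz**2 + vy**2 + vx**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.abs(vz) / np.where(norm > 0, norm, 1.0), 0, 1))
        phi = np.mod(np.arctan2(vy, vx), np.pi)
    flat = energy <= max(energy.max(), 1.0) * 1e-12
    theta_bins = np.minimum(
        (theta / (np.pi / 2) * N_ORIENTATION_BINS).astype(np.int64), N_ORIENTATION_BINS - 1
    )
    phi_bins = np.minimum((phi / np.pi * N_ORIENTATION_BINS).astype(np.int64), N_ORIENTATION_BINS - 1)
    theta_bins[flat] = 0
    phi_bins[flat] = 0
    return theta_bins.reshape(vol.shape), phi_bins.reshape(vol.shape)


def _window_cooccurrence(q: np.ndarray, window: int) -> np.ndarray:
    """Per-voxel co-occurrence counts of quantized symbols, shape (B, B, *vol).

    Pairs are taken along the three axis-aligned unit offsets (symmetric),
    and counted over each voxel's window via box filtering, truncated at
    the volume boundary.
    """
    b = N_ORIENTATION_BINS
    kernel = np.ones((window,) * 3)
    counts = np.zeros((b, b) + q.shape, dtype=np.float32)
    pair = np.zeros(q.shape, dtype=np.float64)
    for i in range(b):
        qi = q == i
        for j in range(i, b):
            qj = q == j
            pair[:] = 0.0
            for off in _CO_OFFSETS:
                src = tuple(slice(0, s - o) for s, o in zip(q.shape, off))
                dst = tuple(slice(o, None) for o in off)
                pair[src] += qi[src] & qj[dst]
                if i != j:
                    pair[src] += qj[src] & qi[dst]
            summed = ndimage.correlate(pair, kernel, mode="constant", cval=0.0)
            counts[i, j] = summed
            counts[j, i] = summed
    return counts


def _haralick_maps(counts: np.ndarray) -> dict[str, np.ndarray]:
    """13 Haralick measures per voxel from per-voxel co-occurrence counts."""
    b = counts.shape[0]
    shape = counts.shape[2:]
    p = counts.reshape(b * b, -1).T.reshape(-1, b, b).astype(np.float64)  # (N, B, B)
    total = p.sum(axis=(1, 2))
    p /= np.where(total > 0, total, 1.0)[:, None, None]

    i = np.arange(1, b + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=2)  # (N, B); symmetric, so py == px
    mu = np.einsum("nij,ij->n", p, ii)
    sigma2 = (p * (ii[None, :, :] - mu[:, None, None]) ** 2).sum(axis=(1, 2))

    def entropy_of(q):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
        return t.sum(axis=tuple(range(1, q.ndim)))

    k_sum = np.arange(2, 2 * b + 1, dtype=np.float64)
    p_sum = np.stack([p[:, (ii + jj) == k].sum(axis=1) for k in k_sum], axis=1)
    k_diff = np.arange(0, b, dtype=np.float64)
    p_diff = np.stack([p[:, np.abs(ii - jj) == k].sum(axis=1) for k in k_diff], axis=1)

    sum_avg = (p_sum * k_sum).sum(axis=1)
    sum_var = (p_sum * (k_sum - sum_avg[:, None]) ** 2).sum(axis=1)
    diff_avg = (p_diff * k_diff).sum(axis=1)
    diff_var = (p_diff * (k_diff - diff_avg[:, None]) ** 2).sum(axis=1)

    hxy = entropy_of(p)
    hx = entropy_of(px)
    pxy = px[:, :, None] * px[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = -(p * log_pxy).sum(axis=(1, 2))
    hxy2 = -(pxy * log_pxy).sum(axis=(1, 2))

    autocorr = np.einsum("nij,ij->n", p, ii * jj)
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(sigma2 > 0, (autocorr - mu**2) / sigma2, 1.0)
        imc1 = np.where(hx > 0, (hxy - hxy1) / hx, 0.0)
    imc2 = np.sqrt(1.0 - np.exp(-2.0 * np.clip(hxy2 - hxy, 0, None)))

    maps = {
        "Energy": (p**2).sum(axis=(1, 2)),
        "Contrast": np.einsum("nij,ij->n", p, (ii - jj) ** 2),
        "Correlation": correlation,
        "Variance": sigma2,
        "InverseDifferenceMoment": np.einsum("nij,ij->n", p, 1.0 / (1.0 + (ii - jj) ** 2)),
        "SumAverage": sum_avg,
        "SumVariance": sum_var,
        "SumEntropy": entropy_of(p_sum),
        "Entropy": hxy,
        "DifferenceVariance": diff_var,
        "DifferenceEntropy": entropy_of(p_diff),
        "Imc1": imc1,
        "Imc2": imc2,
    }
    return {k: v.reshape(shape) for k, v in maps.items()}


def _region_stats(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {s: np.nan for s in STAT_NAMES}
    sd = float(values.std())
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "std": sd,
        "skewness": float(stats.skew(values)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(values, fisher=False)) if sd > 0 else 0.0,
    }


def extract_coliage_features(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 390 CoLIAGe features for one region.

    Regions whose bounding box is smaller than the smallest window along
    any axis return every feature as NaN.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty region")
    out: dict[str, float] = {}
    too_small = min(volume.shape) < min(WINDOW_SIZES)
    for w in WINDOW_SIZES:
        if too_small:
            for angle in ANGLE_NAMES:
                for h in HARALICK_NAMES:
                    for s in STAT_NAMES:
                        out[f"{angle}_w{w}_{h}_{s}"] = np.nan
            continue
        theta_q, phi_q = dominant_orientation_maps(volume, w)
        for angle, q in zip(ANGLE_NAMES, (theta_q, phi_q)):
            counts = _window_cooccurrence(q, w)
            maps = _haralick_maps(counts)
            for h in HARALICK_NAMES:
                st = _region_stats(maps[h][mask])
                for s in STAT_NAMES:
                    out[f"{angle}_w{w}_{h}_{s}"] = st[s]
    # restore the canonical name order (angle-major)
    return {name: out[name] for name in coliage_feature_names()}
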