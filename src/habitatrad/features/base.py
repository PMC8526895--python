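"""Standard radiomics feature set: first-order, shape, and texture matrices.

Implements the conventional 107-feature set — 18 first-order, 14 shape,
24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM — with fixed-bin-width
discretization anchored at the region minimum (25 HU for CT, 0.25 SUV
for PET).  Feature names follow the customary radiomics nomenclature.

Gray levels are 1-based; texture matrices use 13 unique 3-D directions
(GLCM, GLRLM) or 26-connectivity (GLSZM, GLDM, NGTDM).  Texture features
of single-voxel regions are reported as NaN (missing), never as silent
zeros.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

_EPS = np.spacing(1.0)

#: 13 unique direction vectors (z, y, x) covering the 26-neighbourhood
#: up to sign.
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile", "90Percentile",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "Kurtosis", "Variance", "Uniformity",
]
SHAPE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity",
    "Maximum3DDiameter", "Maximum2DDiameterSlice", "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow", "MajorAxisLength", "MinorAxisLength", "LeastAxisLength",
    "Elongation", "Flatness",
]
GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
    "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
]


def base_feature_names() -> list[str]:
    """The 107 feature names in stable order, prefixed by family."""
    names = []
    names += [f"firstorder_{n}" for n in FIRSTORDER_NAMES]
    names += [f"shape_{n}" for n in SHAPE_NAMES]
    names += [f"glcm_{n}" for n in GLCM_NAMES]
    names += [f"glrlm_{n}" for n in GLRLM_NAMES]
    names += [f"glszm_{n}" for n in GLSZM_NAMES]
    names += [f"ngtdm_{n}" for n in NGTDM_NAMES]
    names += [f"gldm_{n}" for n in GLDM_NAMES]
    assert len(names) == 107
    return names


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization to 1-based gray levels.

    Bin edges are anchored at the region minimum: level = floor((x - min)
    / width) + 1, so a shift of the whole region leaves levels unchanged.
    """
    values = np.asarray(values, dtype=np.float64)
    return np.floor((values - values.min()) / bin_width).astype(np.int64) + 1


def _discretized_volume(volume, mask, bin_width):
    """Gray-level volume: 1..Ng inside the mask, 0 outside."""
    disc = np.zeros(volume.shape, dtype=np.int64)
    disc[mask] = discretize(volume[mask], bin_width)
    return disc, int(disc.max())


# ---------------------------------------------------------------------------
# first order


def firstorder_features(values: np.ndarray, bin_width: float, voxel_volume: float = 1.0) -> dict:
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:] / n
    p = p[p > 0]
    mean = x.mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    var = x.var()
    sd = np.sqrt(var)
    m3 = np.mean((x - mean) ** 3)
    m4 = np.mean((x - mean) ** 4)
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / sd**3) if sd > 0 else 0.0,
        "Kurtosis": float(m4 / var**2) if var > 0 else 0.0,
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# shape


def _max_pairwise_distance(coords: np.ndarray) -> float:
    """Largest pairwise Euclidean distance, via the convex hull when large."""
    if coords.shape[0] < 2:
        return 0.0
    pts = coords.astype(np.float64)
    if pts.shape[0] > 400:
        try:
            pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except QhullError:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict:
    mask = np.asarray(mask).astype(bool)
    spacing = np.asarray(spacing, dtype=np.float64)
    coords = np.argwhere(mask) * spacing  # physical (z, y, x)
    n = coords.shape[0]
    voxel_volume = float(np.prod(spacing))

    # light smoothing before meshing suppresses the voxel staircase, which
    # would otherwise bias the surface area (and hence sphericity) upward
    padded = ndimage.gaussian_filter(np.pad(mask, 2).astype(np.float64), sigma=0.8)
    padded = np.clip(padded, 0.0, 1.0)
    if padded.max() <= 0.5:  # tiny regions: smoothing can erase the surface
        padded = np.pad(mask, 2).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    surface_area = float(mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)

    # surface voxels only, for the diameter searches
    eroded = ndimage.binary_erosion(mask)
    surf = np.argwhere(mask & ~eroded) * spacing

    def max2d(axis):
        best = 0.0
        idx = np.argwhere(mask & ~eroded)
        for v in np.unique(idx[:, axis]):
            pts = idx[idx[:, axis] == v] * spacing
            keep = [a for a in range(3) if a != axis]
            best = max(best, _max_pairwise_distance(pts[:, keep]))
        return best

    # principal axes from the physical-coordinate covariance
    if n > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": float(n * voxel_volume),
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else np.nan,
        "Sphericity": float((36 * np.pi * mesh_volume**2) ** (1 / 3) / surface_area)
        if surface_area > 0
        else np.nan,
        "Maximum3DDiameter": _max_pairwise_distance(surf),
        "Maximum2DDiameterSlice": max2d(0),   # within an axial (y, x) plane
        "Maximum2DDiameterColumn": max2d(2),  # within a sagittal (z, y) plane
        "Maximum2DDiameterRow": max2d(1),     # within a coronal (z, x) plane
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrices(disc: np.ndarray, ng: int):
    """Symmetric co-occurrence matrix per direction, normalized."""
    mats = []
    for d in DIRECTIONS_13:
        src = [slice(max(0, -o), disc.shape[a] - max(0, o)) for a, o in enumerate(d)]
        dst = [slice(max(0, o), disc.shape[a] - max(0, -o)) for a, o in enumerate(d)]
        a = disc[tuple(src)].ravel()
        b = disc[tuple(dst)].ravel()
        keep = (a > 0) & (b > 0)
        a, b = a[keep], b[keep]
        if a.size == 0:
            continue
        m = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(m, (a - 1, b - 1), 1.0)
        m = m + m.T
        mats.append(m / m.sum())
    return mats


def _glcm_features_single(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(ii * p))  # symmetric: mu_x == mu_y
    sigma2 = float(np.sum((ii - mu) ** 2 * p))
    sigma = np.sqrt(sigma2)

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    px_nz = px[px > 0]
    hx = float(-np.sum(px_nz * np.log2(px_nz)))
    pxy = np.outer(px, px)
    both = nz & (pxy > 0)
    hxy1 = float(-np.sum(p[both] * np.log2(pxy[both])))
    pxy_nz = pxy[pxy > 0]
    hxy2 = float(-np.sum(pxy_nz * np.log2(pxy_nz)))

    diff_avg = float(np.sum(k_diff * p_diff))
    sum_nz = p_sum > 0
    diff_nz = p_diff > 0

    # maximal correlation coefficient: second-largest singular value of Q
    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / px[:, None]) @ (p / px[:, None]).T  # uses symmetry p_y = p_x
        q = np.nan_to_num(q)
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(np.clip(ev[-2], 0, 1)))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float((np.sum(ii * jj * p) - mu * mu) / sigma2) if sigma2 > 0 else 1.0,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff[diff_nz] * np.log2(p_diff[diff_nz]))),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": float((hxy - hxy1) / hx) if hx > 0 else 0.0,
        "Imc2": float(np.sqrt(1 - np.exp(-2.0 * max(hxy2 - hxy, 0)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": float(np.sum(p[ii != jj] / (ii - jj)[ii != jj] ** 2)),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum[sum_nz] * np.log2(p_sum[sum_nz]))),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


def glcm_features(disc: np.ndarray, ng: int) -> dict:
    """24 co-occurrence features averaged over the 13 directions."""
    mats = _glcm_matrices(disc, ng)
    if not mats:
        return {n: np.nan for n in GLCM_NAMES}
    per = [_glcm_features_single(m) for m in mats]
    return {n: float(np.mean([f[n] for f in per])) for n in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def _runs_along(disc: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and length of every run along one direction.

    Lines are enumerated by offsetting each voxel back along the
    direction; runs of equal nonzero gray level within a line are counted.
    """
    shape = disc.shape
    coords = np.indices(shape).reshape(3, -1)
    d = np.asarray(direction)
    axis = int(np.nonzero(d)[0][0])
    t = coords[axis] * d[axis]  # position along the line (d components in {-1,0,1})
    keys = coords - t[None, :] * d[:, None]
    order = np.lexsort((t, keys[2], keys[1], keys[0]))
    g = disc.reshape(-1)[order]
    k0, k1, k2 = keys[0][order], keys[1][order], keys[2][order]
    new_line = np.ones(g.size, dtype=bool)
    new_line[1:] = (np.diff(k0) != 0) | (np.diff(k1) != 0) | (np.diff(k2) != 0)
    new_run = new_line.copy()
    new_run[1:] |= g[1:] != g[:-1]
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    levels = g[new_run]
    keep = levels > 0
    return levels[keep], lengths[keep]


def _rl_style_features(mat: np.ndarray, n_voxels: int, names: list[str], kind: str) -> dict:
    """Shared feature formulas for run-length-type matrices.

    ``mat[i, l]`` counts runs/zones/dependencies of gray level i+1 and
    size l+1.  ``kind`` selects the naming scheme (run / zone / dependence).
    """
    nr = mat.sum()
    if nr == 0:
        return {n: np.nan for n in names}
    i = np.arange(1, mat.shape[0] + 1)[:, None].astype(np.float64)
    l = np.arange(1, mat.shape[1] + 1)[None, :].astype(np.float64)
    p = mat / nr
    gl_marg = mat.sum(axis=1)
    sz_marg = mat.sum(axis=0)
    mu_i = np.sum(p * i)
    mu_l = np.sum(p * l)
    pz = p[p > 0]

    vals = {
        "small": float(np.sum(mat / l**2) / nr),
        "large": float(np.sum(mat * l**2) / nr),
        "gln": float(np.sum(gl_marg**2) / nr),
        "glnn": float(np.sum(gl_marg**2) / nr**2),
        "szn": float(np.sum(sz_marg**2) / nr),
        "sznn": float(np.sum(sz_marg**2) / nr**2),
        "pct": float(nr / n_voxels),
        "glvar": float(np.sum(p * (i - mu_i) ** 2)),
        "szvar": float(np.sum(p * (l - mu_l) ** 2)),
        "entropy": float(-np.sum(pz * np.log2(pz))),
        "lgl": float(np.sum(mat / i**2) / nr),
        "hgl": float(np.sum(mat * i**2) / nr),
        "slgl": float(np.sum(mat / (i**2 * l**2)) / nr),
        "shgl": float(np.sum(mat * i**2 / l**2) / nr),
        "llgl": float(np.sum(mat * l**2 / i**2) / nr),
        "lhgl": float(np.sum(mat * i**2 * l**2) / nr),
    }
    if kind == "run":
        order = ["small", "large", "gln", "glnn", "szn", "sznn", "pct", "glvar",
                 "szvar", "entropy", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl"]
    elif kind == "zone":
        order = ["small", "large", "gln", "glnn", "szn", "sznn", "pct", "glvar",
                 "szvar", "entropy", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl"]
    else:  # dependence: 14 features, no zone-percentage / size-nonuniformity-normalized pair
        order = ["small", "large", "gln", "szn", "sznn", "glvar", "szvar", "entropy",
                 "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl"]
    return dict(zip(names, (vals[k] for k in order)))


def glrlm_features(disc: np.ndarray, ng: int, n_voxels: int) -> dict:
    """16 run-length features averaged over the 13 directions."""
    max_len = max(disc.shape)
    per_dir = []
    for d in DIRECTIONS_13:
        levels, lengths = _runs_along(disc, d)
        if levels.size == 0:
            continue
        mat = np.zeros((ng, max_len), dtype=np.float64)
        np.add.at(mat, (levels - 1, lengths - 1), 1.0)
        per_dir.append(_rl_style_features(mat, n_voxels, GLRLM_NAMES, "run"))
    if not per_dir:
        return {n: np.nan for n in GLRLM_NAMES}
    return {n: float(np.mean([f[n] for f in per_dir])) for n in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(disc: np.ndarray, ng: int, n_voxels: int) -> dict:
    """16 size-zone features; zones are 26-connected equal-level components."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zones = []  # (level, size)
    for g in range(1, ng + 1):
        labeled, nlab = ndimage.label(disc == g, structure=structure)
        if nlab:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((g, s) for s in sizes)
    if not zones:
        return {n: np.nan for n in GLSZM_NAMES}
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return _rl_style_features(mat, n_voxels, GLSZM_NAMES, "zone")


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(disc: np.ndarray, ng: int) -> dict:
    """5 neighbourhood gray-tone difference features (26-neighbourhood)."""
    mask = disc > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.correlate(disc.astype(np.float64) * mask, kernel, mode="constant")
    nbr_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant")
    valid = mask & (nbr_cnt > 0)
    nv = int(valid.sum())
    if nv == 0:
        return {n: np.nan for n in NGTDM_NAMES}
    avg = nbr_sum[valid] / nbr_cnt[valid]
    lvl = disc[valid].astype(np.float64)

    levels = np.arange(1, ng + 1, dtype=np.float64)
    n_i = np.array([(lvl == g).sum() for g in levels], dtype=np.float64)
    s_i = np.array([np.abs(lvl[lvl == g] - avg[lvl == g]).sum() for g in levels])
    p_i = n_i / nv
    present = p_i > 0
    ngp = int(present.sum())

    coarse_den = float(np.sum(p_i * s_i))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p_i, p_i, indexing="ij")
        gi, gj = np.meshgrid(levels, levels, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = (
            np.sum((pi * pj * (gi - gj) ** 2)[both]) / (ngp * (ngp - 1))
        ) * (s_i.sum() / nv)
        busy_den = float(np.sum(np.abs(gi * pi - gj * pj)[both]))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        si, sj = np.meshgrid(s_i, s_i, indexing="ij")
        complexity = float(
            np.sum((np.abs(gi - gj) * (pi * si + pj * sj) / (pi + pj + _EPS))[both]) / nv
        )
        s_sum = s_i.sum()
        strength = float(np.sum(((pi + pj) * (gi - gj) ** 2)[both]) / s_sum) if s_sum > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(disc: np.ndarray, ng: int, n_voxels: int, alpha: float = 0.0) -> dict:
    """14 dependence features: counts of similar 26-neighbours per voxel."""
    mask = disc > 0
    dep = np.zeros(disc.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for sign in (1, -1):
            o = tuple(sign * c for c in d)
            src = tuple(slice(max(0, -x), disc.shape[a] - max(0, x)) for a, x in enumerate(o))
            dst = tuple(slice(max(0, x), disc.shape[a] - max(0, -x)) for a, x in enumerate(o))
            similar = np.zeros(disc.shape, dtype=bool)
            similar[src] = (
                mask[src] & mask[dst] & (np.abs(disc[src] - disc[dst]) <= alpha)
            )
            dep += similar
    dep_count = dep[mask] + 1  # dependence includes the center voxel
    levels = disc[mask]
    max_dep = int(dep_count.max())
    mat = np.zeros((ng, max_dep), dtype=np.float64)
    np.add.at(mat, (levels - 1, dep_count - 1), 1.0)
    return _rl_style_features(mat, n_voxels, GLDM_NAMES, "dependence")


# ---------------------------------------------------------------------------
# entry point


def extract_base_features(
    volume: np.ndarray,
    mask: np.ndarray,
    bin_width: float,
    spacing=(1.0, 1.0, 1.0),
) -> dict[str, float]:
    """All 107 base features of one region of one modality volume.

    ``volume`` and ``mask`` share a grid (typically the lesion bounding
    box); ``bin_width`` is the fixed discretization width (25 HU for CT,
    0.25 SUV for PET).  Texture families of regions with fewer than 2
    voxels are NaN.
    """
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region")
    out: dict[str, float] = {}
    vv = float(np.prod(spacing))
    fo = firstorder_features(volume[mask], bin_width, vv)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})
    sh = shape_features(mask, spacing)
    out.update({f"shape_{k}": v for k, v in sh.items()})

    if n < 2:
        for fam, names in (
            ("glcm", GLCM_NAMES), ("glrlm", GLRLM_NAMES), ("glszm", GLSZM_NAMES),
            ("ngtdm", NGTDM_NAMES), ("gldm", GLDM_NAMES),
        ):
            out.update({f"{fam}_{k}": np.nan for k in names})
        return out

    disc, ng = _discretized_volume(volume, mask, bin_width)
    out.update({f"glcm_{k}": v for k, v in glcm_features(disc, ng).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(disc, ng, n).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(disc, ng, n).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(disc, ng).items()})
    out.update({f"gldm_{k}": v for k, v in gldm_features(disc, ng, n).items()})
    return out
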