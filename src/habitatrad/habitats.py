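"""Intratumoral habitat generation.

Three methods partition each lesion into habitats:

* **adapted clustering** — per-lesion k-means over a 4-channel feature
  hypervolume (PET SUV, CT intensity, PET local entropy, CT local entropy)
  into supervoxels whose count adapts to lesion volume (fixed ~729 mm^3
  per supervoxel), globally min-max normalized, then cohort-level k-means
  over supervoxel centroids with the habitat count chosen by the
  Calinski-Harabasz (CH) index over k = 2..10;
* **conventional clustering** — same two-stage scheme but with a fixed
  supervoxel count per lesion and local (9x9x9 neighbourhood) min-max
  normalization;
* **Otsu intersection** — per-lesion Otsu thresholds on masked PET and CT
  intersected into four fixed habitats (PET low/high x CT low/high).

Habitat indices from the clustering methods are ordered by ascending mean
PET SUV of the habitat centers, so the highest index is always the
highest-uptake signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .io_preprocess import VoiPair

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("pet_suv", "ct_intensity", "pet_local_entropy", "ct_local_entropy")

#: Physical supervoxel volume for the adaptive method (9 mm cube).
DEFAULT_SUPERVOXEL_VOLUME_MM3 = 729.0
#: Fixed per-lesion supervoxel count for the conventional method.
DEFAULT_FIXED_SUPERVOXELS = 50
DEFAULT_K_RANGE = range(2, 11)

# Otsu-intersection habitat codes (PET x CT)
OTSU_CODES = {
    (0, 0): 1,  # PET low,  CT low
    (0, 1): 2,  # PET low,  CT high
    (1, 0): 3,  # PET high, CT low
    (1, 1): 4,  # PET high, CT high
}
OTSU_CODE_NAMES = {
    1: "PET_low&CT_low",
    2: "PET_low&CT_high",
    3: "PET_high&CT_low",
    4: "PET_high&CT_high",
}


@dataclass
class FeatureHypervolume:
    """Per-voxel 4-channel feature stack over a lesion's bounding box."""

    channels: np.ndarray  # (4, depth, height, width)
    mask: np.ndarray  # (depth, height, width) binary, same box
    lesion_id: str = "lesion"

    def __post_init__(self) -> None:
        if self.channels.ndim != 4 or self.channels.shape[0] != 4:
            raise ValueError(f"expected shape (4, d, h, w), got {self.channels.shape}")
        if self.channels.shape[1:] != self.mask.shape:
            raise ValueError("hypervolume and mask shapes differ")
        if np.any(self.channels[2:] < -1e-9):
            raise ValueError("entropy channels must be non-negative")

    def masked_vectors(self) -> np.ndarray:
        """Feature 4-vectors of masked voxels, shape (n_voxels, 4)."""
        return self.channels[:, self.mask.astype(bool)].T


@dataclass
class SupervoxelSet:
    """Per-lesion supervoxel partition of the masked voxels."""

    lesion_id: str
    labels: np.ndarray  # per masked voxel, values 0..k_sv-1 (flat, mask order)
    centroids: np.ndarray  # (k_sv, 4) mean feature vectors
    k_sv: int
    mask: np.ndarray  # binary box mask, for mapping labels back to voxels
    label: str = "NSCLC"

    def label_volume(self) -> np.ndarray:
        """Supervoxel index per voxel (+1, 0 = background)."""
        out = np.zeros(self.mask.shape, dtype=np.int32)
        out[self.mask.astype(bool)] = self.labels + 1
        return out


@dataclass
class HabitatModel:
    """Cohort-level habitat definition: cluster centers or Otsu scheme."""

    method: str  # adapted | conventional | otsu
    n_habitats: int
    centers: np.ndarray | None = None  # (n_habitats, 4), normalized scale
    ch_scores: dict[int, float] = field(default_factory=dict)
    norm_stats: dict | None = None  # {"min": (4,), "max": (4,)} for global norm

    def __post_init__(self) -> None:
        if self.method == "otsu":
            if self.n_habitats != 4:
                raise ValueError("Otsu method defines exactly 4 habitats")
        elif not 2 <= self.n_habitats <= 10:
            raise ValueError("clustering habitat count must lie in [2, 10]")


@dataclass
class HabitatLabelMap:
    """Per-voxel habitat assignment for one lesion (0 = background)."""

    lesion_id: str
    labels: np.ndarray  # (d, h, w) int, 0 outside mask
    n_habitats: int
    method: str

    @property
    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnt)}

    @property
    def proportions(self) -> dict[int, float]:
        c = self.counts
        total = sum(c.values())
        return {h: n / total for h, n in c.items()}


# ---------------------------------------------------------------------------
# hypervolume construction


def local_entropy_map(
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    neighborhood: int = 9,
    n_bins: int = 32,
) -> np.ndarray:
    """Per-voxel Shannon entropy (bits) over a cubic neighbourhood histogram.

    Intensities are binned into ``n_bins`` equal-width bins spanning the
    masked (or global) intensity range; each voxel's entropy is that of
    the bin-occupancy distribution over its ``neighborhood``-cube, with
    boundary voxels using the truncated cube.  When a mask is given, the
    histogram counts only masked neighbours, so the texture estimate
    reflects the lesion rather than the surrounding background.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd and >= 3")
    volume = np.asarray(volume, dtype=np.float64)
    include = np.ones(volume.shape, dtype=np.float64) if mask is None else mask.astype(np.float64)
    ref = volume[include.astype(bool)]
    lo, hi = float(ref.min()), float(ref.max())
    if hi <= lo:
        return np.zeros_like(volume)
    # digitize into [0, n_bins): equal-width bins over the reference range
    idx = np.clip(((volume - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)

    def boxsum(x):
        # zero-padded box sum via the separable uniform filter
        return ndimage.uniform_filter(x, size=neighborhood, mode="constant", cval=0.0) * (
            neighborhood**3
        )

    denom = boxsum(include)
    entropy = np.zeros_like(volume)
    for b in range(n_bins):
        cnt = boxsum(((idx == b) * include).astype(np.float64))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, cnt / np.where(denom > 0, denom, 1.0), 0.0)
            term = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        entropy += term
    return np.clip(entropy, 0.0, None)


def bounding_box(mask: np.ndarray, pad: int = 0) -> tuple[slice, slice, slice]:
    """Tight bounding-box slices of a binary mask, optionally padded."""
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("empty mask has no bounding box")
    lo = np.maximum(coords.min(axis=0) - pad, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def build_hypervolume(
    voi: VoiPair, neighborhood: int = 9, n_bins: int = 32, crop: bool = True
) -> FeatureHypervolume:
    """Stack PET SUV, CT intensity, and their local entropies over the VOI box.

    The spatial shape is the mask's bounding box (or the full grid when
    ``crop`` is false); a 64x64x64 VOI yields a 4x64x64x64 hypervolume.
    """
    box = bounding_box(voi.mask.voxels) if crop else tuple([slice(None)] * 3)
    pet = voi.pet.voxels[box]
    ct = voi.ct.voxels[box]
    mask = voi.mask.voxels[box]
    pet_ent = local_entropy_map(pet, mask, neighborhood, n_bins)
    ct_ent = local_entropy_map(ct, mask, neighborhood, n_bins)
    channels = np.stack([pet, ct, pet_ent, ct_ent])
    return FeatureHypervolume(channels=channels, mask=mask, lesion_id=voi.mask.lesion_id)


# ---------------------------------------------------------------------------
# supervoxels


def adaptive_supervoxel_count(
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    target_volume_mm3: float = DEFAULT_SUPERVOXEL_VOLUME_MM3,
) -> int:
    """Supervoxel count with a fixed physical volume per supervoxel.

    k = max(1, round(lesion volume / target volume)); small lesions get a
    single supervoxel rather than none.
    """
    n = int(np.asarray(mask).astype(bool).sum())
    if n == 0:
        raise ValueError("empty mask")
    volume = n * float(np.prod(spacing))
    return max(1, int(round(volume / target_volume_mm3)))


def normalize_global(
    hypervolumes: list[FeatureHypervolume],
) -> tuple[list[FeatureHypervolume], dict]:
    """Cohort-wide min-max normalization of each channel to [0, 1].

    The min/max are taken over the masked voxels of the whole cohort and
    returned as stats so later lesions can be mapped onto the same scale.
    """
    if not hypervolumes:
        raise ValueError("need at least one lesion")
    stacked = np.concatenate([hv.masked_vectors() for hv in hypervolumes], axis=0)
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    for c, (a, b) in enumerate(zip(lo, hi)):
        if b <= a:
            raise ValueError(f"channel {CHANNEL_NAMES[c]!r} is constant across the cohort")
    stats = {"min": lo, "max": hi}
    return [apply_global_norm(hv, stats) for hv in hypervolumes], stats


def apply_global_norm(hv: FeatureHypervolume, stats: dict) -> FeatureHypervolume:
    """Map a hypervolume onto a previously computed cohort [0, 1] scale."""
    lo = np.asarray(stats["min"], dtype=np.float64).reshape(4, 1, 1, 1)
    hi = np.asarray(stats["max"], dtype=np.float64).reshape(4, 1, 1, 1)
    channels = (hv.channels - lo) / (hi - lo)
    # keep entropy channels' non-negativity invariant under the affine map
    channels = np.clip(channels, 0.0, None)
    return FeatureHypervolume(channels=channels, mask=hv.mask, lesion_id=hv.lesion_id)


def normalize_local(hv: FeatureHypervolume, neighborhood: int = 9) -> FeatureHypervolume:
    """Per-voxel min-max normalization over the 9x9x9 neighbourhood.

    Each voxel is rescaled by the min/max of its own cubic neighbourhood
    (truncated at the volume boundary); constant neighbourhoods map to 0.
    """
    size = (neighborhood,) * 3
    out = np.empty_like(hv.channels)
    for c in range(4):
        vol = hv.channels[c]
        # 'nearest' edge extension replicates in-window boundary values, so
        # the filtered min/max equal those of the truncated window
        lo = ndimage.minimum_filter(vol, size=size, mode="nearest")
        hi = ndimage.maximum_filter(vol, size=size, mode="nearest")
        rng = hi - lo
        with np.errstate(divide="ignore", invalid="ignore"):
            out[c] = np.where(rng > 0, (vol - lo) / rng, 0.0)
    return FeatureHypervolume(channels=out, mask=hv.mask, lesion_id=hv.lesion_id)


def cluster_supervoxels(
    hv: FeatureHypervolume, k_sv: int, seed: int = 0, label: str = "NSCLC"
) -> SupervoxelSet:
    """K-means over the masked voxels' 4-vectors into ``k_sv`` supervoxels.

    Euclidean distance on the (normalized) feature vectors; centroids are
    member means.  Deterministic given the seed.
    """
    vectors = hv.masked_vectors()
    n = vectors.shape[0]
    if k_sv > n:
        raise ValueError(f"k_sv={k_sv} exceeds masked voxel count {n}")
    if k_sv == 1:
        labels = np.zeros(n, dtype=np.int32)
        centroids = vectors.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k_sv, n_init=10, random_state=seed)
        labels = km.fit_predict(vectors).astype(np.int32)
        # recompute centroids as plain member means (k-means centers already
        # are, but make the contract explicit)
        centroids = np.vstack(
            [
                vectors[labels == j].mean(axis=0) if np.any(labels == j) else km.cluster_centers_[j]
                for j in range(k_sv)
            ]
        )
    return SupervoxelSet(
        lesion_id=hv.lesion_id,
        labels=labels,
        centroids=centroids,
        k_sv=k_sv,
        mask=hv.mask.copy(),
        label=label,
    )


# ---------------------------------------------------------------------------
# cohort-level habitat clustering


def fit_habitat_model(
    supervoxel_sets: list[SupervoxelSet],
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    method: str = "adapted",
    norm_stats: dict | None = None,
) -> HabitatModel:
    """Cluster all lesions' supervoxel centroids; pick k by the CH index.

    For each candidate habitat count k the Calinski-Harabasz index
    (between-cluster over within-cluster dispersion, each per degree of
    freedom) is computed on the centroid clustering; the chosen k
    maximizes CH, ties broken toward smaller k.  Candidate k values not
    smaller than the number of supervoxels are skipped.
    """
    centroids = np.concatenate([s.centroids for s in supervoxel_sets], axis=0)
    n = centroids.shape[0]
    if n <= min(k_range):
        raise ValueError(f"only {n} supervoxels; need more than {min(k_range)}")
    ch_scores: dict[int, float] = {}
    fitted: dict[int, KMeans] = {}
    for k in k_range:
        if k >= n:
            logger.warning("skipping k=%d: only %d supervoxels", k, n)
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(centroids)
        if len(np.unique(labels)) < 2:
            continue
        ch_scores[k] = float(calinski_harabasz_score(centroids, labels))
        fitted[k] = km
    if not ch_scores:
        raise ValueError("no candidate habitat count could be evaluated")
    best = max(ch_scores.values())
    chosen = min(k for k, v in ch_scores.items() if v == best)
    centers = fitted[chosen].cluster_centers_
    # habitat 1..k ordered by ascending mean PET SUV of their centers
    order = np.argsort(centers[:, 0], kind="stable")
    centers = centers[order]
    logger.info("habitat model (%s): k=%d, CH=%s", method, chosen, ch_scores)
    return HabitatModel(
        method=method,
        n_habitats=chosen,
        centers=centers,
        ch_scores=ch_scores,
        norm_stats=norm_stats,
    )


def assign_habitats(model: HabitatModel, supervoxels: SupervoxelSet) -> HabitatLabelMap:
    """Assign each supervoxel to the nearest habitat center (Euclidean).

    Voxels inherit their supervoxel's habitat; habitat indices are 1-based
    per the model's PET-ordered centers.  Emits a warning when centroids
    lie outside the plausible normalized range.
    """
    if model.centers is None:
        raise ValueError("model has no cluster centers (is it an Otsu model?)")
    c = supervoxels.centroids
    if c.min() < -0.05 or c.max() > 1.05:
        logger.warning(
            "supervoxel centroids outside [0,1] (range %.3f..%.3f): "
            "input may not be on the model's normalization scale",
            c.min(),
            c.max(),
        )
    d2 = ((c[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
    habitat_of_sv = d2.argmin(axis=1) + 1  # 1-based
    vol = np.zeros(supervoxels.mask.shape, dtype=np.int32)
    vol[supervoxels.mask.astype(bool)] = habitat_of_sv[supervoxels.labels]
    return HabitatLabelMap(
        lesion_id=supervoxels.lesion_id,
        labels=vol,
        n_habitats=model.n_habitats,
        method=model.method,
    )


# ---------------------------------------------------------------------------
# Otsu-intersection method


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance (exhaustive search).

    Candidate cuts are the midpoints between consecutive distinct values;
    the returned threshold t splits into classes ``<= t`` and ``> t``.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("Otsu threshold undefined for constant input")
    counts = np.array([(values == u).sum() for u in uniq], dtype=np.float64)
    n = counts.sum()
    w0 = np.cumsum(counts)[:-1]  # class sizes below each cut
    m0 = np.cumsum(counts * uniq)[:-1] / w0
    w1 = n - w0
    m1 = (np.sum(counts * uniq) - np.cumsum(counts * uniq)[:-1]) / w1
    between = w0 / n * w1 / n * (m0 - m1) ** 2
    best = int(np.argmax(between))
    return float((uniq[best] + uniq[best + 1]) / 2.0)


def otsu_habitat_map(voi: VoiPair) -> HabitatLabelMap:
    """Four-habitat map from per-lesion Otsu thresholds on PET and CT.

    Habitats are the intersections PET{low,high} x CT{low,high}, coded
    1=low&low, 2=low&CT-high, 3=PET-high&low, 4=high&high.  Intersections
    can be empty; the codes stay fixed.
    """
    box = bounding_box(voi.mask.voxels)
    mask = voi.mask.voxels[box].astype(bool)
    pet = voi.pet.voxels[box]
    ct = voi.ct.voxels[box]
    for name, vol in (("PET", pet), ("CT", ct)):
        if np.unique(vol[mask]).size < 2:
            raise ValueError(f"{name} is constant within the mask; Otsu undefined")
    t_pet = otsu_threshold(pet[mask])
    t_ct = otsu_threshold(ct[mask])
    pet_high = (pet > t_pet).astype(np.int8)
    ct_high = (ct > t_ct).astype(np.int8)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = (2 * pet_high + ct_high + 1)[mask]
    return HabitatLabelMap(
        lesion_id=voi.mask.lesion_id, labels=labels, n_habitats=4, method="otsu"
    )


# ---------------------------------------------------------------------------
# convenience cohort drivers


def fit_clustering_habitats(
    vois: list[VoiPair],
    method: str = "adapted",
    *,
    supervoxel_volume_mm3: float = DEFAULT_SUPERVOXEL_VOLUME_MM3,
    fixed_supervoxels: int = DEFAULT_FIXED_SUPERVOXELS,
    k_range=DEFAULT_K_RANGE,
    neighborhood: int = 9,
    seed: int = 0,
) -> tuple[HabitatModel, list[HabitatLabelMap]]:
    """End-to-end habitat generation for a cohort by a clustering method.

    ``adapted`` uses volume-adaptive supervoxel counts and global
    normalization; ``conventional`` uses a fixed supervoxel count and
    local neighbourhood normalization.
    """
    if method not in ("adapted", "conventional"):
        raise ValueError(f"unknown clustering method {method!r}")
    hvs = [build_hypervolume(v, neighborhood=neighborhood) for v in vois]
    norm_stats = None
    if method == "adapted":
        hvs, norm_stats = normalize_global(hvs)
    else:
        hvs = [normalize_local(hv, neighborhood=neighborhood) for hv in hvs]
    sv_sets = []
    for voi, hv in zip(vois, hvs):
        if method == "adapted":
            k_sv = adaptive_supervoxel_count(
                voi.mask.voxels, voi.mask.spacing, supervoxel_volume_mm3
            )
        else:
            k_sv = min(fixed_supervoxels, int(hv.mask.sum()))
        sv_sets.append(cluster_supervoxels(hv, k_sv, seed=seed, label=voi.mask.label))
    model = fit_habitat_model(sv_sets, k_range=k_range, seed=seed, method=method, norm_stats=norm_stats)
    maps = [assign_habitats(model, s) for s in sv_sets]
    return model, maps
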