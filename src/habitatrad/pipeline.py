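"""End-to-end orchestration: preprocess -> habitats -> features -> models.

A single :class:`RunConfig` drives the whole comparison.  Seven model
variants are supported, combining four base feature tables:

    nonhabitat               whole-lesion features (the habitat pipeline
                             run with one whole-lesion region)
    otsu                     Otsu-intersection habitat features
    conventional             conventional clustering habitat features
    adapted                  adaptive clustering habitat features
    adapted+nonhabitat       column concatenation of the constituents
    otsu+nonhabitat          "
    adapted+otsu+nonhabitat  "

Combination variants concatenate feature columns at the lesion level:
the first constituent's rows are kept and every other constituent
contributes its per-lesion feature vector (its single whole-lesion row,
or the mean over its habitat rows), broadcast onto those rows.
Intermediate tables are cached on disk keyed by a hash of the governing
parameters, so a rerun with an unchanged config reloads them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import features as feat
from . import habitats as hab
from . import selection_modeling as sm
from .io_preprocess import VoiPair, load_manifest, load_voi_pair

logger = logging.getLogger(__name__)

BASE_METHODS = ("nonhabitat", "otsu", "conventional", "adapted")
ALL_VARIANTS = (
    "nonhabitat",
    "otsu",
    "conventional",
    "adapted",
    "adapted+nonhabitat",
    "otsu+nonhabitat",
    "adapted+otsu+nonhabitat",
)


@dataclass
class RunConfig:
    """Everything one comparison run needs."""

    manifest_path: str | None = None
    variants: tuple[str, ...] = ALL_VARIANTS
    out_dir: str = "habitatrad_run"
    seed: int = 0
    n_folds: int = 5
    k_range: tuple[int, int] = (2, 10)
    supervoxel_volume_mm3: float = hab.DEFAULT_SUPERVOXEL_VOLUME_MM3
    fixed_supervoxels: int = hab.DEFAULT_FIXED_SUPERVOXELS
    gate: str = "conventional"
    ct_window: str | tuple[float, float] = "custom"
    families: tuple[str, ...] = feat.ALL_FAMILIES
    pipelines: tuple[tuple[str, str], ...] | None = None  # None -> full 18 grid

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in ALL_VARIANTS:
                raise ValueError(f"unknown variant {v!r}; choose from {ALL_VARIANTS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML mapping of the fields above."""
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        for key in ("variants", "families", "k_range"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        if "pipelines" in payload and payload["pipelines"] is not None:
            payload["pipelines"] = tuple(tuple(p) for p in payload["pipelines"])
        return cls(**payload)

    def cache_key(self) -> str:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("out_dir", "manifest_path")
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class RunResult:
    tables: dict[str, pd.DataFrame]
    cv_reports: dict[str, dict[str, sm.CvReport]]
    comparison: sm.ComparisonReport
    habitat_models: dict[str, hab.HabitatModel] = field(default_factory=dict)


def _load_cohort(config: RunConfig) -> list[VoiPair]:
    manifest = load_manifest(config.manifest_path)
    vois = []
    for _, row in manifest.iterrows():
        vois.append(
            load_voi_pair(
                row.pet_path,
                row.ct_path,
                row.mask_path,
                window=config.ct_window,
                lesion_id=row.lesion_id,
                label=row.label,
                subtype=row.get("subtype", "none"),
            )
        )
    return vois


def _method_regions(method: str, vois: list[VoiPair], config: RunConfig, models: dict):
    """Per-lesion region lists for one base method."""
    if method == "nonhabitat":
        box_masks = []
        for voi in vois:
            box = hab.bounding_box(voi.mask.voxels)
            box_masks.append(
                [feat.whole_lesion_region(voi.mask.voxels[box], voi.mask.lesion_id, voi.mask.label)]
            )
        return box_masks
    if method == "otsu":
        maps = [hab.otsu_habitat_map(voi) for voi in vois]
        models["otsu"] = hab.HabitatModel(method="otsu", n_habitats=4)
    else:
        model, maps = hab.fit_clustering_habitats(
            vois,
            method,
            supervoxel_volume_mm3=config.supervoxel_volume_mm3,
            fixed_supervoxels=config.fixed_supervoxels,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            seed=config.seed,
        )
        models[method] = model
    return [
        feat.regions_from_habitat_map(m, label=voi.mask.label)
        for m, voi in zip(maps, vois)
    ]


def base_feature_tables(
    vois: list[VoiPair], methods, config: RunConfig, models: dict | None = None
) -> dict[str, pd.DataFrame]:
    """Extract one habitat-level (or whole-lesion) table per base method."""
    if models is None:
        models = {}
    tables = {}
    for method in methods:
        per_lesion = _method_regions(method, vois, config, models)
        parts = [
            feat.extract_all(voi, regions, families=config.families)
            for voi, regions in zip(vois, per_lesion)
        ]
        tables[method] = pd.concat(parts)
        logger.info("features[%s]: %s rows x %s columns", method, *tables[method].shape)
    return tables


def combine_variant_table(variant: str, base_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Build a variant's table; combinations concatenate prefixed columns."""
    parts = variant.split("+")
    primary = base_tables[parts[0]].copy()
    primary.columns = [f"{parts[0]}:{c}" for c in primary.columns]
    lesions = primary.index.get_level_values("lesion_id")
    for other in parts[1:]:
        t = base_tables[other]
        per_lesion = t.groupby(level="lesion_id").mean()
        broadcast = per_lesion.loc[lesions]
        broadcast.columns = [f"{other}:{c}" for c in broadcast.columns]
        broadcast.index = primary.index
        primary = pd.concat([primary, broadcast], axis=1)
    return primary


def run(config: RunConfig, vois: list[VoiPair] | None = None) -> RunResult:
    """Execute the configured comparison end-to-end.

    ``vois`` may be passed directly (e.g. a synthetic in-memory cohort);
    otherwise the manifest is loaded and preprocessed.  Results and
    intermediates are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    key = config.cache_key()
    if vois is None:
        if config.manifest_path is None:
            raise ValueError("either a manifest path or an in-memory cohort is required")
        vois = _load_cohort(config)

    needed = sorted({m for v in config.variants for m in v.split("+")})
    models: dict[str, hab.HabitatModel] = {}
    base_tables = {}
    for method in needed:
        cache = out / f"features_{method}_{key}.csv"
        if cache.exists():
            base_tables[method] = pd.read_csv(cache, index_col=[0, 1, 2])
            logger.info("cache hit: %s", cache)
        else:
            base_tables.update(base_feature_tables(vois, [method], config, models))
            base_tables[method].to_csv(cache)

    labels_by_lesion = {v.mask.lesion_id: v.mask.label for v in vois}
    pipelines = None
    if config.pipelines is not None:
        pipelines = [sm.PipelineSpec(s, c, config.seed) for s, c in config.pipelines]

    cv_reports: dict[str, dict[str, sm.CvReport]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for variant in config.variants:
        table = combine_variant_table(variant, base_tables)
        tables[variant] = table
        lesion_ids = pd.Series(table.index.get_level_values("lesion_id"))
        labels = lesion_ids.map(labels_by_lesion)
        cv_reports[variant] = sm.run_cv_grid(
            table.reset_index(drop=True),
            labels,
            lesion_ids,
            n_folds=config.n_folds,
            seed=config.seed,
            gate=config.gate,
            pipelines=pipelines,
        )

    comparison = sm.compare_methods(cv_reports)
    comparison.summary.to_csv(out / f"comparison_summary_{key}.csv")
    comparison.pairwise_p.to_csv(out / f"comparison_pvalues_{key}.csv")
    with open(out / f"run_{key}.json", "w") as fh:
        json.dump(
            {
                "variants": list(config.variants),
                "seed": config.seed,
                "summary": comparison.summary.to_dict(),
                "habitat_counts": {m: mod.n_habitats for m, mod in models.items()},
            },
            fh,
            indent=2,
        )
    return RunResult(tables=tables, cv_reports=cv_reports, comparison=comparison, habitat_models=models)
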