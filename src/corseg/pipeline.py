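"""End-to-end segmentation pipeline: whole-heart-guided multi-atlas mapping
of chambers and great vessels followed by geometric modelling of valves,
coronary arteries and conduction nodes.

The pipeline is a pure function of (CT image, WH mask, atlas set, config):
every atlas is registered to the target independently, the warped labels
are fused and binarised at (optionally leave-one-out-optimised) thresholds,
post-processed into a disjoint set, and the ten geometric structures are
added last. A whole-heart mask must be supplied (file or in-memory) or
produced by a pluggable backend with the single-operation contract
``backend(ct: VolumeGrid) -> BinaryMask``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .core import BinaryMask, VolumeGrid, read_mask, read_volume
from .fusion import (DEFAULT_THRESHOLD, ProbabilityMap, ThresholdTable, binarise, fuse,
                     optimise_threshold, postprocess)
from .geometry import ArteryParams, GeometricParams, NodeParams, ValveParams, build_all_geometric
from .metrics import MetricReport, compare_structure_sets
from .phantom import AtlasCase
from .register import (AffineParams, DemonsParams, RegistrationConfig, RegistrationError,
                       StructureGuidedParams, register_atlas)
from .structures import (CORONARY_ARTERIES, MULTI_ATLAS_STRUCTURES, StructureSet,
                         read_structure_set)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ConfigError",
    "run_case",
    "load_atlas_dir",
    "load_config",
    "save_config",
]

WHBackend = Callable[[VolumeGrid], BinaryMask]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the images themselves.

    ``thresholds`` is either a ThresholdTable, the string ``"optimise"``
    (leave-one-out optimisation over the warped atlas masks), or a float
    applied uniformly (default 0.5).
    """

    registration: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    geometric: GeometricParams = dc_field(default_factory=GeometricParams)
    thresholds: ThresholdTable | str | float = DEFAULT_THRESHOLD
    #: At least this fraction of atlas registrations must succeed.
    min_atlas_success_fraction: float = 0.5
    n_atlases: int = 10

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, str) and self.thresholds != "optimise":
            raise ConfigError(f"thresholds: unknown mode {self.thresholds!r}")
        if isinstance(self.thresholds, float) and not 0 < self.thresholds < 1:
            raise ConfigError("thresholds: uniform threshold must be in (0, 1)")
        if self.n_atlases < 1:
            raise ConfigError("n_atlases: must be >= 1")


@dataclass
class PipelineResult:
    structures: StructureSet
    report: MetricReport | None
    n_atlases_used: int
    atlas_wh_dsc: dict[str, float]
    thresholds: ThresholdTable
    stage_seconds: dict[str, float]


def _same_mask(a: BinaryMask, b: BinaryMask) -> bool:
    return a.grid.same_geometry(b.grid) and np.array_equal(a.values, b.values)


def _loo_thresholds(
    warped_sets: Mapping[str, StructureSet], structure_names: Sequence[str]
) -> ThresholdTable:
    """Leave-one-out threshold optimisation in target space: each warped
    atlas in turn serves as pseudo-reference against the fusion of the
    others."""
    case_ids = list(warped_sets)
    prob_maps: dict[str, list[ProbabilityMap]] = {n: [] for n in structure_names}
    ref_vols: dict[str, list[float]] = {n: [] for n in structure_names}
    for held_out in case_ids:
        others = [warped_sets[c] for c in case_ids if c != held_out]
        for name in structure_names:
            masks = [s[name] for s in others if name in s and not s[name].is_empty]
            ref = warped_sets[held_out].get(name)
            if not masks or ref is None or ref.is_empty:
                prob_maps[name].append(None)  # skipped with warning downstream
                ref_vols[name].append(None)
                continue
            prob_maps[name].append(fuse(masks))
            ref_vols[name].append(ref.volume_mm3)
    return optimise_threshold(prob_maps, ref_vols)


def run_case(
    ct: VolumeGrid,
    wh: BinaryMask | None,
    atlases: Sequence[AtlasCase],
    config: PipelineConfig | None = None,
    reference: StructureSet | None = None,
    wh_backend: WHBackend | None = None,
    case_id: str = "target",
) -> PipelineResult:
    """Segment the 18 cardiac structures on one CT volume.

    If the target case itself appears in the atlas set (identical WH mask,
    or matching ``case_id``) it is excluded, leaving n−1 atlases. Failed
    atlas registrations are dropped with a warning as long as at least
    ``min_atlas_success_fraction`` of atlases succeed.
    """
    config = config or PipelineConfig()
    if wh is None:
        if wh_backend is None:
            raise ValueError("either a WH mask or a WH backend must be supplied")
        wh = wh_backend(ct)
    if wh.is_empty:
        raise ValueError("whole-heart mask is empty")
    timings: dict[str, float] = {}

    usable = []
    for atlas in atlases:
        if atlas.case_id == case_id or _same_mask(atlas.structures["WH"], wh):
            logger.info("excluding atlas %s: it is the target case (leave-one-out)",
                        atlas.case_id)
            continue
        usable.append(atlas)

    t0 = time.perf_counter()
    warped_sets: dict[str, StructureSet] = {}
    wh_dsc: dict[str, float] = {}
    for atlas in usable:
        try:
            _, warped = register_atlas(atlas, ct, wh, config.registration)
        except RegistrationError as exc:
            logger.warning("atlas %s dropped: %s", atlas.case_id, exc)
            continue
        warped_sets[atlas.case_id] = warped
        if not warped["WH"].is_empty:
            from .metrics import dsc as _dsc

            wh_dsc[atlas.case_id] = _dsc(warped["WH"], wh)
    timings["registration"] = time.perf_counter() - t0
    if not usable or len(warped_sets) < config.min_atlas_success_fraction * len(usable):
        raise RuntimeError(
            f"only {len(warped_sets)} of {len(usable)} atlas registrations succeeded"
        )
    logger.info("registered %d atlases in %.1f s", len(warped_sets), timings["registration"])

    # label fusion + thresholds + post-processing for the 7 multi-atlas structures
    t0 = time.perf_counter()
    if isinstance(config.thresholds, ThresholdTable):
        table = config.thresholds
    elif config.thresholds == "optimise":
        table = _loo_thresholds(warped_sets, MULTI_ATLAS_STRUCTURES)
    else:
        table = ThresholdTable.uniform(float(config.thresholds))

    fused = StructureSet()
    for name in MULTI_ATLAS_STRUCTURES:
        masks = [s[name] for s in warped_sets.values() if name in s and not s[name].is_empty]
        if not masks:
            raise RuntimeError(f"no atlas produced structure {name}")
        fused[name] = binarise(fuse(masks), table.get(name, DEFAULT_THRESHOLD))
    fused = postprocess(fused)
    fused["WH"] = wh
    timings["fusion"] = time.perf_counter() - t0

    # geometric structures
    t0 = time.perf_counter()
    warped_arteries = {
        name: [s[name] for s in warped_sets.values() if name in s and not s[name].is_empty]
        for name in CORONARY_ARTERIES
    }
    result = build_all_geometric(fused, warped_arteries, config.geometric)
    timings["geometric"] = time.perf_counter() - t0
    logger.info("stage timings: %s", {k: round(v, 1) for k, v in timings.items()})

    report = compare_structure_sets(result, reference, case_id=case_id) if reference else None
    return PipelineResult(
        structures=result,
        report=report,
        n_atlases_used=len(warped_sets),
        atlas_wh_dsc=wh_dsc,
        thresholds=table,
        stage_seconds=timings,
    )


# -- atlas and config I/O ---------------------------------------------------

def load_atlas_dir(directory) -> list[AtlasCase]:
    """Load atlas cases from ``directory/<case>/image.nii.gz`` +
    ``directory/<case>/structures/*.nii.gz``."""
    directory = Path(directory)
    cases = []
    for case_dir in sorted(p for p in directory.iterdir() if p.is_dir()):
        image_path = case_dir / "image.nii.gz"
        struct_dir = case_dir / "structures"
        if not image_path.exists() or not struct_dir.is_dir():
            logger.warning("skipping %s: not an atlas case directory", case_dir)
            continue
        cases.append(AtlasCase(
            case_id=case_dir.name,
            image=read_volume(image_path),
            structures=read_structure_set(struct_dir),
        ))
    if not cases:
        raise ValueError(f"no atlas cases found in {directory}")
    return cases


def _params_to_dict(obj) -> dict:
    from dataclasses import asdict

    return asdict(obj)


def save_config(config: PipelineConfig, path) -> None:
    thresholds = config.thresholds
    if isinstance(thresholds, ThresholdTable):
        thresholds = dict(thresholds)
    doc = {
        "registration": _params_to_dict(config.registration),
        "geometric": _params_to_dict(config.geometric),
        "thresholds": thresholds,
        "min_atlas_success_fraction": config.min_atlas_success_fraction,
        "n_atlases": config.n_atlases,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _build(section: str, cls, doc: dict):
    try:
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; raises ConfigError naming the offending
    field on invalid input."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    reg = doc.get("registration", {})
    registration = RegistrationConfig(
        affine=_build("registration.affine", AffineParams, reg.get("affine", {})),
        structure_guided=_build("registration.structure_guided", StructureGuidedParams,
                                reg.get("structure_guided", {})),
        demons=_build("registration.demons", DemonsParams, reg.get("demons", {})),
        hu_window=tuple(reg["hu_window"]) if reg.get("hu_window") else None,
    )
    geo = doc.get("geometric", {})
    geometric = GeometricParams(
        valves=_build("geometric.valves", ValveParams, geo.get("valves", {})),
        arteries=_build("geometric.arteries", ArteryParams, geo.get("arteries", {})),
        nodes=_build("geometric.nodes", NodeParams, geo.get("nodes", {})),
    )
    thresholds = doc.get("thresholds", DEFAULT_THRESHOLD)
    if isinstance(thresholds, dict):
        t = ThresholdTable()
        for k, v in thresholds.items():
            try:
                t[k] = v
            except ValueError as exc:
                raise ConfigError(f"thresholds.{k}: {exc}") from exc
        thresholds = t
    return PipelineConfig(
        registration=registration,
        geometric=geometric,
        thresholds=thresholds,
        min_atlas_success_fraction=doc.get("min_atlas_success_fraction", 0.5),
        n_atlases=doc.get("n_atlases", 10),
    )
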