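"""End-to-end orchestration: segment -> shells -> profiles -> statistics.

A run consumes a list of (stack, condition) inputs, produces per-layer and
per-RO CSVs plus a two-group comparisons CSV when exactly two conditions
with enough nuclei are present, and writes a JSON manifest (full config
echo, per-image nucleus counts and d_max values, software version) from
which every CSV is reproducible given the input TIFFs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import __version__
from .errors import EmptyResultError, ValidationError
from .io import (
    VolumeImage,
    load_stack,
    profiles_to_frame,
    write_comparisons,
    write_mask,
    write_profiles,
    write_ro_summaries,
)
from .segment import LabelMask, SegmentationParams, segment_stack
from .shells import RadialProfile, assign_shells, distance_transform, layer_profile
from .stats import aggregate_ro, compare_groups

logger = logging.getLogger("nucshell")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "analyse_volume"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run.

    ``inputs`` is a sequence of ``(path, condition)`` pairs; K defaults to
    24 layers grouped into 6 regions of interest of 4 layers each, with
    significance assessed at alpha = 0.05.
    """

    inputs: tuple[tuple[str, str], ...]
    spacing_um: tuple[float, float, float]
    outdir: str
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    K: int = 24
    metric_mode: str = "physical"
    ro_size: int = 4
    alpha: float = 0.05
    export_masks: bool = False
    export_shells: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if self.K % self.ro_size != 0:
            raise ValidationError(f"ro_size={self.ro_size} must divide K={self.K}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        object.__setattr__(self, "inputs", tuple((str(p), str(c)) for p, c in self.inputs))


@dataclass
class RunResult:
    profiles: list[RadialProfile]
    summaries: dict[str, list]
    comparisons: dict[str, list]
    manifest: dict


def analyse_volume(
    img: VolumeImage,
    params: SegmentationParams | None = None,
    K: int = 24,
    metric_mode: str = "physical",
) -> tuple[LabelMask, list[RadialProfile], dict[int, float]]:
    """Segment one stack and profile every surviving nucleus.

    Returns the label mask, the per-nucleus layer profiles, and each
    nucleus's maximum boundary distance (µm in physical mode).
    """
    labels = segment_stack(img, params)
    if labels.n_objects == 0:
        raise EmptyResultError(f"no nuclei survive segmentation in image {img.source_id!r}")
    dmap = distance_transform(labels, metric_mode)
    shells = assign_shells(dmap, labels, K)
    profiles = layer_profile(img, shells, labels)
    for p in profiles:
        missing = p.missing_layers
        if missing.size:
            logger.warning(
                "image %s nucleus %d: empty layers %s", img.source_id, p.nucleus_id, missing.tolist()
            )
    return labels, profiles, shells.per_nucleus_dmax


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis over all configured inputs and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_profiles: list[RadialProfile] = []
    image_records = []
    for path, condition in config.inputs:
        img = load_stack(path, config.spacing_um, condition=condition)
        labels, profiles, dmax = analyse_volume(
            img, config.segmentation, config.K, config.metric_mode
        )
        all_profiles.extend(profiles)
        image_records.append(
            {
                "path": str(path),
                "source_id": img.source_id,
                "condition": condition,
                "n_nuclei": labels.n_objects,
                "dmax_um": {str(k): v for k, v in dmax.items()},
            }
        )
        if config.export_masks:
            write_mask(labels.labels, outdir / f"{img.source_id}_mask.tif")
        if config.export_shells:
            dmap = distance_transform(labels, config.metric_mode)
            shells = assign_shells(dmap, labels, config.K)
            write_mask(shells.layer, outdir / f"{img.source_id}_shells.tif")

    write_profiles(all_profiles, outdir / "layers.csv")

    by_condition: dict[str, list[RadialProfile]] = {}
    for p in all_profiles:
        by_condition.setdefault(p.condition, []).append(p)

    summaries = {
        cond: aggregate_ro(profiles, config.ro_size) for cond, profiles in by_condition.items()
    }
    write_ro_summaries(
        [s for group in summaries.values() for s in group], outdir / "ro_summary.csv"
    )

    comparisons: dict[str, list] = {}
    skip_reason = None
    conditions = sorted(by_condition)
    if len(conditions) == 2:
        a, b = (by_condition[c] for c in conditions)
        if len(a) >= 2 and len(b) >= 2:
            comparisons = {
                "layer": compare_groups(a, b, unit="layer", alpha=config.alpha),
                "RO": compare_groups(a, b, unit="RO", alpha=config.alpha, ro_size=config.ro_size),
            }
            write_comparisons(
                comparisons["RO"] + comparisons["layer"], outdir / "comparisons.csv"
            )
        else:
            skip_reason = "a condition has < 2 nuclei; comparison stage skipped"
    else:
        skip_reason = f"{len(conditions)} condition(s) present; pairwise comparison needs exactly 2"
    if skip_reason:
        logger.warning(skip_reason)

    manifest = {
        "software": {"name": "nucshell", "version": __version__},
        "config": {
            "inputs": [list(pair) for pair in config.inputs],
            "spacing_um": list(config.spacing_um),
            "segmentation": dataclasses.asdict(config.segmentation),
            "K": config.K,
            "metric_mode": config.metric_mode,
            "ro_size": config.ro_size,
            "alpha": config.alpha,
            "seed": config.seed,
        },
        "images": image_records,
        "n_profiles": len(all_profiles),
        "comparison_skipped": skip_reason,
    }
    # morph_ops tuples -> lists for stable JSON
    manifest["config"]["segmentation"]["morph_ops"] = [
        list(op) for op in config.segmentation.morph_ops
    ]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(all_profiles, summaries, comparisons, manifest)
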