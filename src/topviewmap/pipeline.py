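"""High-level pipeline stages tying the modules together.

Each stage is a plain function over in-memory objects; the CLI wraps these
with file reading/writing.  ``run_study`` chains everything from a study
directory (images + delineations + metadata) to significance maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio
from .config import PipelineConfig
from .errors import ValidationError
from .maps import (
    AnimalMap,
    ConditionMap,
    ConditionStack,
    ReferenceMap,
    build_reference_map,
    condition_mean,
    difference_map,
    map_animal_to_reference,
    sampling_distribution,
    smooth_map_edges,
)
from .slices import SliceProfile, profile_slice
from .stats import SignificanceMaps, StatConfig, step_down_adjusted_p, threshold_and_contour

__all__ = ["profile_study", "build_maps", "compare_conditions", "run_study", "MapBundle"]


def profile_study(
    metadata: pd.DataFrame, geometry_dir: str | Path, config: PipelineConfig
) -> list[SliceProfile]:
    """Profile every slice listed in a metadata table.

    Geometry JSON files are located next to each image (same stem).  All
    per-slice failures are collected and reported together; any failure
    aborts the run.
    """
    geometry_dir = Path(geometry_dir)
    profiles = []
    failures = []
    for _, row in metadata.iterrows():
        meta = fileio.metadata_row_to_slice(row)
        img_path = geometry_dir / meta.filename
        geo_path = img_path.with_suffix(".json")
        try:
            if not img_path.exists():
                raise ValidationError(f"missing image {img_path}")
            if not geo_path.exists():
                raise ValidationError(f"missing delineation {geo_path}")
            image = fileio.read_image(img_path)
            delineation = fileio.read_delineation(geo_path)
            profiles.append(
                profile_slice(
                    image,
                    delineation,
                    meta,
                    config.k_points,
                    contour_window=config.contour_window,
                )
            )
        except Exception as exc:  # collected so the user sees all bad slices
            failures.append(f"{meta.animal}/{meta.filename}: {exc}")
    if failures:
        raise ValidationError(
            "profiling failed for {} slice(s):\n  {}".format(
                len(failures), "\n  ".join(failures)
            )
        )
    return profiles


@dataclass
class MapBundle:
    reference: ReferenceMap
    animal_maps: dict  # animal -> AnimalMap (edge-smoothed)
    stacks: dict  # condition -> ConditionStack
    condition_maps: dict  # condition -> ConditionMap
    sampling: dict  # lateral-resolution summary of the reference map


def build_maps(profiles: list[SliceProfile], config: PipelineConfig) -> MapBundle:
    """Animal maps -> reference map -> per-condition stacks and mean maps."""
    by_animal: dict = {}
    for p in profiles:
        by_animal.setdefault(p.metadata.animal, []).append(p)
    animal_maps = {
        animal: smooth_map_edges(
            AnimalMap.from_profiles(plist), w=config.smoothing_window
        )
        for animal, plist in by_animal.items()
    }
    reference = build_reference_map(
        list(animal_maps.values()), w=config.smoothing_window
    )
    by_condition: dict = {}
    for amap in animal_maps.values():
        by_condition.setdefault(amap.condition, []).append(amap)
    stacks = {}
    cmaps = {}
    for condition, maps_ in sorted(by_condition.items()):
        maps_ = sorted(maps_, key=lambda m: m.animal)
        rasters = np.stack(
            [map_animal_to_reference(m, reference) for m in maps_]
        )
        stack = ConditionStack(
            condition=condition,
            animals=[m.animal for m in maps_],
            rasters=rasters,
            reference=reference,
        )
        stacks[condition] = stack
        cmaps[condition] = condition_mean(
            stack,
            upsample=config.display_upsample,
            display_fwhm_intervals=config.display_fwhm_intervals,
        )
    return MapBundle(
        reference=reference,
        animal_maps=animal_maps,
        stacks=stacks,
        condition_maps=cmaps,
        sampling=sampling_distribution(reference),
    )


def compare_conditions(
    stack_a: ConditionStack, stack_b: ConditionStack, config: PipelineConfig
) -> tuple[SignificanceMaps, dict]:
    """Step-down permutation comparison of two condition stacks."""
    if not stack_a.reference.grid_matches(stack_b.reference):
        raise ValidationError("condition stacks are on different reference grids")
    stat_config = StatConfig(
        alpha=config.alpha,
        tails=config.tails,
        variance_fwhm=config.variance_fwhm,
        seed=config.seed,
    )
    maps = step_down_adjusted_p(stack_a.rasters, stack_b.rasters, config=stat_config)
    decision = threshold_and_contour(maps)
    return maps, decision


def run_study(
    study_dir: str | Path,
    config: PipelineConfig,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> dict:
    """End-to-end: profile a study directory, build maps, compare conditions.

    Returns a dict with the profiles, map bundle, difference map,
    significance maps and threshold decision.
    """
    study_dir = Path(study_dir)
    metadata = fileio.read_metadata(study_dir / "metadata.tsv")
    profiles = profile_study(metadata, study_dir, config)
    bundle = build_maps(profiles, config)
    conditions = sorted(bundle.stacks)
    if condition_a is None or condition_b is None:
        if len(conditions) != 2:
            raise ValidationError(
                f"study has conditions {conditions}; specify which two to compare"
            )
        condition_a, condition_b = conditions
    for c in (condition_a, condition_b):
        if c not in bundle.stacks:
            raise ValidationError(f"unknown condition {c!r}")
    delta = difference_map(
        bundle.condition_maps[condition_a], bundle.condition_maps[condition_b]
    )
    maps, decision = compare_conditions(
        bundle.stacks[condition_a], bundle.stacks[condition_b], config
    )
    return {
        "profiles": profiles,
        "bundle": bundle,
        "conditions": (condition_a, condition_b),
        "difference": delta,
        "significance": maps,
        "decision": decision,
    }
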