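"""ROI model for bundle dissection: seed pair, endpoint exclusion, and
hard/distance-modified exclusion masks.

The distance modification removes, from each neighbouring-bundle mask, the
voxels lying within a threshold distance (default 40 mm) of *both* seed
regions. Streamlines of the target bundle are thereby allowed to share the
near-seed corridor with neighbouring bundles while still being rejected if
they stray into those bundles' distal territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .formats import BinaryMask, distance_map, read_mask


@dataclass
class FilterConfig:
    """Thresholds of the acceptance rules.

    Defaults are the published operating point: a 40 mm near-seed corridor
    for the distance-modified exclusion masks, a 60 mm streamline length
    cap, a track-density threshold of 10 streamlines per voxel, and the
    stopping criteria of 1,000 accepted or 150 million generated candidate
    streamlines per seed.
    """

    distance_threshold_mm: float = 40.0
    max_length_mm: float = 60.0
    density_threshold: int = 10
    max_accepted: int = 1_000
    max_generated: int = 150_000_000
    traversal_step_mm: float | None = None  # default: half min voxel spacing
    both_seeds_required: bool = True
    corridor_conjunctive: bool = True  # AND reading of the near-seed rule
    reject_midpath_endpoint_exclude: bool = False

    def __post_init__(self) -> None:
        for name in ("distance_threshold_mm", "max_length_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("density_threshold", "max_accepted", "max_generated"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_accepted > self.max_generated:
            raise ValueError("max_accepted must not exceed max_generated")
        if self.traversal_step_mm is not None and self.traversal_step_mm <= 0:
            raise ValueError("traversal_step_mm must be positive")

    def step_for(self, spacing) -> float:
        if self.traversal_step_mm is not None:
            return self.traversal_step_mm
        return float(np.min(spacing)) / 2.0


@dataclass
class RoiModel:
    """Named region masks with dissection roles.

    seed_a plays the thalamic (MGN) role, seed_b the cortical (HG) role,
    endpoint_exclude the adjacent-cortex (STG) role; hard_exclude masks
    reject any traversal, soft_exclude masks reject traversal only outside
    the near-seed corridor (their modified versions are derived here).
    """

    seed_a: BinaryMask
    seed_b: BinaryMask
    endpoint_exclude: BinaryMask | None = None
    hard_exclude: dict[str, BinaryMask] = field(default_factory=dict)
    soft_exclude_raw: dict[str, BinaryMask] = field(default_factory=dict)
    soft_exclude_modified: dict[str, BinaryMask] = field(default_factory=dict)

    def validate(self) -> None:
        if self.seed_a.n_voxels == 0 or self.seed_b.n_voxels == 0:
            raise ValueError("seed masks must be non-empty")
        if not self.seed_a.same_grid(self.seed_b):
            raise ValueError("seed masks live on different grids")
        if np.any(self.seed_a.values & self.seed_b.values):
            raise ValueError("seed masks overlap; seeds must be disjoint")
        others = dict(self.hard_exclude)
        others.update(self.soft_exclude_raw)
        if self.endpoint_exclude is not None:
            others["endpoint_exclude"] = self.endpoint_exclude
        mismatched = [
            name for name, m in others.items() if not m.same_grid(self.seed_a)
        ]
        if mismatched:
            raise ValueError(
                "masks on a different grid than the seeds (resample explicitly "
                f"first): {', '.join(sorted(mismatched))}"
            )
        for name, mod in self.soft_exclude_modified.items():
            raw = self.soft_exclude_raw[name]
            if np.any(mod.values & ~raw.values):
                raise ValueError(
                    f"modified soft mask {name!r} is not a subset of its raw mask"
                )

    @property
    def grid(self) -> BinaryMask:
        return self.seed_a


def modify_exclusion_mask(
    mask: BinaryMask,
    seed_a: BinaryMask,
    seed_b: BinaryMask,
    threshold_mm: float,
    conjunctive: bool = True,
) -> BinaryMask:
    """Remove from ``mask`` the voxels closer than ``threshold_mm`` to both
    seeds (conjunctive reading, the default) or to either seed
    (``conjunctive=False``).

    "Closer than" is strict: voxels at exactly the threshold are kept.
    Distances are Euclidean world mm to the nearest set voxel of each seed.
    """
    if seed_a.n_voxels == 0 or seed_b.n_voxels == 0:
        raise ValueError("seed masks must be non-empty")
    if threshold_mm < 0:
        raise ValueError("threshold_mm must be >= 0")
    if threshold_mm == 0:
        return BinaryMask(values=mask.values.copy(), affine=mask.affine)
    da = distance_map(seed_a).values
    db = distance_map(seed_b).values
    if conjunctive:
        near = (da < threshold_mm) & (db < threshold_mm)
    else:
        near = (da < threshold_mm) | (db < threshold_mm)
    return BinaryMask(values=mask.values & ~near, affine=mask.affine)


def build_roi_model(
    mask_paths: Mapping[str, object],
    config: FilterConfig | None = None,
) -> RoiModel:
    """Assemble and validate a RoiModel from a role -> path mapping.

    ``mask_paths`` keys: ``seed_a``, ``seed_b`` (required), optional
    ``endpoint_exclude``, and optional ``hard_exclude`` / ``soft_exclude``
    sub-mappings of name -> path. All masks must share one voxel grid;
    resampling is deliberately not performed here.
    """
    config = config or FilterConfig()
    try:
        seed_a = read_mask(Path(str(mask_paths["seed_a"])))
        seed_b = read_mask(Path(str(mask_paths["seed_b"])))
    except KeyError as exc:
        raise ValueError(f"mask_paths is missing required role {exc}") from exc
    endpoint = None
    if mask_paths.get("endpoint_exclude"):
        endpoint = read_mask(Path(str(mask_paths["endpoint_exclude"])))
    hard = {
        name: read_mask(Path(str(p)))
        for name, p in dict(mask_paths.get("hard_exclude", {})).items()
    }
    soft_raw = {
        name: read_mask(Path(str(p)))
        for name, p in dict(mask_paths.get("soft_exclude", {})).items()
    }
    model = RoiModel(
        seed_a=seed_a,
        seed_b=seed_b,
        endpoint_exclude=endpoint,
        hard_exclude=hard,
        soft_exclude_raw=soft_raw,
    )
    model.soft_exclude_modified = {
        name: modify_exclusion_mask(
            m,
            seed_a,
            seed_b,
            config.distance_threshold_mm,
            conjunctive=config.corridor_conjunctive,
        )
        for name, m in soft_raw.items()
    }
    model.validate()
    return model


def finalize_roi_model(model: RoiModel, config: FilterConfig | None = None) -> RoiModel:
    """Compute the modified soft-exclusion masks for an in-memory model."""
    config = config or FilterConfig()
    model.soft_exclude_modified = {
        name: modify_exclusion_mask(
            m,
            model.seed_a,
            model.seed_b,
            config.distance_threshold_mm,
            conjunctive=config.corridor_conjunctive,
        )
        for name, m in model.soft_exclude_raw.items()
    }
    model.validate()
    return model
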