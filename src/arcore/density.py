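"""Track-density maps and the thresholded bundle-core mask.

The bundle core is defined as the set of voxels traversed by at least k
accepted streamlines (k = 10 by default), computed after merging the two
seed-direction tractograms. Traversal uses the same supersampled path
visitation as the filter, with each streamline counted at most once per
voxel (the `tckmap` convention).
"""

from __future__ import annotations

import numpy as np

from .filtering import _supersample, merge_tractograms
from .formats import BinaryMask, TractogramMM, VolumeGrid, world_to_voxel
from .roi import FilterConfig


def visited_voxels(s, grid: VolumeGrid, step_mm: float) -> np.ndarray:
    """(n, 3) unique in-grid voxel indices visited by one streamline."""
    pts = _supersample(np.asarray(s, dtype=np.float64), step_mm)
    idx, inside = world_to_voxel(pts, grid)
    idx = idx[inside]
    if len(idx) == 0:
        return idx.reshape(0, 3)
    return np.unique(idx, axis=0)


def track_density_map(
    t: TractogramMM, grid: VolumeGrid, step_mm: float | None = None
) -> VolumeGrid:
    """Per-voxel count of distinct streamlines whose path enters the voxel.

    Out-of-grid excursions are ignored; a streamline contributes at most 1
    to any voxel regardless of how often it re-enters it.
    """
    if step_mm is None:
        step_mm = float(np.min(grid.spacing)) / 2.0
    counts = np.zeros(grid.shape, dtype=np.int32)
    for s in t.streamlines:
        vox = visited_voxels(s, grid, step_mm)
        if len(vox):
            counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return VolumeGrid(values=counts, affine=grid.affine)


def threshold_density(density: VolumeGrid, k: int) -> BinaryMask:
    """Binary mask of voxels with count >= k ("at least k streamlines")."""
    if int(k) != k or k < 1:
        raise ValueError("k must be an integer >= 1")
    return BinaryMask(values=density.values >= k, affine=density.affine)


def build_core_mask(
    accepted_a: TractogramMM,
    accepted_b: TractogramMM,
    grid: VolumeGrid,
    cfg: FilterConfig | None = None,
) -> BinaryMask:
    """Combine the two seed-direction tractograms, map track density on
    ``grid`` and threshold at ``cfg.density_threshold``."""
    cfg = cfg or FilterConfig()
    merged = merge_tractograms(accepted_a, accepted_b)
    density = track_density_map(merged, grid, cfg.step_for(grid.spacing))
    return threshold_density(density, cfg.density_threshold)
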