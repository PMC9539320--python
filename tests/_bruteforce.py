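"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written with plain Python loops, its own
affine inversion (numpy.linalg.solve) and Python's built-in banker's
rounding, sharing no code path with the package's vectorised
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def bf_length(points) -> float:
    total = 0.0
    pts = [tuple(map(float, p)) for p in points]
    for a, b in zip(pts, pts[1:]):
        total += math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
    return total


def bf_point_to_voxel(point, affine):
    """Continuous voxel coordinate -> nearest index, round-half-to-even."""
    rhs = np.asarray(point, float) - np.asarray(affine, float)[:3, 3]
    cont = np.linalg.solve(np.asarray(affine, float)[:3, :3], rhs)
    return tuple(int(round(float(c))) for c in cont)


def bf_point_in_mask(point, mask) -> bool:
    i, j, k = bf_point_to_voxel(point, mask.affine)
    sx, sy, sz = mask.values.shape
    if not (0 <= i < sx and 0 <= j < sy and 0 <= k < sz):
        return False
    return bool(mask.values[i, j, k])


def bf_supersample(points, step_mm):
    pts = [np.asarray(p, float) for p in points]
    out = [pts[0]]
    for a, b in zip(pts, pts[1:]):
        seg_len = math.dist(a, b)
        n = max(1, math.ceil(seg_len / step_mm))
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return out

def bf_traverses(points, mask, step_mm) -> bool:
    if not mask.values.any():
        return False
    return any(bf_point_in_mask(p, mask) for p in bf_supersample(points, step_mm))


def bf_filter_streamline(s, roi, cfg) -> str:
    """Rule order: length -> endpoints -> endpoint_exclude -> hard -> soft.

    A failed seed connection whose stray terminus sits in the endpoint-
    exclusion region (outside any seed) is labelled as an endpoint-exclusion
    rejection; this mirrors the documented report semantics.
    """
    if bf_length(s) > cfg.max_length_mm:
        return "rejected_length"
    first, last = s[0], s[-1]
    fa = bf_point_in_mask(first, roi.seed_a)
    fb = bf_point_in_mask(first, roi.seed_b)
    la = bf_point_in_mask(last, roi.seed_a)
    lb = bf_point_in_mask(last, roi.seed_b)
    epx = roi.endpoint_exclude
    if not ((fa and lb) or (fb and la)):
        for p, in_seed in ((first, fa or fb), (last, la or lb)):
            if epx is not None and not in_seed and bf_point_in_mask(p, epx):
                return "rejected_endpoint_exclude"
        return "rejected_endpoints"
    for p, in_seed in ((first, fa or fb), (last, la or lb)):
        if epx is not None and bf_point_in_mask(p, epx) and not in_seed:
            return "rejected_endpoint_exclude"
    step = cfg.step_for(np.linalg.norm(np.asarray(roi.seed_a.affine)[:3, :3], axis=0))
    for name in sorted(roi.hard_exclude):
        if bf_traverses(s, roi.hard_exclude[name], step):
            return f"rejected_hard_exclusion:{name}"
    for name in sorted(roi.soft_exclude_modified):
        if bf_traverses(s, roi.soft_exclude_modified[name], step):
            return f"rejected_soft_exclusion:{name}"
    return "accepted"


def bf_filter_tractogram(t, roi, cfg):
    """Accepted indices plus per-reason counts, honouring early stopping."""
    counts: dict[str, int] = {}
    accepted_idx = []
    generated = 0
    for i, s in enumerate(t.streamlines):
        outcome = bf_filter_streamline(s, roi, cfg)
        generated += 1
        counts[outcome] = counts.get(outcome, 0) + 1
        if outcome == "accepted":
            accepted_idx.append(i)
            if len(accepted_idx) >= cfg.max_accepted:
                break
        if generated >= cfg.max_generated:
            break
    return accepted_idx, counts, generated


def bf_visited_voxels(points, mask_shape, affine, step_mm) -> set:
    visited = set()
    sx, sy, sz = mask_shape
    for p in bf_supersample(points, step_mm):
        rhs = np.asarray(p, float) - np.asarray(affine, float)[:3, 3]
        cont = np.linalg.solve(np.asarray(affine, float)[:3, :3], rhs)
        i, j, k = (int(round(float(c))) for c in cont)
        if 0 <= i < sx and 0 <= j < sy and 0 <= k < sz:
            visited.add((i, j, k))
    return visited


def bf_density_map(tractogram, grid, step_mm) -> np.ndarray:
    counts = np.zeros(grid.shape, dtype=int)
    for s in tractogram.streamlines:
        for v in bf_visited_voxels(s, grid.shape, grid.affine, step_mm):
            counts[v] += 1
    return counts


def bf_distance_map(mask) -> np.ndarray:
    """Exhaustive min-over-set-voxels Euclidean distance (world mm)."""
    spacing = np.linalg.norm(np.asarray(mask.affine)[:3, :3], axis=0)
    set_idx = np.argwhere(mask.values).astype(float) * spacing
    out = np.zeros(mask.values.shape)
    for idx in np.ndindex(mask.values.shape):
        p = np.asarray(idx, float) * spacing
        out[idx] = np.min(np.linalg.norm(set_idx - p, axis=1))
    return out


def bf_connected_components(values, connectivity) -> list[set]:
    """Flood-fill components as sets of voxel tuples."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    todo = {tuple(v) for v in np.argwhere(values)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps
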