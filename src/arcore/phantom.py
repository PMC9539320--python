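"""Synthetic phantom scenes with known ground truth.

A scene emulates the dissection geometry of a short curved projection
bundle (40-60 mm) between a small deep-grey blob and a cortical blob, with
an adjacent cortical region abutting the cortical seed, a crossing
distractor bundle that must be rejected outright, a neighbouring bundle
that shares the near-seed corridor (traversal allowed after the distance
modification) but also has distal territory (forbidden), and a smooth
scalar field whose along-tract profile is known in closed form. Every
generated streamline carries the filter outcome it is constructed to
produce, so the filter's confusion matrix is fully checkable without any
imaging data.

Geometry defaults: 64 voxels at 1.25 mm isotropic (an 80 mm cube), seed
separation 45 mm, bundle arc length 48 mm — the length range reported for
the acoustic radiation, at a typical high-quality dMRI working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .density import track_density_map, threshold_density
from .filtering import (
    ACCEPTED,
    REJECTED_ENDPOINT_EXCLUDE,
    REJECTED_ENDPOINTS,
    REJECTED_HARD,
    REJECTED_LENGTH,
    REJECTED_SOFT,
)
from .formats import BinaryMask, TractogramMM, VolumeGrid, streamline_length
from .roi import FilterConfig, RoiModel, finalize_roi_model


@dataclass
class SceneConfig:
    """Geometry and sampling parameters of a phantom scene."""

    grid_size: int = 64
    spacing_mm: float = 1.25
    seed_radius_mm: float = 4.0
    seed_separation_mm: float = 45.0
    bundle_length_mm: float = 48.0  # target arc length of the centreline
    n_bundle: int = 1000
    n_per_distractor: int = 10
    points_per_streamline: int = 50
    bundle_radius_mm: float = 2.5  # uniform-density bundle cross-section
    distractor_jitter_sd_mm: float = 0.5
    distractor_jitter_clip_mm: float = 1.0
    fa_background: float = 0.15
    fa_corridor_radius_mm: float = 6.0
    filter: FilterConfig = field(default_factory=FilterConfig)

    @property
    def extent_mm(self) -> float:
        return (self.grid_size - 1) * self.spacing_mm


@dataclass
class PhantomScene:
    """A generated scene: ROI model, ground truth, labelled candidates."""

    config: SceneConfig
    seed: int
    grid: VolumeGrid
    roi: RoiModel
    centreline: np.ndarray  # noiseless bundle centreline, seed_a -> seed_b
    bundle: TractogramMM  # ground-truth streamlines (all must be accepted)
    corridor: BinaryMask  # k=1 density footprint of the ground-truth bundle
    candidates: TractogramMM  # bundle + distractors, shuffled
    labels: list[str]  # expected filter outcome per candidate
    distractors: dict[str, TractogramMM]
    fa: VolumeGrid | None = None
    fa_profile: Callable[[np.ndarray], np.ndarray] | None = None


# ---------------------------------------------------------------------------
# geometric helpers


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _bezier_arc_length(p0, p1, p2, n: int = 400) -> float:
    pts = _bezier(np.asarray(p0, float), np.asarray(p1, float), np.asarray(p2, float), n)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _solve_bulge(p0, p2, direction, target_length: float) -> float:
    """Bisection for the control-point offset giving a target arc length."""
    p0 = np.asarray(p0, float)
    p2 = np.asarray(p2, float)
    direction = np.asarray(direction, float)
    chord = float(np.linalg.norm(p2 - p0))
    mid = (p0 + p2) / 2
    lo, hi = 0.0, 2.0 * chord
    for _ in range(60):
        b = (lo + hi) / 2
        if _bezier_arc_length(p0, mid + b * direction, p2) < target_length:
            lo = b
        else:
            hi = b
    return (lo + hi) / 2


def _perp_frame(p0, p2) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to the chord p0 -> p2."""
    axis = np.asarray(p2, float) - np.asarray(p0, float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def make_bundle(
    start_center,
    end_center,
    curvature: float,
    n_streamlines: int,
    jitter_sd_mm: float,
    seed: int | np.random.Generator,
    *,
    curve_direction=None,
    jitter_clip_mm: float | None = None,
    jitter: str = "gaussian",
    n_points: int = 50,
) -> TractogramMM:
    """Streamlines along a quadratic Bezier centreline with per-streamline
    perpendicular offsets.

    ``curvature`` is the control-point offset (mm) applied at the chord
    midpoint along ``curve_direction`` (a deterministic perpendicular if
    not given); the centreline's maximum deviation from the chord is half
    of it. Offsets are drawn in the plane perpendicular to the chord:
    ``jitter='gaussian'`` draws isotropic Gaussian offsets with sd
    ``jitter_sd_mm`` (clipped in norm at ``jitter_clip_mm`` if set, so
    endpoints stay inside seed blobs of known radius); ``jitter='disc'``
    draws offsets uniformly over a disc of radius ``jitter_sd_mm``, giving
    a bundle with approximately uniform track density across its
    cross-section. Deterministic for a fixed seed.
    """
    p0 = np.asarray(start_center, dtype=np.float64)
    p2 = np.asarray(end_center, dtype=np.float64)
    if np.linalg.norm(p2 - p0) < 1e-9:
        raise ValueError("start and end centres coincide")
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    if jitter_sd_mm < 0:
        raise ValueError("jitter_sd_mm must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u, v = _perp_frame(p0, p2)
    if curve_direction is None:
        curve_direction = u
    d = np.asarray(curve_direction, dtype=np.float64)
    d = d / max(np.linalg.norm(d), 1e-12)
    control = (p0 + p2) / 2 + curvature * d
    centreline = _bezier(p0, control, p2, n_points)
    if jitter not in ("gaussian", "disc"):
        raise ValueError("jitter must be 'gaussian' or 'disc'")
    streamlines = []
    for _ in range(n_streamlines):
        if jitter_sd_mm == 0:
            off2d = np.zeros(2)
        elif jitter == "disc":
            r = jitter_sd_mm * np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2 * np.pi)
            off2d = np.array([r * np.cos(theta), r * np.sin(theta)])
        else:
            off2d = rng.normal(0.0, jitter_sd_mm, size=2)
            if jitter_clip_mm is not None:
                norm = float(np.linalg.norm(off2d))
                if norm > jitter_clip_mm:
                    off2d *= jitter_clip_mm / norm
        streamlines.append(centreline + off2d[0] * u + off2d[1] * v)
    return TractogramMM(streamlines=streamlines, provenance="phantom-bundle")


def _sphere_mask(grid: VolumeGrid, center_mm, radius_mm: float) -> BinaryMask:
    world = _voxel_centres(grid)
    inside = np.linalg.norm(world - np.asarray(center_mm, float), axis=1) <= radius_mm
    return BinaryMask(values=inside.reshape(grid.shape), affine=grid.affine)


def _cylinder_mask_z(grid: VolumeGrid, center_xy_mm, radius_mm: float) -> BinaryMask:
    world = _voxel_centres(grid)
    inside = np.linalg.norm(world[:, :2] - np.asarray(center_xy_mm, float), axis=1) <= radius_mm
    return BinaryMask(values=inside.reshape(grid.shape), affine=grid.affine)


def _voxel_centres(grid: VolumeGrid) -> np.ndarray:
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(np.float64)
    return idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]


# ---------------------------------------------------------------------------
# scene assembly


def make_scene(config: SceneConfig | None = None, seed: int = 0) -> PhantomScene:
    """Build a phantom scene with a ground-truth bundle, one distractor
    family per rejection rule, and a near-seed-corridor toucher that must
    be accepted.

    Raises on infeasible geometry: ROIs outside the grid, or a requested
    bundle arc length more than a third longer than the seed separation
    (the centreline would have to coil unrealistically).
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    extent = cfg.extent_mm
    n = cfg.grid_size
    affine = np.diag([cfg.spacing_mm] * 3 + [1.0])
    grid = VolumeGrid(values=np.zeros((n, n, n)), affine=affine)

    sep = cfg.seed_separation_mm
    if cfg.bundle_length_mm < sep:
        raise ValueError("bundle_length_mm cannot be shorter than the seed separation")
    if cfg.bundle_length_mm > sep * 4.0 / 3.0:
        raise ValueError(
            f"infeasible geometry: arc length {cfg.bundle_length_mm} mm needs "
            f"excessive curvature for a {sep} mm seed separation"
        )
    cy = cz = extent / 2
    ax = (extent - sep) / 2
    if ax - cfg.seed_radius_mm < cfg.spacing_mm:
        raise ValueError("infeasible geometry: seeds (plus radius) exceed the grid")
    A = np.array([ax, cy, cz])  # thalamic seed centre (MGN role)
    B = np.array([ax + sep, cy, cz])  # cortical seed centre (HG role)
    u = np.array([0.0, 1.0, 0.0])  # bundle bulge direction
    w = np.array([0.0, 0.0, 1.0])

    # regions ------------------------------------------------------------
    seed_a = _sphere_mask(grid, A, cfg.seed_radius_mm)
    seed_b = _sphere_mask(grid, B, cfg.seed_radius_mm)
    stg_c = B - 10.0 * u  # adjacent cortical blob abutting seed_b
    stg = _sphere_mask(grid, stg_c, 4.5)
    hard = _cylinder_mask_z(grid, (ax + sep / 2, cy - 12.0), 4.0)  # crossing bundle
    # neighbouring bundle: a blob inside the near-seed corridor of both
    # seeds (removed by the distance modification) plus a distal blob that
    # stays >= the distance threshold away from the thalamic seed mask
    # (retained after modification).
    soft_near_c = np.array([ax + sep / 2, cy + 8.0, cz])
    far_dx, far_dy = 45.44 * sep / 45.0, 12.0
    soft_far_c = np.array([ax + far_dx, cy + far_dy, cz])
    soft = BinaryMask(
        values=_sphere_mask(grid, soft_near_c, 4.0).values
        | _sphere_mask(grid, soft_far_c, 2.5).values,
        affine=affine,
    )
    roi = RoiModel(
        seed_a=seed_a,
        seed_b=seed_b,
        endpoint_exclude=stg,
        hard_exclude={"CST": hard},
        soft_exclude_raw={"AF": soft},
    )
    finalize_roi_model(roi, cfg.filter)

    # ground-truth bundle -------------------------------------------------
    bulge = _solve_bulge(A, B, u, cfg.bundle_length_mm)
    centreline = _bezier(A, (A + B) / 2 + bulge * u, B, cfg.points_per_streamline)
    bundle = make_bundle(
        A, B, bulge, cfg.n_bundle, cfg.bundle_radius_mm, rng,
        curve_direction=u, jitter="disc",
        n_points=cfg.points_per_streamline,
    )
    step = cfg.filter.step_for(grid.spacing)
    corridor = threshold_density(track_density_map(bundle, grid, step), 1)

    # distractor families, one per rejection label ------------------------
    def djitter(p0, p2, curvature, direction) -> TractogramMM:
        return make_bundle(
            p0, p2, curvature, cfg.n_per_distractor,
            cfg.distractor_jitter_sd_mm, rng,
            curve_direction=direction, jitter_clip_mm=cfg.distractor_jitter_clip_mm,
            n_points=cfg.points_per_streamline,
        )

    # over the length cap (bulges upward out of the crowded plane)
    too_long = djitter(A, B, _solve_bulge(A, B, w, cfg.filter.max_length_mm + 10.0), w)
    # terminates in the adjacent cortical blob instead of the cortical seed
    stg_leak = djitter(A, stg_c, 2.0, w)
    # terminates in free space (wrong endpoint, not the exclusion region)
    stray = djitter(A, np.array([ax + sep * 42 / 45, cy + 30.0, cz]), 2.0, w)
    # dips through the crossing bundle (hard exclusion)
    hard_crosser = djitter(A, B, 24.0, -u)
    # detours through the retained distal territory of the neighbour bundle
    soft_toucher = _make_soft_toucher(A, B, soft_far_c, cfg, rng)
    # bulges through the removed near-seed blob of the neighbour -> accepted
    corridor_toucher = djitter(A, B, 16.0, u)

    distractors = {
        REJECTED_LENGTH: too_long,
        REJECTED_ENDPOINT_EXCLUDE: stg_leak,
        REJECTED_ENDPOINTS: stray,
        f"{REJECTED_HARD}:CST": hard_crosser,
        f"{REJECTED_SOFT}:AF": soft_toucher,
        f"{ACCEPTED}:corridor": corridor_toucher,
    }

    for s in too_long.streamlines:
        if streamline_length(s) <= cfg.filter.max_length_mm:
            raise ValueError("infeasible geometry: over-length distractor too short")
    for tract in (bundle, corridor_toucher, soft_toucher):
        for s in tract.streamlines:
            if streamline_length(s) > cfg.filter.max_length_mm:
                raise ValueError("infeasible geometry: streamline exceeds length cap")

    # shuffle candidates deterministically --------------------------------
    all_streamlines = list(bundle.streamlines)
    all_labels = [ACCEPTED] * len(bundle)
    for label, tract in distractors.items():
        expected = label.split(":")[0] if label.startswith(ACCEPTED) else label
        all_streamlines.extend(tract.streamlines)
        all_labels.extend([expected] * len(tract))
    order = rng.permutation(len(all_streamlines))
    candidates = TractogramMM(
        streamlines=[all_streamlines[i] for i in order],
        reference_affine=affine,
        reference_shape=(n, n, n),
        provenance="phantom-candidates",
    )
    labels = [all_labels[i] for i in order]

    scene = PhantomScene(
        config=cfg,
        seed=seed,
        grid=grid,
        roi=roi,
        centreline=centreline,
        bundle=bundle,
        corridor=corridor,
        candidates=candidates,
        labels=labels,
        distractors=distractors,
    )
    scene.fa = make_fa_volume(scene, default_fa_profile)
    scene.fa_profile = default_fa_profile
    return scene


def _make_soft_toucher(A, B, via, cfg: SceneConfig, rng) -> TractogramMM:
    """Seed-to-seed polylines detouring through ``via`` (the retained distal
    soft-exclusion blob), with small whole-streamline z offsets."""
    base = np.vstack([np.linspace(A, via, 25), np.linspace(via, B, 26)[1:]])
    streamlines = []
    for _ in range(cfg.n_per_distractor):
        dz = float(np.clip(rng.normal(0.0, cfg.distractor_jitter_sd_mm),
                           -cfg.distractor_jitter_clip_mm, cfg.distractor_jitter_clip_mm))
        streamlines.append(base + np.array([0.0, 0.0, dz]))
    return TractogramMM(streamlines=streamlines, provenance="phantom-soft-toucher")


# ---------------------------------------------------------------------------
# scalar field


def default_fa_profile(t: np.ndarray) -> np.ndarray:
    """Low-high-low along-tract FA: low at the thalamic end, peaking
    mid-tract, dropping again towards cortex."""
    t = np.asarray(t, dtype=np.float64)
    return 0.12 + 1.5 * t * (1.0 - t)


def make_fa_volume(
    scene: PhantomScene,
    profile_fn: Callable[[np.ndarray], np.ndarray],
) -> VolumeGrid:
    """Scalar volume following ``profile_fn`` of normalised arc position
    inside a tube around the bundle centreline, constant background outside.

    ``profile_fn`` must map [0, 1] into [0, 1].
    """
    cfg = scene.config
    probe = np.asarray(profile_fn(np.linspace(0, 1, 201)))
    if np.any(probe < 0) or np.any(probe > 1):
        raise ValueError("profile_fn must map [0, 1] into [0, 1]")

    from .tractometry import resample_streamline

    dense = resample_streamline(scene.centreline, 400)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    t_par = arc / arc[-1]

    grid = scene.grid
    world = _voxel_centres(grid)
    dist, nearest = cKDTree(dense).query(world, workers=-1)
    values = np.full(len(world), cfg.fa_background)
    inside = dist <= cfg.fa_corridor_radius_mm
    values[inside] = profile_fn(t_par[nearest[inside]])
    return VolumeGrid(values=values.reshape(grid.shape), affine=grid.affine)
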