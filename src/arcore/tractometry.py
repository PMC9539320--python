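"""Along-tract statistics (tractometry).

Streamlines are oriented so position 0 sits at the thalamic seed (MGN role)
and position 1 at the cortical seed (HG role), resampled to a fixed number
of equal arc-length positions, and used to sample a scalar map (typically
fractional anisotropy) by trilinear interpolation. Group comparison is done
on subject-level mean profiles — one profile per subject, never individual
streamlines, to avoid pseudo-replication — with pointwise two-sample
t-tests corrected for family-wise error across positions (Bonferroni by
default, a maxT permutation scheme optionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import stats
from scipy.ndimage import map_coordinates

from .formats import (
    BinaryMask,
    Streamline,
    TractogramMM,
    VolumeGrid,
    streamline_length,
    world_to_voxel_continuous,
)

DEFAULT_N_POINTS = 100


def resample_streamline(s: Streamline, n_points: int = DEFAULT_N_POINTS) -> Streamline:
    """Resample to ``n_points`` at equal arc-length spacing.

    The first and last output points equal the original termini exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    s = np.asarray(s, dtype=np.float64)
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("cannot resample a zero-length streamline")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_points)
    out = np.column_stack(
        [np.interp(targets, arc, s[:, d]) for d in range(3)]
    )
    out[0], out[-1] = s[0], s[-1]
    return out


def orient_streamlines(t: TractogramMM, seed_a: BinaryMask) -> TractogramMM:
    """Flip streamlines so each starts at its seed_a-side terminus.

    Side is decided by the smaller Euclidean distance from a terminus to the
    nearest seed_a voxel centre; exact ties keep the stored order.
    """
    seed_pts = seed_a.world_coordinates()
    oriented: list[Streamline] = []
    for s in t.streamlines:
        d_first = np.min(np.linalg.norm(seed_pts - s[0], axis=1))
        d_last = np.min(np.linalg.norm(seed_pts - s[-1], axis=1))
        oriented.append(s[::-1].copy() if d_last < d_first else s)
    return TractogramMM(
        streamlines=oriented,
        reference_affine=t.reference_affine,
        reference_shape=t.reference_shape,
        provenance=f"{t.provenance}|oriented",
    )


def sample_scalar_along(
    t: TractogramMM, vol: VolumeGrid, n_points: int = DEFAULT_N_POINTS
) -> NDArray[np.float64]:
    """(n_streamlines, n_points) trilinear samples of ``vol`` along each
    resampled streamline; out-of-volume samples are NaN."""
    samples = np.full((len(t), n_points), np.nan)
    values = np.asarray(vol.values, dtype=np.float64)
    for i, s in enumerate(t.streamlines):
        pts = resample_streamline(s, n_points)
        vox = world_to_voxel_continuous(pts, vol).T
        row = map_coordinates(values, vox, order=1, mode="constant", cval=np.nan)
        samples[i] = row
    return samples


def subject_mean_profile(sample_matrix: NDArray) -> NDArray[np.float64]:
    """Per-position mean over a subject's streamlines (NaN-aware)."""
    m = np.asarray(sample_matrix, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        return np.nanmean(m, axis=0)


@dataclass
class TractProfile:
    """Group-level along-tract summary. Position 0 = seed_a (MGN role),
    position 1 = seed_b (HG role)."""

    positions: NDArray[np.float64]
    group_names: tuple[str, ...]
    subject_profiles: dict[str, NDArray[np.float64]]  # group -> (n_subj, P)
    mean: dict[str, NDArray[np.float64]] = field(default_factory=dict)
    ci_lower: dict[str, NDArray[np.float64]] = field(default_factory=dict)
    ci_upper: dict[str, NDArray[np.float64]] = field(default_factory=dict)
    p_corrected: NDArray[np.float64] | None = None


def _t_ci(profiles: NDArray, level: float = 0.95):
    """Pointwise t-based CI of the mean over subjects, NaN-aware."""
    n = np.sum(np.isfinite(profiles), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(profiles, axis=0)
        sd = np.nanstd(profiles, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    tcrit = np.where(n > 1, stats.t.ppf(0.5 + level / 2, np.maximum(n - 1, 1)), np.nan)
    half = tcrit * sem
    return mean, mean - half, mean + half


def group_profile(
    subject_matrices: list[NDArray],
    group_labels: list[str],
    ci_level: float = 0.95,
) -> TractProfile:
    """Build per-group mean and CI profiles from per-subject sample matrices.

    Each element of ``subject_matrices`` is one subject's
    (n_streamlines, n_points) sample matrix; ``group_labels`` gives the
    subject's group. Every group needs at least 2 subjects.
    """
    if len(subject_matrices) != len(group_labels):
        raise ValueError("one group label per subject matrix required")
    n_points = {np.asarray(m).shape[1] for m in subject_matrices}
    if len(n_points) != 1:
        raise ValueError("all subjects must share the same n_points")
    (P,) = n_points
    groups = tuple(dict.fromkeys(group_labels))
    by_group: dict[str, NDArray] = {}
    for g in groups:
        rows = [
            subject_mean_profile(m)
            for m, lab in zip(subject_matrices, group_labels)
            if lab == g
        ]
        if len(rows) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        by_group[g] = np.vstack(rows)
    profile = TractProfile(
        positions=np.linspace(0.0, 1.0, P),
        group_names=groups,
        subject_profiles=by_group,
    )
    for g, mat in by_group.items():
        mean, lo, hi = _t_ci(mat, ci_level)
        profile.mean[g] = mean
        profile.ci_lower[g] = lo
        profile.ci_upper[g] = hi
    return profile


def _pointwise_t(a: NDArray, b: NDArray) -> NDArray[np.float64]:
    """Two-sample pooled-variance t statistic per position, NaN pairs omitted."""
    res = stats.ttest_ind(a, b, axis=0, nan_policy="omit")
    return np.asarray(res.statistic, dtype=np.float64)


def alongtract_test(
    profiles_a: NDArray,
    profiles_b: NDArray,
    alpha: float = 0.05,
    method: str = "bonferroni",
    n_permutations: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> NDArray[np.float64]:
    """Pointwise two-sample t-tests with family-wise-error correction.

    Inputs are subject-level profile matrices (n_subjects x n_points), one
    per group. ``method='bonferroni'`` multiplies each pointwise p-value by
    the number of positions (capped at 1). ``method='maxT'`` builds the null
    distribution of the maximum |t| over positions by permuting group labels
    and assigns each position the tail probability of its observed |t|
    under that maximum distribution, which controls the family-wise error
    rate while adapting to the spatial correlation of neighbouring
    positions.
    """
    a = np.asarray(profiles_a, dtype=np.float64)
    b = np.asarray(profiles_b, dtype=np.float64)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same n_points")
    P = a.shape[1]
    t_obs = _pointwise_t(a, b)

    if method == "bonferroni":
        nA = np.sum(np.isfinite(a), axis=0)
        nB = np.sum(np.isfinite(b), axis=0)
        df = nA + nB - 2
        with np.errstate(invalid="ignore"):
            p_raw = 2 * stats.t.sf(np.abs(t_obs), np.maximum(df, 1))
        return np.minimum(p_raw * P, 1.0)

    if method == "maxT":
        gen = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )
        pooled = np.vstack([a, b])
        nA = a.shape[0]
        max_null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = gen.permutation(len(pooled))
            ta = pooled[perm[:nA]]
            tb = pooled[perm[nA:]]
            with np.errstate(invalid="ignore"):
                max_null[i] = np.nanmax(np.abs(_pointwise_t(ta, tb)))
        abs_obs = np.abs(t_obs)
        p = np.array(
            [(1 + np.sum(max_null >= x)) / (n_permutations + 1) for x in abs_obs]
        )
        return p

    raise ValueError(f"unknown correction method {method!r}")


def compare_groups(
    profile: TractProfile,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    method: str = "bonferroni",
    **kwargs,
) -> TractProfile:
    """Attach corrected p-values for a two-group comparison to a profile."""
    p = alongtract_test(
        profile.subject_profiles[group_a],
        profile.subject_profiles[group_b],
        alpha=alpha,
        method=method,
        **kwargs,
    )
    profile.p_corrected = p
    return profile
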