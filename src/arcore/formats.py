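"""Volume and tractogram containers, file I/O, and coordinate primitives.

All streamline coordinates are held internally in world RAS millimetres;
masks and scalar maps keep their native voxel grid plus an affine. The TRK
dialect's voxel-scaled, corner-origin convention is converted at the I/O
boundary only, so the rest of the package never sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from nibabel.streamlines import Field, TckFile, TrkFile
from nibabel.streamlines.tractogram import Tractogram as _NibTractogram
from numpy.typing import NDArray


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with an invertible voxel-index -> world-mm affine.

    Voxel centres sit at integer indices; ``affine @ (i, j, k, 1)`` is the
    world position of the centre of voxel ``(i, j, k)``.
    """

    values: NDArray
    affine: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(
                f"expected 3D data, got {self.values.ndim}D of shape {self.values.shape}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> NDArray[np.float64]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_values(self, values: NDArray) -> "VolumeGrid":
        return replace(self, values=values)

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class BinaryMask(VolumeGrid):
    """A VolumeGrid whose values are {0, 1} (stored as bool)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values) != 0

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def voxel_indices(self) -> NDArray[np.int64]:
        """(n, 3) integer indices of set voxels."""
        return np.argwhere(self.values)

    def world_coordinates(self) -> NDArray[np.float64]:
        """(n, 3) world-mm centres of set voxels."""
        return voxel_to_world(self.voxel_indices(), self)


Streamline = NDArray[np.float64]
"""An ordered (n_points >= 2, 3) array of world-mm coordinates."""


def as_streamline(points: Iterable[Sequence[float]]) -> Streamline:
    s = np.asarray(points, dtype=np.float64)
    if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
        raise ValueError(f"streamline must be (n>=2, 3), got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("streamline contains non-finite coordinates")
    return s


@dataclass
class TractogramMM:
    """A list of streamlines in world RAS mm plus the reference grid they
    were generated against (used when writing TRK and building density maps).
    """

    streamlines: list[Streamline] = field(default_factory=list)
    reference_affine: NDArray[np.float64] = field(
        default_factory=lambda: np.eye(4)
    )
    reference_shape: tuple[int, int, int] = (1, 1, 1)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.reference_affine = np.asarray(self.reference_affine, dtype=np.float64)
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def same_space(self, other: "TractogramMM", atol: float = 1e-4) -> bool:
        return self.reference_shape == other.reference_shape and np.allclose(
            self.reference_affine, other.reference_affine, atol=atol
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI scalar volume (e.g. an FA map)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D volume, got dim={data.ndim} shape={data.shape}"
        )
    return VolumeGrid(values=np.asarray(data, dtype=np.float64), affine=img.affine)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI region mask, binarising nonzero voxels to 1."""
    vol = read_volume(path)
    return BinaryMask(values=vol.values != 0, affine=vol.affine)


def write_volume(vol: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), vol.affine)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    write_volume(mask, path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# tractogram I/O


def read_tractogram(path: str | Path) -> TractogramMM:
    """Read a TCK or TRK file into world RAS mm.

    nibabel applies each dialect's native transform (TRK stores voxel-scaled,
    corner-origin coordinates) so both formats land in the same space.
    """
    path = Path(path)
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise FormatError(f"{path}: not a readable TCK/TRK file ({exc})") from exc
    header = tfile.header
    affine = np.asarray(
        header.get(Field.VOXEL_TO_RASMM, np.eye(4)), dtype=np.float64
    )
    shape = tuple(int(d) for d in header.get(Field.DIMENSIONS, (1, 1, 1)))
    streamlines = [np.asarray(s, dtype=np.float64) for s in tfile.streamlines]
    return TractogramMM(
        streamlines=streamlines,
        reference_affine=affine,
        reference_shape=shape,  # type: ignore[arg-type]
        provenance=str(path.name),
    )


def write_tractogram(t: TractogramMM, path: str | Path) -> None:
    """Write to .tck or .trk depending on the file suffix."""
    path = Path(path)
    nt = _NibTractogram(
        [np.asarray(s, dtype=np.float32) for s in t.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    suffix = path.suffix.lower()
    if suffix == ".tck":
        TckFile(nt).save(str(path))
    elif suffix == ".trk":
        header = {
            Field.VOXEL_TO_RASMM: np.asarray(t.reference_affine, dtype=np.float64),
            Field.VOXEL_SIZES: np.linalg.norm(
                np.asarray(t.reference_affine)[:3, :3], axis=0
            ),
            Field.DIMENSIONS: np.asarray(t.reference_shape, dtype=np.int16),
        }
        TrkFile(nt, header=header).save(str(path))
    else:
        raise FormatError(f"unknown tractogram suffix {suffix!r} (use .tck or .trk)")


# ---------------------------------------------------------------------------
# coordinate primitives


def world_to_voxel_continuous(
    points: NDArray, grid: VolumeGrid
) -> NDArray[np.float64]:
    """Map world-mm points to continuous voxel coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    inv = np.linalg.inv(grid.affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def world_to_voxel(
    points: NDArray, grid: VolumeGrid
) -> tuple[NDArray[np.int64], NDArray[np.bool_]]:
    """Nearest-voxel indices of world points plus an in-grid flag.

    Voxel membership: a point belongs to the voxel whose centre is nearest,
    with round-half-to-even ties (numpy's default rounding). Out-of-grid
    points are flagged, never clamped; their indices are still returned.
    """
    cont = world_to_voxel_continuous(points, grid)
    idx = np.round(cont).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    return idx, inside


def voxel_to_world(indices: NDArray, grid: VolumeGrid) -> NDArray[np.float64]:
    idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
    return idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def distance_map(mask: BinaryMask) -> VolumeGrid:
    """Per-voxel Euclidean distance in mm to the nearest set voxel.

    Anisotropic spacings are honoured through the EDT sampling argument;
    distances are measured between voxel centres in world mm, assuming the
    affine has no shear (rotations do not change Euclidean distance).
    """
    from scipy.ndimage import distance_transform_edt

    if mask.n_voxels == 0:
        raise ValueError("distance_map of an empty mask is undefined")
    dist = distance_transform_edt(~mask.values, sampling=mask.spacing)
    return VolumeGrid(values=dist, affine=mask.affine)


def streamline_length(s: Streamline) -> float:
    """Arc length in mm: sum of Euclidean segment lengths."""
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("streamline_length needs at least 2 points")
    return float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())
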