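"""Grid-aware 3D volumes, binary masks, signed distance maps and morphology.

Everything downstream operates in world millimetres: a :class:`VolumeGrid`
carries the physical geometry (voxel spacing, origin of the first voxel
centre, axis direction matrix) alongside the scalar array, and every
algorithm parameter in the package (radii, resolutions, margins) is
expressed in mm, never in voxels.

Array index convention: ``values[i, j, k]`` with the world position of a
voxel centre given by ``origin + direction @ (spacing * (i, j, k))``
(0-based, voxel-centre). This matches the (x, y, z) index order of
SimpleITK images; conversion helpers transpose to/from SimpleITK's
NumPy (z, y, x) view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "SignedDistanceMap",
    "signed_distance",
    "resample",
    "morphology",
    "read_volume",
    "write_volume",
    "read_mask",
]

#: HU value used to fill out-of-extent voxels when resampling images (air).
AIR_HU = -1000.0

_GEOM_ATOL = 1e-4  # mm tolerance when comparing grid geometries


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar field with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values — Hounsfield units for CT images, unitless for masks
        and probability maps, mm for distance maps.
    spacing : array-like of 3 floats
        Per-axis voxel size in mm; strictly positive.
    origin : array-like of 3 floats
        World position (mm) of the centre of voxel (0, 0, 0).
    direction : (3, 3) array-like
        Orthonormal axis matrix mapping index axes to world axes.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ValueError("origin must have 3 components")
        d = self.direction
        if d.shape != (3, 3) or not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be 3x3 orthonormal")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel-centre indices, shape (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def world_to_index(self, point: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points, shape (..., 3)."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.direction) / self.spacing

    def same_geometry(self, other: "VolumeGrid", atol: float = _GEOM_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid sharing this geometry with different voxel values."""
        if values.shape != self.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.shape}")
        return replace(self, values=values)

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self, dtype=None) -> sitk.Image:
        vals = self.values if dtype is None else self.values.astype(dtype)
        img = sitk.GetImageFromArray(np.ascontiguousarray(vals.T))
        img.SetSpacing(tuple(map(float, self.spacing)))
        img.SetOrigin(tuple(map(float, self.origin)))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeGrid":
        return cls(
            values=sitk.GetArrayFromImage(img).T,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )


@dataclass(frozen=True)
class BinaryMask:
    """A binary structure mask; ``grid.values`` are exactly 0 or 1."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        vals = self.grid.values
        if vals.dtype != np.uint8:
            if not np.isin(np.unique(vals), (0, 1)).all():
                raise ValueError("mask values must be exactly 0 or 1")
            object.__setattr__(self, "grid", self.grid.with_values(vals.astype(np.uint8)))

    @classmethod
    def from_array(cls, values: np.ndarray, like: VolumeGrid) -> "BinaryMask":
        return cls(like.with_values(np.asarray(values).astype(np.uint8)))

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def is_empty(self) -> bool:
        return not bool(self.values.any())

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    def centroid_mm(self) -> np.ndarray:
        """World-space centroid of the labelled voxel centres."""
        if self.is_empty:
            raise ValueError("centroid of empty mask is undefined")
        idx = np.argwhere(self.values > 0)
        return self.grid.index_to_world(idx).mean(axis=0)

    # set algebra on a shared grid ---------------------------------------
    def _check(self, other: "BinaryMask") -> None:
        if not self.grid.same_geometry(other.grid):
            raise ValueError("masks are on different grids")

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask.from_array(self.values | other.values, self.grid)

    def intersection(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask.from_array(self.values & other.values, self.grid)

    def difference(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask.from_array(self.values & ~other.values.astype(bool), self.grid)

    def to_sitk(self) -> sitk.Image:
        return self.grid.to_sitk(np.uint8)

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "BinaryMask":
        g = VolumeGrid.from_sitk(img)
        return cls.from_array(g.values > 0, g)


@dataclass(frozen=True)
class SignedDistanceMap:
    """Euclidean signed distance to a mask boundary (negative inside).

    When ``normalised``, all values have been divided by ``depth_scale``,
    the maximum interior depth in mm, so the deepest interior voxel sits at
    −1 and exterior values are scaled by the same factor. Normalisation
    makes distance maps of differently sized hearts commensurate, which is
    what structure-guided registration requires.
    """

    grid: VolumeGrid
    normalised: bool
    depth_scale: float

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def signed_distance(mask: BinaryMask, normalise: bool = False) -> SignedDistanceMap:
    """Signed Euclidean distance map of a binary mask.

    Negative inside the mask, positive outside, zero level set on the mask
    boundary. With ``normalise`` the map is divided by the maximum interior
    depth so interior values lie in [−1, 0].

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    if mask.is_empty:
        raise ValueError("cannot compute distance map of empty mask")
    d = sitk.SignedMaurerDistanceMap(
        mask.to_sitk(), insideIsPositive=False, squaredDistance=False, useImageSpacing=True
    )
    grid = VolumeGrid.from_sitk(d)
    depth = float(-grid.values.min())
    if depth <= 0:  # single-voxel-thin mask: fall back to half a voxel
        depth = 0.5 * float(mask.grid.spacing.min())
    if normalise:
        grid = grid.with_values(grid.values / depth)
    return SignedDistanceMap(grid=grid, normalised=normalise, depth_scale=depth)


_INTERPOLATORS = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}


def resample(
    volume: VolumeGrid,
    target_geometry: VolumeGrid,
    interpolation: Literal["linear", "nearest"] = "linear",
    background: float | None = None,
    transform: sitk.Transform | None = None,
) -> VolumeGrid:
    """Sample ``volume`` at the voxel centres of ``target_geometry``.

    ``transform`` (optional) maps target world points into the volume's
    world frame before sampling — this is how warped atlases are produced.
    Out-of-extent samples are filled with ``background`` (0 by default;
    pass :data:`AIR_HU` for CT images).
    """
    if interpolation not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    bg = 0.0 if background is None else float(background)
    out = sitk.Resample(
        volume.to_sitk(np.float64),
        target_geometry.to_sitk(),
        transform if transform is not None else sitk.Transform(),
        _INTERPOLATORS[interpolation],
        bg,
    )
    return VolumeGrid.from_sitk(out)


def resample_mask(
    mask: BinaryMask,
    target_geometry: VolumeGrid,
    transform: sitk.Transform | None = None,
    method: Literal["nearest", "linear_threshold"] = "linear_threshold",
) -> BinaryMask:
    """Resample a binary mask; linear interpolation + 0.5 threshold by default."""
    if method == "nearest":
        out = resample(mask.grid, target_geometry, "nearest", 0.0, transform)
        return BinaryMask.from_array(out.values > 0.5, out)
    out = resample(mask.grid, target_geometry, "linear", 0.0, transform)
    return BinaryMask.from_array(out.values >= 0.5, out)


def _radius_voxels(radius_mm: float, spacing: np.ndarray) -> list[int]:
    return [max(1, int(round(radius_mm / s))) for s in spacing]


def morphology(
    mask: BinaryMask,
    op: Literal["dilate", "erode", "fill_holes", "largest_component"],
    radius_mm: float = 0.0,
) -> BinaryMask:
    """Binary morphology with a physical-unit (mm) structuring element.

    ``dilate``/``erode`` use a ball of ``radius_mm``; ``fill_holes`` closes
    fully enclosed cavities (6-connected background); ``largest_component``
    keeps the single largest 26-connected component (empty in → empty out,
    with a warning).
    """
    img = mask.to_sitk()
    if op in ("dilate", "erode"):
        if radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")
        if radius_mm == 0:
            return mask
        r = _radius_voxels(radius_mm, mask.grid.spacing)
        fn = sitk.BinaryDilate if op == "dilate" else sitk.BinaryErode
        out = fn(img, r, sitk.sitkBall)
    elif op == "fill_holes":
        out = sitk.BinaryFillhole(img, fullyConnected=False)
    elif op == "largest_component":
        if mask.is_empty:
            logger.warning("largest_component of empty mask")
            return mask
        cc = sitk.ConnectedComponent(img, True)  # 26-connectivity
        out = sitk.RelabelComponent(cc, sortByObjectSize=True) == 1
    else:
        raise ValueError(f"unknown morphology op {op!r}")
    return BinaryMask.from_sitk(out)


def polyline_tube(grid: VolumeGrid, points: np.ndarray, radius_mm: float,
                  densify_mm: float = 0.3) -> np.ndarray:
    """Boolean array of voxels whose centres lie within ``radius_mm`` of the
    polyline through ``points`` (world mm), densified to ``densify_mm`` steps."""
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dense = [pts[:1]]
    for p0, p1, L in zip(pts[:-1], pts[1:], seglen):
        n = max(2, int(np.ceil(L / densify_mm)))
        dense.append(np.linspace(p0, p1, n)[1:])
    dense = np.vstack(dense)
    lo = grid.world_to_index(dense.min(axis=0) - radius_mm - grid.spacing)
    hi = grid.world_to_index(dense.max(axis=0) + radius_mm + grid.spacing)
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int) + 1, grid.shape)
    out = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    sub_idx = np.stack(
        np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    d, _ = cKDTree(dense).query(grid.index_to_world(sub_idx), workers=-1)
    hit = sub_idx[d <= radius_mm]
    out[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    return out


# -- NIfTI I/O -------------------------------------------------------------

def read_volume(path) -> VolumeGrid:
    """Read a NIfTI volume (or a DICOM series directory) as a VolumeGrid."""
    import os

    if os.path.isdir(str(path)):
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise ValueError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        return VolumeGrid.from_sitk(reader.Execute())
    return VolumeGrid.from_sitk(sitk.ReadImage(str(path)))


def write_volume(volume: VolumeGrid, path, dtype=None) -> None:
    sitk.WriteImage(volume.to_sitk(dtype), str(path))


def read_mask(path) -> BinaryMask:
    g = read_volume(path)
    return BinaryMask.from_array(g.values > 0.5, g)
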