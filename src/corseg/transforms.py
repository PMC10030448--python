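"""Spatial transforms between image grids: affine, dense displacement, composite.

All transforms are *resampling* transforms in world mm: they map points of
the target (fixed) frame to points of the atlas (moving) frame, which is
the direction SimpleITK's resampler consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk

from .core import BinaryMask, VolumeGrid

__all__ = ["SpatialTransform"]


@dataclass(frozen=True)
class SpatialTransform:
    """Wrapper around a SimpleITK transform with explicit composition order.

    ``kind`` is one of ``affine``, ``displacement_field``, ``composite``.
    A composite built from ``[t1, t2, t3]`` applies its components to a
    point in declared order: ``t3(t2(t1(x)))`` — for the registration
    pipeline the declared order is [demons field, structure-guided field,
    affine], i.e. function composition affine ∘ structure-guided ∘ demons.
    """

    kind: Literal["affine", "displacement_field", "composite"]
    sitk_transform: sitk.Transform
    components: tuple["SpatialTransform", ...] = ()

    # constructors --------------------------------------------------------
    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls("affine", sitk.AffineTransform(3))

    @classmethod
    def from_affine(cls, matrix: np.ndarray, offset: np.ndarray) -> "SpatialTransform":
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(np.asarray(matrix, dtype=float).flatten()))
        t.SetTranslation(tuple(np.asarray(offset, dtype=float)))
        return cls("affine", t)

    @classmethod
    def from_sitk(cls, transform: sitk.Transform) -> "SpatialTransform":
        kind = (
            "affine"
            if transform.GetTransformEnum() in (sitk.sitkAffine, sitk.sitkTranslation, sitk.sitkEuler)
            else "displacement_field"
            if transform.GetTransformEnum() == sitk.sitkDisplacementField
            else "composite"
        )
        return cls(kind, transform)

    @classmethod
    def from_displacement_field(cls, field: sitk.Image) -> "SpatialTransform":
        """From a vector image of world-frame displacements in mm."""
        t = sitk.DisplacementFieldTransform(sitk.Image(field))  # copies; the ctor consumes
        return cls("displacement_field", t)

    @classmethod
    def compose(cls, components: Sequence["SpatialTransform"]) -> "SpatialTransform":
        """Composite applying ``components`` to a point in declared order."""
        comps = tuple(components)
        if not comps:
            return cls.identity()
        if len(comps) == 1:
            return comps[0]
        ct = sitk.CompositeTransform(3)
        # SimpleITK applies the most recently added transform first, so add
        # in reverse of the declared application order.
        for c in reversed(comps):
            ct.AddTransform(c.sitk_transform)
        return cls("composite", ct, comps)

    # properties ----------------------------------------------------------
    @property
    def affine_matrix(self) -> np.ndarray:
        if self.kind != "affine":
            raise ValueError("not an affine transform")
        return np.asarray(self.sitk_transform.GetMatrix()).reshape(3, 3)

    @property
    def affine_offset(self) -> np.ndarray:
        if self.kind != "affine":
            raise ValueError("not an affine transform")
        t = self.sitk_transform
        # effective offset of x -> M (x - c) + c + translation
        c = np.asarray(t.GetCenter())
        return np.asarray(t.GetTranslation()) + c - self.affine_matrix @ c

    # application ---------------------------------------------------------
    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.array([self.sitk_transform.TransformPoint(tuple(p)) for p in pts])
        return out.reshape(np.shape(points))

    def displacement_field_on(self, grid: VolumeGrid) -> sitk.Image:
        """Materialise the transform as a displacement-field image on ``grid``."""
        f = sitk.TransformToDisplacementFieldFilter()
        f.SetReferenceImage(grid.to_sitk())
        f.SetOutputPixelType(sitk.sitkVectorFloat64)
        return f.Execute(self.sitk_transform)

    def jacobian_determinant(self, grid: VolumeGrid) -> VolumeGrid:
        field = self.displacement_field_on(grid)
        return VolumeGrid.from_sitk(sitk.DisplacementFieldJacobianDeterminant(field))

    def invert(self) -> "SpatialTransform":
        if self.kind == "affine":
            inv = sitk.AffineTransform(self.sitk_transform.GetInverse())
            return SpatialTransform("affine", inv)
        if self.kind == "displacement_field":
            df = sitk.DisplacementFieldTransform(self.sitk_transform)
            field = df.GetDisplacementField()
            inv_field = sitk.InvertDisplacementField(
                field, maximumNumberOfIterations=50, enforceBoundaryCondition=True
            )
            return SpatialTransform.from_displacement_field(inv_field)
        raise ValueError("cannot invert a general composite transform")

    def max_mask_displacement_mm(self, mask: BinaryMask) -> float:
        """Maximum displacement magnitude over the mask's voxel centres."""
        pts = mask.grid.index_to_world(np.argwhere(mask.values > 0))
        if len(pts) == 0:
            return 0.0
        moved = self.transform_points(pts)
        return float(np.linalg.norm(moved - pts, axis=1).max())
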