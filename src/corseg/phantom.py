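"""Synthetic thoracic CT phantoms with ground-truth cardiac structures.

The phantom emulates a radiotherapy-planning thoracic CT at clinical
resolution (~1–2 mm in-plane, 2–2.5 mm slices): a soft-tissue background,
two low-density lungs, a heart built from four ellipsoidal chambers in
anatomical arrangement, three great-vessel tubes abutting the correct
chambers (AA–LV, PA–RV, SVC–RA), four thin coronary-artery tubes on the
epicardial surface, and a myocardium shell — with per-tissue Hounsfield
levels plus Gaussian noise. Ground-truth masks are produced for the whole
heart (union of all cardiac components dilated 3 mm), the four chambers,
the three great-vessel bases and the four coronary arteries; chambers and
vessels are pairwise disjoint by construction.

Atlas cohorts are generated by warping the template with random smooth
diffeomorphic displacement fields; the true field of each case is retained
so registration recovery is testable without any external data.

Everything is deterministic given the seed, and case ``i`` of a cohort
depends only on the master seed and ``i`` (cohorts are prefix-stable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import BinaryMask, VolumeGrid, morphology
from .structures import StructureSet
from .transforms import SpatialTransform

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "AtlasCase",
    "generate_phantom",
    "generate_atlas_cohort",
    "random_smooth_transform",
]

# Reference anatomy, defined in world mm on a 256 x 256 x 200 mm extent and
# rescaled to other grids. Chamber entries are (centre, radii); vessel
# entries are (start, end, radius) tubes; coronaries are polylines swept by
# a 2 mm-radius tube (4 mm diameter).
_REF_EXTENT = np.array([256.0, 256.0, 200.0])

_REF_CHAMBERS: Mapping[str, tuple[tuple, tuple]] = {
    "LV": ((105.0, 150.0, 85.0), (34.0, 30.0, 30.0)),
    "RV": ((152.0, 148.0, 88.0), (30.0, 27.0, 26.0)),
    "LA": ((108.0, 102.0, 112.0), (26.0, 25.0, 23.0)),
    "RA": ((155.0, 100.0, 110.0), (27.0, 24.0, 24.0)),
}

_REF_VESSELS: Mapping[str, tuple[tuple, tuple, float]] = {
    "AA": ((105.0, 150.0, 110.0), (105.0, 150.0, 158.0), 14.0),
    "PA": ((152.0, 148.0, 110.0), (152.0, 148.0, 152.0), 12.0),
    "SVC": ((155.0, 100.0, 128.0), (155.0, 100.0, 166.0), 10.0),
}

_REF_CORONARIES: Mapping[str, list[tuple]] = {
    "LMCA": [(122.0, 154.0, 112.0), (124.0, 166.0, 108.0)],
    "LAD": [
        (124.0, 166.0, 108.0),
        (130.0, 172.0, 100.0),
        (128.0, 176.0, 82.0),
        (122.0, 174.0, 66.0),
    ],
    "LCX": [(124.0, 166.0, 108.0), (98.0, 176.0, 104.0), (76.0, 160.0, 100.0)],
    "RCA": [
        (168.0, 136.0, 110.0),
        (180.0, 124.0, 96.0),
        (178.0, 106.0, 84.0),
        (166.0, 92.0, 74.0),
    ],
}

_REF_LUNGS = (((50.0, 128.0, 100.0), (38.0, 70.0, 85.0)),
              ((206.0, 128.0, 100.0), (38.0, 70.0, 85.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic thoracic phantom.

    Chamber/vessel/coronary geometry defaults to the reference anatomy
    scaled to the grid extent; HU levels approximate blood (~40),
    myocardium (~50), lung (~-750) and soft tissue (~30) on non-contrast
    CT, with ``noise_sigma_hu`` Gaussian noise (default 10 HU).
    """

    shape: tuple[int, int, int] = (128, 128, 80)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    chambers: Mapping[str, tuple[tuple, tuple]] | None = None
    vessels: Mapping[str, tuple[tuple, tuple, float]] | None = None
    coronaries: Mapping[str, list[tuple]] | None = None
    coronary_radius_mm: float = 2.0
    wh_margin_mm: float = 3.0
    myocardium_mm: float = 6.0
    hu_blood: float = 40.0
    hu_myocardium: float = 50.0
    hu_lung: float = -750.0
    hu_soft_tissue: float = 30.0
    noise_sigma_hu: float = 10.0
    seed: int = 0

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * np.asarray(self.spacing, dtype=float)

    def _axis_scale(self) -> np.ndarray:
        return self.extent_mm / _REF_EXTENT

    def _size_scale(self) -> float:
        return float(np.min(self._axis_scale()))

    def resolved_anatomy(self):
        """Anatomy in world mm, scaled from the reference if not given."""
        f = self._axis_scale()
        s = self._size_scale()
        chambers = self.chambers or {
            n: (tuple(np.asarray(c) * f), tuple(np.asarray(r) * s))
            for n, (c, r) in _REF_CHAMBERS.items()
        }
        vessels = self.vessels or {
            n: (tuple(np.asarray(a) * f), tuple(np.asarray(b) * f), r * s)
            for n, (a, b, r) in _REF_VESSELS.items()
        }
        coronaries = self.coronaries or {
            n: [tuple(np.asarray(p) * f) for p in pts]
            for n, pts in _REF_CORONARIES.items()
        }
        return chambers, vessels, coronaries


@dataclass(frozen=True)
class DeformationSpec:
    """Random smooth diffeomorphic deformation: coarse random displacement
    grid (``control_spacing_mm``) smoothly upsampled, scaled so the largest
    displacement is ``max_displacement_mm`` and the Jacobian stays positive."""

    control_spacing_mm: float = 40.0
    max_displacement_mm: float = 8.0
    seed: int = 0


@dataclass(frozen=True)
class AtlasCase:
    """One atlas patient: CT-like image and structure set, co-registered."""

    case_id: str
    image: VolumeGrid
    structures: StructureSet
    true_transform: SpatialTransform | None = None


# -- rasterisation helpers -------------------------------------------------

def _world_coords(grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sp, o = grid.spacing, grid.origin
    ax = [o[a] + sp[a] * np.arange(grid.shape[a]) for a in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid_level(coords, centre, radii) -> np.ndarray:
    X, Y, Z = coords
    c, r = np.asarray(centre), np.asarray(radii)
    return ((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2 + ((Z - c[2]) / r[2]) ** 2


def _tube_mask(grid: VolumeGrid, points: np.ndarray, radius_mm: float) -> np.ndarray:
    from .core import polyline_tube

    return polyline_tube(grid, points, radius_mm)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, StructureSet]:
    """Generate the CT-like image and ground-truth structure set.

    Deterministic given ``spec.seed``. Raises if any structure would leave
    the grid.
    """
    geom = VolumeGrid(
        np.zeros(spec.shape, dtype=np.float32),
        spacing=np.asarray(spec.spacing),
        origin=np.zeros(3),
    )
    chambers, vessels, coronaries = spec.resolved_anatomy()
    extent = spec.extent_mm
    for name, (c, r) in chambers.items():
        if np.any(np.asarray(c) - r < 0) or np.any(np.asarray(c) + r > extent):
            raise ValueError(f"chamber {name} exceeds the grid extent")

    coords = _world_coords(geom)

    # chambers: ellipsoids made pairwise disjoint by nearest-in-ellipsoid-
    # metric assignment (curved septa at mutual overlaps)
    names = list(chambers)
    levels = np.stack([_ellipsoid_level(coords, *chambers[n]) for n in names])
    inside = levels.min(axis=0) < 1.0
    winner = levels.argmin(axis=0)
    chamber_masks = {n: inside & (winner == i) for i, n in enumerate(names)}
    chamber_union = inside

    # great vessels: tubes abutting their chamber, trimmed for disjointness
    occupied = chamber_union.copy()
    vessel_masks = {}
    for name, (a, b, radius) in vessels.items():
        tube = _tube_mask(geom, np.array([a, b]), radius)
        if not tube.any():
            raise ValueError(f"vessel {name} rasterised empty")
        vessel_masks[name] = tube & ~occupied
        occupied |= tube

    # coronary arteries: thin surface tubes, trimmed for disjointness; the
    # radius is floored at one voxel so tubes stay resolvable (and survive
    # interpolation) on coarse grids
    cor_radius = max(spec.coronary_radius_mm, float(np.max(geom.spacing)))
    coronary_masks = {}
    for name, pts in coronaries.items():
        tube = _tube_mask(geom, np.asarray(pts), cor_radius)
        coronary_masks[name] = tube & ~occupied
        occupied |= tube

    structures = StructureSet()
    for n, m in {**chamber_masks, **vessel_masks, **coronary_masks}.items():
        if not m.any():
            raise ValueError(f"structure {n} is empty after disjointness trimming")
        structures[n] = BinaryMask.from_array(m, geom)

    union = BinaryMask.from_array(occupied, geom)
    wh = morphology(union, "dilate", spec.wh_margin_mm)
    if wh.values[0, :, :].any() or wh.values[-1, :, :].any() or wh.values[:, 0, :].any() \
            or wh.values[:, -1, :].any() or wh.values[:, :, 0].any() or wh.values[:, :, -1].any():
        raise ValueError("whole heart touches the grid boundary; enlarge the grid")
    structures["WH"] = wh

    # image: soft tissue, lungs, myocardium shell, blood pool
    img = np.full(spec.shape, spec.hu_soft_tissue, dtype=np.float32)
    f = spec._axis_scale()
    s = spec._size_scale()
    for c, r in _REF_LUNGS:
        lung = _ellipsoid_level(coords, np.asarray(c) * f, np.asarray(r) * s) < 1.0
        img[lung] = spec.hu_lung
    myo = morphology(BinaryMask.from_array(chamber_union, geom), "dilate", spec.myocardium_mm)
    img[myo.values > 0] = spec.hu_myocardium
    blood = chamber_union.copy()
    for m in vessel_masks.values():
        blood |= m
    for m in coronary_masks.values():
        blood |= m
    img[blood] = spec.hu_blood
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma_hu, size=spec.shape).astype(np.float32)
    return geom.with_values(img.astype(np.float32)), structures


# -- random smooth deformations --------------------------------------------

def random_smooth_transform(
    grid: VolumeGrid, deform: DeformationSpec, rng: np.random.Generator
) -> SpatialTransform:
    """Sample a smooth, diffeomorphic displacement-field transform on ``grid``.

    Displacements are drawn on a coarse control grid (zero at the volume
    boundary), upsampled with cubic interpolation, and scaled so the
    maximum displacement equals ``max_displacement_mm``. If the Jacobian
    determinant is not strictly positive the field is shrunk (bounded
    retries) before erroring.
    """
    extent = np.asarray(grid.shape) * grid.spacing
    n_ctrl = np.maximum(np.ceil(extent / deform.control_spacing_mm).astype(int) + 1, 4)
    u = rng.normal(size=(3, *n_ctrl))
    u[:, [0, -1], :, :] = 0.0
    u[:, :, [0, -1], :] = 0.0
    u[:, :, :, [0, -1]] = 0.0
    zoom = np.asarray(grid.shape) / n_ctrl
    full = np.stack(
        [ndimage.zoom(u[c], zoom, order=3, grid_mode=True, mode="nearest") for c in range(3)]
    )
    mag = np.linalg.norm(full, axis=0).max()
    if deform.max_displacement_mm == 0 or mag == 0:
        full = np.zeros_like(full)
    else:
        full *= deform.max_displacement_mm / mag

    scale = 1.0
    for _ in range(6):
        # (3, nx, ny, nz) -> (nz, ny, nx, component) as SimpleITK expects
        field_arr = np.ascontiguousarray(
            np.transpose(np.moveaxis(full * scale, 0, -1), (2, 1, 0, 3))
        )
        field_img = sitk.GetImageFromArray(field_arr, isVector=True)
        field_img = sitk.Cast(field_img, sitk.sitkVectorFloat64)
        field_img.SetSpacing(tuple(map(float, grid.spacing)))
        field_img.SetOrigin(tuple(map(float, grid.origin)))
        field_img.SetDirection(tuple(grid.direction.flatten()))
        jac = sitk.GetArrayFromImage(sitk.DisplacementFieldJacobianDeterminant(field_img))
        if jac.min() > 0.05:
            return SpatialTransform.from_displacement_field(field_img)
        scale *= 0.7
    raise RuntimeError("could not sample a diffeomorphic deformation field")


def warp_case(
    image: VolumeGrid,
    structures: StructureSet,
    transform: SpatialTransform,
    background: float,
) -> tuple[VolumeGrid, StructureSet]:
    """Warp an image + structure set by a resampling transform."""
    from .core import resample, resample_mask

    warped_img = resample(image, image, "linear", background, transform.sitk_transform)
    warped = StructureSet()
    for name, mask in structures.items():
        warped[name] = resample_mask(mask, image, transform.sitk_transform)
    return warped_img, warped


def generate_atlas_cohort(
    template: PhantomSpec, n: int, deform: DeformationSpec
) -> list[AtlasCase]:
    """Generate ``n`` atlas cases by randomly deforming the template phantom.

    Each case is the noiseless template warped by an independent random
    smooth field, with independent image noise added afterwards; the true
    field is kept on the case for registration-recovery tests. Case ``i``
    depends only on ``(deform.seed, i)``, so a cohort of size ``k`` is a
    prefix of the cohort of size ``k + 1``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    clean_spec = replace(template, noise_sigma_hu=0.0)
    image, structures = generate_phantom(clean_spec)
    cases = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(deform.seed, spawn_key=(i,)))
        t = random_smooth_transform(image, deform, rng)
        warped_img, warped = warp_case(image, structures, t, background=template.hu_soft_tissue)
        if template.noise_sigma_hu > 0:
            noisy = warped_img.values + rng.normal(
                0.0, template.noise_sigma_hu, size=warped_img.shape
            ).astype(np.float32)
            warped_img = warped_img.with_values(noisy.astype(np.float32))
        cases.append(
            AtlasCase(case_id=f"case_{i:02d}", image=warped_img, structures=warped, true_transform=t)
        )
    return cases
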