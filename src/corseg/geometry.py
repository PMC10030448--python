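"""Geometric models of heart valves, coronary arteries and conduction nodes.

Valves, coronary arteries and conduction nodes are barely visible on
non-gated, non-contrast planning CT, so they are constructed geometrically
from the segmented chambers and great vessels instead of from image
intensities, following published cardiac contouring guidance:

* aortic / pulmonic valves — an 8 mm-thick slab where the dilated
  ventricle meets its great vessel;
* mitral / tricuspid valves — a 30 mm-diameter, 8 mm-thick cylinder at
  the atrium–ventricle junction, aligned with the chamber-centroid axis;
* coronary arteries — 4 mm-diameter tubes swept along a smoothing spline
  through the fused atlas centreline;
* atrioventricular node — a 10 mm-radius sphere at the four-chamber
  junction; sinoatrial node — a 10 mm-radius sphere at the SVC–right
  atrium junction, shifted inward so it never leaves the whole heart.

All constructions are deterministic functions of the input masks and
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import interpolate, ndimage
from skimage.morphology import skeletonize

from .core import BinaryMask, VolumeGrid, morphology, polyline_tube, signed_distance
from .fusion import fuse
from .structures import CHAMBERS, CORONARY_ARTERIES, StructureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ValveParams",
    "ArteryParams",
    "NodeParams",
    "GeometricParams",
    "build_semilunar_valve",
    "build_atrioventricular_valve",
    "build_coronary_artery",
    "place_avn",
    "place_san",
    "build_all_geometric",
]


@dataclass(frozen=True)
class ValveParams:
    """Valve sizing: AV/PV slab thickness 8 mm; MV/TV cylinder 30 mm
    diameter x 8 mm thickness (guideline values, identical for all cases)."""

    av_pv_thickness_mm: float = 8.0
    mv_tv_diameter_mm: float = 30.0
    mv_tv_thickness_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.av_pv_thickness_mm < 0 or self.mv_tv_diameter_mm <= 0 or self.mv_tv_thickness_mm <= 0:
            raise ValueError("valve dimensions must be positive")


@dataclass(frozen=True)
class ArteryParams:
    """Coronary tube diameter (4 mm) and centreline spline smoothing."""

    tube_diameter_mm: float = 4.0
    spline_smoothing: float = 2.0

    def __post_init__(self) -> None:
        if self.tube_diameter_mm <= 0:
            raise ValueError("tube_diameter_mm must be positive")


@dataclass(frozen=True)
class NodeParams:
    """Conduction node sphere radius (10 mm for both AVN and SAN)."""

    node_radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.node_radius_mm <= 0:
            raise ValueError("node_radius_mm must be positive")


@dataclass(frozen=True)
class GeometricParams:
    valves: ValveParams = field(default_factory=ValveParams)
    arteries: ArteryParams = field(default_factory=ArteryParams)
    nodes: NodeParams = field(default_factory=NodeParams)


# -- shared helpers ---------------------------------------------------------

def _interface_centroid(a: BinaryMask, b: BinaryMask, dilate_mm: float = 2.0) -> np.ndarray | None:
    """World centroid of the A-side interface voxels (6-neighbourhood);
    falls back to the overlap after mutual ``dilate_mm`` dilation."""
    conn6 = ndimage.generate_binary_structure(3, 1)
    ia, ib = a.values.astype(bool), b.values.astype(bool)
    interface = ia & ndimage.binary_dilation(ib, structure=conn6)
    if not interface.any():
        da = morphology(a, "dilate", dilate_mm).values.astype(bool)
        db = morphology(b, "dilate", dilate_mm).values.astype(bool)
        interface = da & db
    if not interface.any():
        return None
    return a.grid.index_to_world(np.argwhere(interface)).mean(axis=0)


def voxelised_sphere(grid: VolumeGrid, centre_mm: np.ndarray, radius_mm: float) -> BinaryMask:
    """Every voxel whose centre lies within ``radius_mm`` of ``centre_mm``."""
    c = np.asarray(centre_mm, dtype=float)
    lo = np.maximum(np.floor(grid.world_to_index(c - radius_mm - grid.spacing)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.world_to_index(c + radius_mm + grid.spacing)).astype(int) + 1,
                    grid.shape)
    out = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        return BinaryMask.from_array(out, grid)
    idx = np.stack(np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    d = np.linalg.norm(grid.index_to_world(idx) - c, axis=1)
    hit = idx[d <= radius_mm]
    out[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    return BinaryMask.from_array(out, grid)


# -- valves -----------------------------------------------------------------

def build_semilunar_valve(ventricle: BinaryMask, vessel: BinaryMask,
                          params: ValveParams | None = None) -> BinaryMask:
    """Aortic / pulmonic valve: dilate the ventricle by the valve thickness
    and mask by the great vessel — ``(dilate(V, t) \\ V) ∩ vessel``.

    Zero thickness yields an empty valve; a non-adjacent ventricle/vessel
    pair raises (the dilated shell never reaches the vessel).
    """
    params = params or ValveParams()
    if ventricle.is_empty or vessel.is_empty:
        raise ValueError("valve construction requires non-empty inputs")
    t = params.av_pv_thickness_mm
    if t == 0:
        return BinaryMask.from_array(np.zeros(ventricle.grid.shape, bool), ventricle.grid)
    shell = morphology(ventricle, "dilate", t).difference(ventricle)
    valve = shell.intersection(vessel)
    if valve.is_empty:
        raise ValueError("valve construction failed: structures not adjacent")
    return valve


def build_atrioventricular_valve(atrium: BinaryMask, ventricle: BinaryMask,
                                 params: ValveParams | None = None) -> BinaryMask:
    """Mitral / tricuspid valve: a cylinder at the atrium–ventricle junction.

    The cylinder (diameter ``mv_tv_diameter_mm``, height ``mv_tv_thickness_mm``)
    is centred on the junction centroid so its mid-plane passes through the
    junction, with its axis along the unit vector from the atrium centroid
    to the ventricle centroid.
    """
    params = params or ValveParams()
    if atrium.is_empty or ventricle.is_empty:
        raise ValueError("valve construction requires non-empty inputs")
    ca, cv = atrium.centroid_mm(), ventricle.centroid_mm()
    axis = cv - ca
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise ValueError("degenerate chamber configuration: coincident centroids")
    axis = axis / norm
    centre = _interface_centroid(atrium, ventricle)
    if centre is None:
        raise ValueError("valve construction failed: chambers not adjacent")

    grid = atrium.grid
    r = params.mv_tv_diameter_mm / 2.0
    h = params.mv_tv_thickness_mm / 2.0
    # canonical axis sign (first non-zero component positive) so swapping
    # the chamber arguments yields the identical voxel set; the sub-voxel
    # offset keeps end planes that align exactly with voxel centres from
    # being counted on both faces
    nz = int(np.nonzero(np.abs(axis) > 1e-9)[0][0])
    if axis[nz] < 0:
        axis = -axis
    centre_v = centre + 1e-3 * axis
    reach = np.sqrt(r ** 2 + h ** 2) + grid.voxel_diagonal_mm
    lo = np.maximum(np.floor(grid.world_to_index(centre - reach)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.world_to_index(centre + reach)).astype(int) + 1, grid.shape)
    idx = np.stack(np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    rel = grid.index_to_world(idx) - centre_v
    along = rel @ axis
    radial = np.linalg.norm(rel - np.outer(along, axis), axis=1)
    hit = idx[(np.abs(along) <= h) & (radial < r)]
    out = np.zeros(grid.shape, dtype=bool)
    out[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    return BinaryMask.from_array(out, grid)


# -- coronary arteries ------------------------------------------------------

def _skeleton_longest_path(mask_vals: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Ordered voxel indices of the longest path through the 3D skeleton."""
    skel = skeletonize(mask_vals.astype(bool))
    pts = np.argwhere(skel)
    if len(pts) < 2:
        # thin structure: fall back to the mask voxels themselves
        pts = np.argwhere(mask_vals.astype(bool))
        if len(pts) < 2:
            raise ValueError("centreline shorter than 2 points")
    g = nx.Graph()
    voxset = {tuple(p) for p in pts}
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for p in voxset:
        g.add_node(p)
        for o in offsets:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            if q in voxset:
                g.add_edge(p, q, weight=float(np.linalg.norm(np.array(o) * spacing)))
    # largest connected piece; two sweeps of Dijkstra find the graph diameter
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    start = next(iter(comp))
    dist = nx.single_source_dijkstra_path_length(sub, start)
    u = max(dist, key=dist.get)
    dist_u, paths_u = nx.single_source_dijkstra(sub, u)
    v = max(dist_u, key=dist_u.get)
    return np.asarray(paths_u[v])


def build_coronary_artery(warped_artery_masks: Sequence[BinaryMask],
                          params: ArteryParams | None = None) -> BinaryMask:
    """A coronary artery as a 4 mm-diameter tube along a smoothing spline.

    The co-registered atlas artery masks are fused into a probability map,
    thresholded at 0.5 (falling back to the maximum-probability ridge when
    the majority region is empty); the centreline is the longest path
    through the 3D skeleton, ordered and fitted with a cubic smoothing
    spline, and a sphere of ``tube_diameter_mm`` is swept along it.
    """
    params = params or ArteryParams()
    prob = fuse(list(warped_artery_masks))
    region = prob.values >= 0.5
    if not region.any():
        peak = prob.values.max()
        if peak <= 0:
            raise ValueError("coronary construction failed: fused probability map is empty")
        region = prob.values >= peak
    grid = prob.grid
    path_idx = _skeleton_longest_path(region, grid.spacing)
    pts = grid.index_to_world(path_idx)

    k = min(3, len(pts) - 1)
    if k >= 1 and len(pts) > k:
        tck, _ = interpolate.splprep(pts.T, s=params.spline_smoothing * len(pts), k=k)
        u = np.linspace(0, 1, max(10 * len(pts), 50))
        pts = np.stack(interpolate.splev(u, tck), axis=1)
    tube = polyline_tube(grid, pts, params.tube_diameter_mm / 2.0)
    out = BinaryMask.from_array(tube, grid)
    return morphology(out, "largest_component")


# -- conduction nodes -------------------------------------------------------

def place_avn(chambers: StructureSet, params: NodeParams | None = None) -> BinaryMask:
    """Atrioventricular node: a 10 mm-radius sphere centred at the
    four-chamber junction — the point minimising the summed Euclidean
    distances to the four chamber surfaces."""
    params = params or NodeParams()
    masks = []
    for name in CHAMBERS:
        m = chambers.get(name)
        if m is None or m.is_empty:
            raise ValueError(f"AVN placement requires non-empty chamber {name}")
        masks.append(m)
    grid = masks[0].grid
    total = np.zeros(grid.shape, dtype=float)
    for m in masks:
        total += np.abs(signed_distance(m).values)
    best = np.unravel_index(np.argmin(total), total.shape)
    if total[best] > 50.0:
        raise ValueError("no plausible four-chamber junction (chambers too far apart)")
    centre = grid.index_to_world(np.asarray(best, dtype=float))
    return voxelised_sphere(grid, centre, params.node_radius_mm)


def place_san(svc: BinaryMask, ra: BinaryMask, wh: BinaryMask,
              params: NodeParams | None = None) -> BinaryMask:
    """Sinoatrial node: a 10 mm-radius sphere at the SVC–right-atrium
    junction, shifted inward along the whole-heart depth gradient just far
    enough that it does not extend beyond the whole heart."""
    params = params or NodeParams()
    if svc.is_empty or ra.is_empty or wh.is_empty:
        raise ValueError("SAN placement requires non-empty SVC, RA and WH")
    r = params.node_radius_mm
    grid = wh.grid
    sd = signed_distance(wh)
    if float(sd.values.min()) > -r:
        raise ValueError("whole heart too thin to contain the SAN sphere")
    centre = _interface_centroid(svc, ra)
    if centre is None:
        raise ValueError("SAN placement failed: SVC and RA not adjacent")

    gx, gy, gz = np.gradient(sd.values, *grid.spacing)

    def depth_and_grad(p: np.ndarray) -> tuple[float, np.ndarray]:
        ci = grid.world_to_index(p).reshape(3, 1)
        d = float(ndimage.map_coordinates(sd.values, ci, order=1)[0])
        g = np.array([ndimage.map_coordinates(a, ci, order=1)[0] for a in (gx, gy, gz)])
        n = np.linalg.norm(g)
        return d, (g / n if n > 1e-9 else g)

    def contained(c: np.ndarray) -> BinaryMask | None:
        sphere = voxelised_sphere(grid, c, r)
        outside = sphere.values.astype(bool) & ~wh.values.astype(bool)
        return None if outside.any() else sphere

    junction = centre.copy()

    # walk along the steepest-inward depth gradient until the continuous
    # containment condition d(centre) <= -r holds, then nudge for the
    # discrete voxelisation
    ok = False
    for _ in range(60):
        d, g = depth_and_grad(centre)
        if d <= -r:
            ok = True
            break
        centre = centre - min(d + r, 5.0) * g  # -grad points inward
    if ok:
        step = 0.5 * float(grid.spacing.min())
        for _ in range(20):
            sphere = contained(centre)
            if sphere is not None:
                return sphere
            _, g = depth_and_grad(centre)
            centre = centre - step * g

    # thin or ridged whole hearts can stall the gradient walk: fall back to
    # the deep-enough voxel centre nearest the junction
    eligible = np.argwhere(sd.values <= -r)
    if len(eligible):
        pts = grid.index_to_world(eligible)
        order = np.argsort(np.linalg.norm(pts - junction, axis=1), kind="stable")
        for k in order[:200]:
            sphere = contained(pts[k])
            if sphere is not None:
                return sphere
    raise ValueError("could not shift SAN sphere inside the whole heart")


# -- assembly ---------------------------------------------------------------

def build_all_geometric(
    structures: StructureSet,
    warped_arteries: Mapping[str, Sequence[BinaryMask]],
    params: GeometricParams | None = None,
) -> StructureSet:
    """Add the ten geometric structures to a chambers+vessels structure set.

    Builds AV (LV+AA), PV (RV+PA), MV (LA+LV), TV (RA+RV), the four
    coronary arteries from the warped atlas tubes, and the AVN/SAN spheres.
    Construction errors propagate annotated with the structure name.
    Valves deliberately overlap the chambers/vessels that define them and
    are not subtracted from them.
    """
    params = params or GeometricParams()
    out = structures.copy()

    recipes = {
        "AV": lambda: build_semilunar_valve(out["LV"], out["AA"], params.valves),
        "PV": lambda: build_semilunar_valve(out["RV"], out["PA"], params.valves),
        "MV": lambda: build_atrioventricular_valve(out["LA"], out["LV"], params.valves),
        "TV": lambda: build_atrioventricular_valve(out["RA"], out["RV"], params.valves),
    }
    for name in CORONARY_ARTERIES:
        tubes = list(warped_arteries.get(name, []))
        recipes[name] = (lambda t=tubes: build_coronary_artery(t, params.arteries))
    recipes["AVN"] = lambda: place_avn(out, params.nodes)
    recipes["SAN"] = lambda: place_san(out["SVC"], out["RA"], out["WH"], params.nodes)

    for name, build in recipes.items():
        try:
            out[name] = build()
        except Exception as exc:
            raise RuntimeError(f"geometric construction of {name} failed: {exc}") from exc
    return out
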