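"""Geometric constructions of valves, coronary arteries and conduction nodes."""

import numpy as np
import pytest

from corseg import (BinaryMask, StructureSet, ValveParams, build_all_geometric,
                    build_atrioventricular_valve, build_coronary_artery,
                    build_semilunar_valve, dsc, place_avn, place_san, polyline_tube)
from conftest import box, make_grid, sphere, world_axes


def cylinder_z(grid, centre_xy, radius, z_lo, z_hi):
    X, Y, Z = world_axes(grid)
    m = (np.hypot(X - centre_xy[0], Y - centre_xy[1]) < radius) & (Z >= z_lo) & (Z < z_hi)
    return BinaryMask.from_array(m, grid)


@pytest.fixture(scope="module")
def g100():
    return make_grid((100, 100, 100), (1.0, 1.0, 1.0))


class TestSemilunarValve:
    def test_slab_thickness_along_vessel_axis(self, g100):
        vent = box(g100, (20, 20, 10), (60, 60, 50))
        vessel = cylinder_z(g100, (40, 40), 10.0, 50, 90)
        valve = build_semilunar_valve(vent, vessel, ValveParams(av_pv_thickness_mm=8.0))
        zs = np.argwhere(valve.values)[:, 2]
        thickness = (zs.max() - zs.min() + 1) * g100.spacing[2]
        assert thickness == pytest.approx(8.0, abs=g100.spacing[2])
        # contained in the vessel by construction
        assert not valve.difference(vessel).values.any()

    def test_zero_thickness_gives_empty_valve(self, g100):
        vent = box(g100, (20, 20, 10), (60, 60, 50))
        vessel = cylinder_z(g100, (40, 40), 10.0, 50, 90)
        assert build_semilunar_valve(vent, vessel, ValveParams(av_pv_thickness_mm=0.0)).is_empty

    def test_distant_vessel_rejected(self, g100):
        vent = box(g100, (20, 20, 10), (60, 60, 50))
        vessel = cylinder_z(g100, (40, 40), 10.0, 70, 90)  # 20 mm gap
        with pytest.raises(ValueError, match="not adjacent"):
            build_semilunar_valve(vent, vessel)


class TestAtrioventricularValve:
    def test_cylinder_volume_matches_analytic(self, g100):
        a = sphere(g100, (50, 30, 50), 20.0)
        v = sphere(g100, (50, 70, 50), 20.0)
        valve = build_atrioventricular_valve(a, v)
        assert valve.volume_mm3 == pytest.approx(np.pi * 15 ** 2 * 8, rel=0.10)

    def test_axis_parallel_to_centroid_vector(self, g100):
        a = sphere(g100, (40, 30, 45), 18.0)
        v = sphere(g100, (55, 65, 55), 18.0)
        valve = build_atrioventricular_valve(a, v)
        axis = v.centroid_mm() - a.centroid_mm()
        axis /= np.linalg.norm(axis)
        pts = valve.grid.index_to_world(np.argwhere(valve.values))
        rel = pts - pts.mean(axis=0)
        # principal thinnest direction of an 8 mm x 30 mm disc is its axis
        w, vecs = np.linalg.eigh(np.cov(rel.T))
        disc_axis = vecs[:, 0]
        angle = np.degrees(np.arccos(min(1.0, abs(disc_axis @ axis))))
        assert angle < 5.0

    def test_swapping_chambers_gives_identical_voxels(self, g100):
        a = sphere(g100, (50, 30, 50), 20.0)
        v = sphere(g100, (50, 70, 50), 20.0)
        m1 = build_atrioventricular_valve(a, v)
        m2 = build_atrioventricular_valve(v, a)
        assert np.array_equal(m1.values, m2.values)

    def test_coincident_centroids_rejected(self, g100):
        a = sphere(g100, (50, 50, 50), 15.0)
        with pytest.raises(ValueError, match="degenerate"):
            build_atrioventricular_valve(a, a)


class TestCoronaryArtery:
    def test_straight_tube_round_trip(self, g100):
        pts = np.array([[20.0, 50, 50], [80, 50, 50]])
        tube = BinaryMask.from_array(polyline_tube(g100, pts, 2.0), g100)
        out = build_coronary_artery([tube])
        assert dsc(out, tube) >= 0.8

    def test_three_parallel_tubes_centreline_near_middle(self, g100):
        tubes = [
            BinaryMask.from_array(
                polyline_tube(g100, np.array([[20.0, 50, 50 + dz], [80, 50, 50 + dz]]), 2.0),
                g100)
            for dz in (-2.0, 0.0, 2.0)
        ]
        out = build_coronary_artery(tubes)
        zs = np.argwhere(out.values)[:, 2] * g100.spacing[2]
        assert abs(zs.mean() - 50.0) <= 1.0

    def test_output_diameter_is_four_mm(self, g100):
        pts = np.array([[20.0, 50, 50], [80, 50, 50]])
        tube = BinaryMask.from_array(polyline_tube(g100, pts, 2.0), g100)
        out = build_coronary_artery([tube])
        # equivalent diameter of the mean cross-section away from the ends
        idx = np.argwhere(out.values)
        counts = [np.sum(idx[:, 0] == x) for x in range(30, 70)]
        diam = 2 * np.sqrt(np.mean(counts) / np.pi)
        assert diam == pytest.approx(4.0, abs=1.0)

    def test_empty_input_rejected(self, g100):
        e = BinaryMask.from_array(np.zeros(g100.shape), g100)
        with pytest.raises(ValueError):
            build_coronary_artery([e])


def octant_chambers(grid, centre=(50.0, 50.0, 50.0), pad=15.0):
    """Four boxes in an alternating octant pattern meeting at one point."""
    X, Y, Z = world_axes(grid)
    cx, cy, cz = centre
    lo, hi = pad, 100 - pad
    inside = (X > lo) & (X < hi) & (Y > lo) & (Y < hi) & (Z > lo) & (Z < hi)
    ss = StructureSet()
    ss["LA"] = BinaryMask.from_array((X < cx) & (Y < cy) & (Z < cz) & inside, grid)
    ss["LV"] = BinaryMask.from_array((X < cx) & (Y >= cy) & (Z >= cz) & inside, grid)
    ss["RA"] = BinaryMask.from_array((X >= cx) & (Y < cy) & (Z >= cz) & inside, grid)
    ss["RV"] = BinaryMask.from_array((X >= cx) & (Y >= cy) & (Z < cz) & inside, grid)
    return ss


class TestConductionNodes:
    def test_avn_at_four_chamber_junction(self, g100):
        ss = octant_chambers(g100)
        avn = place_avn(ss)
        # the common corner of the voxelised octants sits at 49.5 mm
        assert np.abs(avn.centroid_mm() - 49.5).max() <= 1.0
        radius = (3 * avn.volume_mm3 / (4 * np.pi)) ** (1 / 3)
        assert radius == pytest.approx(10.0, rel=0.05)

    def test_avn_translation_equivariance(self, g100):
        ss = octant_chambers(g100)
        shifted = StructureSet({n: BinaryMask.from_array(
            np.roll(ss[n].values, (5, 5, 5), axis=(0, 1, 2)), g100) for n in ss.names()})
        c1 = place_avn(ss).centroid_mm()
        c2 = place_avn(shifted).centroid_mm()
        assert np.allclose(c2 - c1, [5, 5, 5], atol=1.0)

    def test_avn_missing_chamber_rejected(self, g100):
        ss = octant_chambers(g100)
        ss["LV"] = BinaryMask.from_array(np.zeros(g100.shape), g100)
        with pytest.raises(ValueError, match="LV"):
            place_avn(ss)

    def test_san_deep_junction_not_shifted(self, g100):
        X, Y, Z = world_axes(g100)
        ra = sphere(g100, (50, 50, 35), 22.0)
        svc = cylinder_z(g100, (50, 50), 8.0, 52, 85)
        wh = box(g100, (5, 5, 5), (95, 95, 95))  # junction far from WH surface
        san = place_san(svc, ra, wh)
        junction_z = 55.0  # approx interface height
        assert abs(san.centroid_mm()[2] - junction_z) < 4.0
        assert not (san.values.astype(bool) & ~wh.values.astype(bool)).any()

    def test_san_shifted_inward_and_contained(self, g100):
        ra = sphere(g100, (50, 50, 40), 20.0)
        svc = cylinder_z(g100, (50, 50), 8.0, 58, 85)
        wh = box(g100, (5, 5, 5), (95, 95, 64))  # junction ~4 mm from WH surface
        san = place_san(svc, ra, wh)
        radius = (3 * san.volume_mm3 / (4 * np.pi)) ** (1 / 3)
        assert radius == pytest.approx(10.0, rel=0.05)
        assert not (san.values.astype(bool) & ~wh.values.astype(bool)).any()
        assert san.centroid_mm()[2] <= 54.0  # shifted >= ~6 mm inward

    def test_san_impossible_containment_rejected(self, g100):
        ra = sphere(g100, (50, 50, 40), 20.0)
        svc = cylinder_z(g100, (50, 50), 8.0, 58, 85)
        thin_wh = box(g100, (5, 5, 30), (95, 95, 45))  # 15 mm slab: no 10 mm sphere fits
        with pytest.raises(ValueError, match="too thin|inside the whole heart"):
            place_san(svc, ra, thin_wh)


@pytest.fixture(scope="module")
def phantom_structures(small_phantom):
    return small_phantom[1]


class TestBuildAll:
    def test_all_ten_structures_added_and_deterministic(self, phantom_structures):
        arteries = {n: [phantom_structures[n]] for n in ("LAD", "LCX", "LMCA", "RCA")}
        out1 = build_all_geometric(phantom_structures, arteries)
        out2 = build_all_geometric(phantom_structures, arteries)
        new = {"AV", "PV", "MV", "TV", "LAD", "LCX", "LMCA", "RCA", "AVN", "SAN"}
        for name in new:
            assert name in out1 and not out1[name].is_empty
            assert np.array_equal(out1[name].values, out2[name].values)

    def test_valves_contained_in_their_vessel(self, phantom_structures):
        arteries = {n: [phantom_structures[n]] for n in ("LAD", "LCX", "LMCA", "RCA")}
        out = build_all_geometric(phantom_structures, arteries)
        assert not out["AV"].difference(out["AA"]).values.any()
        assert not out["PV"].difference(out["PA"]).values.any()
        # valves overlap the anatomy that defines them
        assert out["AV"].intersection(out["AA"]).voxel_count > 0
        assert out["MV"].intersection(out["LA"].union(out["LV"])).voxel_count > 0
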