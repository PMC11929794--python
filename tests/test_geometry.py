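"""Island shape and isolation predictors: analytic cases, a dense
boundary-sampling distance oracle, and invariance properties."""

import math

import numpy as np
import pytest
import shapely
from scipy.spatial.distance import cdist
from shapely import affinity
from shapely.geometry import Polygon, box

from insularity.geometry import (
    Archipelago,
    GeometryError,
    IslandPolygon,
    compute_area_perimeter,
    distance_to_main_island,
    nearest_neighbour_distance,
    predictor_geometry_table,
    proximity_index,
    target_effect,
)


def boundary_sample_distance(a: Polygon, b: Polygon, spacing: float = 0.01) -> float:
    """Independent oracle: min distance between boundary points sampled
    every ``spacing`` metres."""
    pa = shapely.get_coordinates(shapely.segmentize(a.boundary, spacing))
    pb = shapely.get_coordinates(shapely.segmentize(b.boundary, spacing))
    return float(cdist(pa, pb).min())


class TestAreaPerimeter:
    def test_unit_square(self):
        isl = IslandPolygon("s", box(0, 0, 1, 1))
        assert compute_area_perimeter(isl) == (1.0, 4.0)

    def test_circle_256gon(self):
        r = 100.0
        ang = np.linspace(0, 2 * math.pi, 257)[:-1]
        poly = Polygon(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        area, perim = compute_area_perimeter(IslandPolygon("c", poly))
        assert area == pytest.approx(math.pi * r**2, rel=1e-3)
        assert perim == pytest.approx(2 * math.pi * r, rel=1e-3)

    def test_square_with_hole(self):
        # shoelace oracle: 100 − 4 = 96 m²; rings 40 + 8 = 48 m
        poly = Polygon(
            [(0, 0), (10, 0), (10, 10), (0, 10)],
            holes=[[(4, 4), (6, 4), (6, 6), (4, 6)]],
        )
        area, perim = compute_area_perimeter(IslandPolygon("h", poly))
        assert area == pytest.approx(96.0)
        assert perim == pytest.approx(48.0)

    def test_rigid_motion_invariance(self):
        poly = Polygon([(0, 0), (7, 1), (9, 6), (3, 8)])
        isl = IslandPolygon("p", poly)
        moved = affinity.rotate(affinity.translate(poly, 123.4, -56.7), 37.0, origin="centroid")
        a0, p0 = compute_area_perimeter(isl)
        a1, p1 = compute_area_perimeter(IslandPolygon("p", moved))
        assert a1 == pytest.approx(a0, rel=1e-9)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_invalid_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(GeometryError):
            IslandPolygon("x", bowtie)


class TestDistances:
    def test_parallel_squares_gap(self):
        arch = Archipelago(
            [IslandPolygon("a", box(0, 0, 1, 1)), IslandPolygon("b", box(11, 0, 12, 1))],
            crs="m",
        )
        assert nearest_neighbour_distance(arch["a"], arch) == pytest.approx(10.0)

    def test_touching_squares(self):
        arch = Archipelago(
            [IslandPolygon("a", box(0, 0, 1, 1)), IslandPolygon("b", box(1, 0, 2, 1))],
            crs="m",
        )
        assert nearest_neighbour_distance(arch["a"], arch) == 0.0

    @pytest.fixture
    def irregular_archipelago(self):
        polys = [
            Polygon([(0, 0), (4, 1), (5, 4), (2, 5), (-1, 3)]),
            Polygon([(9, 2), (12, 1), (13, 5), (10, 6)]),
            Polygon([(3, 10), (6, 9), (8, 12), (4, 14)]),
            Polygon([(14, 10), (17, 11), (16, 15)]),
        ]
        return Archipelago(
            [IslandPolygon(f"i{k}", p) for k, p in enumerate(polys)], crs="m"
        )

    def test_against_dense_sampling_oracle(self, irregular_archipelago):
        for isl in irregular_archipelago:
            others = [o for o in irregular_archipelago if o.id != isl.id]
            oracle = min(boundary_sample_distance(isl.geometry, o.geometry) for o in others)
            got = nearest_neighbour_distance(isl, irregular_archipelago)
            assert abs(got - oracle) <= 0.01

    def test_symmetry_and_centroid_bound(self, toy_archipelago):
        for a in toy_archipelago:
            for b in toy_archipelago:
                if a.id >= b.id:
                    continue
                dab = a.geometry.distance(b.geometry)
                assert dab == pytest.approx(b.geometry.distance(a.geometry))
                assert dab <= a.geometry.centroid.distance(b.geometry.centroid)

    def test_singleton_error(self):
        with pytest.raises(GeometryError, match="at least 2"):
            Archipelago([IslandPolygon("only", box(0, 0, 1, 1))], crs="m")


class TestMainIsland:
    def test_dmi_zero_for_main(self, toy_archipelago):
        assert distance_to_main_island(toy_archipelago["big"], toy_archipelago) == 0.0

    def test_dmi_equals_nn_when_main_is_nearest(self, toy_archipelago):
        isl = toy_archipelago["b"]  # nearest neighbour is 'big'
        assert distance_to_main_island(isl, toy_archipelago) == pytest.approx(
            nearest_neighbour_distance(isl, toy_archipelago)
        )

    def test_dmi_against_oracle(self):
        polys = [
            Polygon([(0, 0), (8, 0), (9, 6), (4, 8), (-1, 5)]),  # main
            Polygon([(14, 1), (17, 2), (16, 5)]),
            Polygon([(2, 12), (5, 11), (6, 15)]),
        ]
        arch = Archipelago([IslandPolygon(f"i{k}", p) for k, p in enumerate(polys)], crs="m")
        main = arch.main_island()
        assert main.id == "i0"
        for isl in arch:
            if isl.id == main.id:
                continue
            oracle = boundary_sample_distance(isl.geometry, main.geometry)
            assert abs(distance_to_main_island(isl, arch) - oracle) <= 0.01

    def test_area_tie_broken_by_id(self):
        arch = Archipelago(
            [IslandPolygon("zz", box(0, 0, 10, 10)), IslandPolygon("aa", box(100, 0, 110, 10))],
            crs="m",
        )
        assert arch.main_island().id == "aa"


class TestTargetEffect:
    def test_log_of_one(self):
        assert target_effect(area=2500.0, dmi=50.0) == 0.0

    def test_decade(self):
        assert target_effect(area=1e4, dmi=1e3) == pytest.approx(1.0)

    def test_monotone_in_dmi_and_area(self):
        vals = [target_effect(1e4, d) for d in (10, 100, 1000)]
        assert vals == sorted(vals) and len(set(vals)) == 3
        areas = [target_effect(a, 500.0) for a in (1e3, 1e4, 1e5)]
        assert areas == sorted(areas, reverse=True)

    def test_domain_errors(self):
        with pytest.raises(GeometryError):
            target_effect(area=0.0, dmi=10.0)
        with pytest.raises(GeometryError):
            target_effect(area=100.0, dmi=-1.0)


class TestProximityIndex:
    def test_no_neighbour_within_radius(self, toy_archipelago):
        assert proximity_index(toy_archipelago["c"], toy_archipelago, radius=50.0) == 0.0

    def test_single_neighbour_closed_form(self):
        arch = Archipelago(
            [IslandPolygon("f", box(0, 0, 1, 1)), IslandPolygon("n", box(11, 0, 21, 10))],
            crs="m",
        )
        # neighbour area 100 m² at edge distance 10 m → 100/10² = 1
        assert proximity_index(arch["f"], arch, radius=20.0) == pytest.approx(1.0)

    def test_hand_sum(self, toy_archipelago):
        focal = toy_archipelago["big"]
        total = 0.0
        for other in toy_archipelago:
            if other.id == focal.id:
                continue
            d = focal.geometry.distance(other.geometry)
            if d <= 200.0:
                total += other.geometry.area / max(d, 2.0) ** 2
        assert proximity_index(focal, toy_archipelago, radius=200.0) == pytest.approx(total)


class TestArchipelagoValidation:
    def test_lonlat_rejected(self):
        a = IslandPolygon("a", box(18.1, -31.2, 18.11, -31.19))
        b = IslandPolygon("b", box(18.2, -31.2, 18.21, -31.19))
        with pytest.raises(GeometryError, match="geographic"):
            Archipelago([a, b], crs="EPSG:4326")

    def test_overlap_rejected(self):
        a = IslandPolygon("a", box(0, 0, 10, 10))
        b = IslandPolygon("b", box(5, 5, 15, 15))
        with pytest.raises(GeometryError, match="overlap"):
            Archipelago([a, b], crs="m")

    def test_duplicate_ids_rejected(self):
        a = IslandPolygon("a", box(0, 0, 1, 1))
        b = IslandPolygon("a", box(5, 5, 6, 6))
        with pytest.raises(GeometryError, match="unique"):
            Archipelago([a, b], crs="m")


def test_predictor_table_covers_sampled_only(toy_archipelago):
    table = predictor_geometry_table(toy_archipelago)
    assert set(table["island_id"]) == {"big", "a", "b", "c"}
    row_a = table.set_index("island_id").loc["a"]
    assert row_a["nn_dist_m"] == pytest.approx(10.0)  # unsampled 'd' is 10 m away
    assert row_a["dmi_m"] == pytest.approx(50.0)
    assert row_a["target_effect"] == pytest.approx(math.log10(50.0 / 10.0))
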