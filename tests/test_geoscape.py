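import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from pelletscape import geoscape
from pelletscape.geoscape import (
    DroughtEvent,
    Landscape,
    assign_procurement_radius,
    circle_intersection_area,
    circle_lens_area,
    drought_covered_fraction,
    drought_flag,
    great_circle_distance,
    local_km_transform,
    overlap_fraction,
    population_in_landscape,
    proximity_flag,
)

R = geoscape.EARTH_RADIUS_KM


class TestProcurementRadius:
    @pytest.mark.parametrize(
        "sector,capacity,expected",
        [
            ("pellet", 150_000, 80.0),
            ("pellet", 100_000, 80.0),  # "at least 100 thousand tons" inclusive
            ("pellet", 99_999, 48.0),
            ("pellet", 50_000, 48.0),
            ("power", 10_000, 80.0),
            ("pulp", 500_000, 121.0),
            ("pulp", 1, 121.0),
        ],
    )
    def test_radius_rules(self, sector, capacity, expected):
        assert assign_procurement_radius(capacity, sector) == expected

    @pytest.mark.parametrize(
        "capacity,sector", [(0, "pellet"), (-5, "pulp"), (1000, "sawmill")]
    )
    def test_rejections(self, capacity, sector):
        with pytest.raises(ValueError):
            assign_procurement_radius(capacity, sector)


class TestGreatCircle:
    def test_one_degree_meridian(self):
        # closed form: 1 degree of arc = R * pi/180
        assert great_circle_distance((0.0, 0.0), (1.0, 0.0)) == pytest.approx(
            111.195, abs=1e-3
        )

    def test_identity_and_antipodal(self):
        assert great_circle_distance((12.0, 45.0), (12.0, 45.0)) == 0.0
        assert great_circle_distance((0.0, 0.0), (180.0, 0.0)) == pytest.approx(
            math.pi * R, rel=1e-12
        )

    @given(
        lon1=st.floats(-180, 180), lat1=st.floats(-90, 90),
        lon2=st.floats(-180, 180), lat2=st.floats(-90, 90),
    )
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_nonnegativity(self, lon1, lat1, lon2, lat2):
        d12 = great_circle_distance((lon1, lat1), (lon2, lat2))
        d21 = great_circle_distance((lon2, lat2), (lon1, lat1))
        assert d12 == pytest.approx(d21, abs=1e-9)
        assert d12 >= 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance((200.0, 0.0), (0.0, 0.0))


def mc_lens_oracle(r1, r2, d, n=10**6, seed=0):
    """Rejection-sampling Monte-Carlo lens area and its standard deviation."""
    rg = np.random.default_rng(seed)
    x = rg.uniform(-r1, r1, n)
    y = rg.uniform(-r1, r1, n)
    hit = (x * x + y * y < r1 * r1) & ((x - d) ** 2 + y * y < r2 * r2)
    p = hit.mean()
    box = 4.0 * r1 * r1
    return box * p, box * math.sqrt(p * (1 - p) / n)


class TestLensArea:
    def test_coincident_and_disjoint(self):
        assert circle_lens_area(1.0, 1.0, 0.0) == pytest.approx(math.pi, rel=1e-12)
        assert circle_lens_area(1.0, 1.0, 2.0) == 0.0
        assert circle_lens_area(3.0, 1.0, 1.5) == pytest.approx(math.pi, rel=1e-12)

    def test_monte_carlo_agreement(self):
        rg = np.random.default_rng(42)
        for k in range(25):
            r1 = rg.uniform(20.0, 130.0)
            r2 = rg.uniform(20.0, 130.0)
            d = rg.uniform(0.0, r1 + r2 + 20.0)
            est, sd = mc_lens_oracle(r1, r2, d, seed=k)
            assert circle_lens_area(r1, r2, d) == pytest.approx(
                est, abs=max(3.0 * sd, 1e-9)
            )

    @given(
        r1=st.floats(1.0, 150.0), r2=st.floats(1.0, 150.0), d=st.floats(0.0, 350.0)
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, r1, r2, d):
        a = circle_lens_area(r1, r2, d)
        assert a == pytest.approx(circle_lens_area(r2, r1, d), rel=1e-9, abs=1e-9)
        assert -1e-12 <= a <= math.pi * min(r1, r2) ** 2 + 1e-9


def _ls(fid, lon, lat, r):
    return Landscape(facility_id=fid, lon=lon, lat=lat, radius_km=r)


class TestOverlapFraction:
    def test_no_neighbours(self):
        assert overlap_fraction(_ls("a", -84, 35, 80), []) == 0.0

    def test_double_containment_counts_twice(self):
        # target entirely inside each of two big neighbours -> exactly 2.0
        target = _ls("a", -84.0, 35.0, 10.0)
        big1 = _ls("b", -84.0, 35.0, 121.0)
        big2 = _ls("c", -84.05, 35.05, 121.0)
        assert overlap_fraction(target, [big1, big2]) == pytest.approx(2.0, rel=1e-9)

    def test_partial_matches_lens_ratio(self):
        target = _ls("a", -84.0, 35.0, 80.0)
        other = _ls("b", -83.5, 35.2, 80.0)
        d = great_circle_distance((-84.0, 35.0), (-83.5, 35.2))
        est, sd = mc_lens_oracle(80.0, 80.0, d, seed=3)
        frac = overlap_fraction(target, [other])
        assert frac == pytest.approx(est / target.circle_area_km2, abs=3 * sd / target.circle_area_km2)

    def test_monotone_in_neighbours(self):
        target = _ls("a", -84.0, 35.0, 80.0)
        others = [_ls(f"b{i}", -84.0 + 0.3 * i, 35.0, 80.0) for i in range(4)]
        fracs = [overlap_fraction(target, others[:k]) for k in range(5)]
        assert all(f2 >= f1 for f1, f2 in zip(fracs, fracs[1:]))


class TestFlags:
    def test_proximity_strict_boundary(self):
        c = (-84.0, 35.0)
        near = [(-84.0, 35.0 + 50.0 / 111.19492664455873)]
        far = [(-84.0, 35.0 + 200.0 / 111.19492664455873)]
        assert proximity_flag(c, near) == 1
        assert proximity_flag(c, far) == 0
        # point at exactly the threshold distance is outside (strict <)
        d_exact = 121.0 / (R * math.pi / 180.0)
        assert proximity_flag(c, [(-84.0, 35.0 + d_exact)]) == 0
        assert proximity_flag(c, []) == 0

    def test_flags_order_invariant(self):
        c = (-84.0, 35.0)
        pts = [(-83.0, 35.0), (-84.0, 35.4), (-80.0, 32.0)]
        assert proximity_flag(c, pts) == proximity_flag(c, pts[::-1])


class TestDrought:
    def _half_plane_event(self, landscape, year):
        # half-plane through the centroid, in local km coordinates
        _, to_lonlat = local_km_transform(landscape.lon, landscape.lat)
        big = 1000.0
        half = Polygon([(0, -big), (big, -big), (big, big), (0, big)])
        from shapely import transform as shp_transform

        return DroughtEvent(
            august_year=year - 1, severity="extreme", footprint=shp_transform(half, to_lonlat)
        )

    def test_no_event_and_full_cover(self):
        ls = _ls("a", -84.0, 35.0, 48.0)
        assert drought_flag(ls, [], 2011) == 0
        _, to_lonlat = local_km_transform(ls.lon, ls.lat)
        from shapely import transform as shp_transform
        from shapely.geometry import Point

        cover = DroughtEvent(
            august_year=2010,
            severity="exceptional",
            footprint=shp_transform(Point(0, 0).buffer(500.0), to_lonlat),
        )
        assert drought_flag(ls, [cover], 2011) == 1
        # wrong august year: not the preceding August
        assert drought_flag(ls, [cover], 2014) == 0

    def test_half_plane_covers_half(self):
        ls = _ls("a", -84.0, 35.0, 80.0)
        ev = self._half_plane_event(ls, 2011)
        frac = drought_covered_fraction(ls, [ev], 2011)
        assert frac == pytest.approx(0.5, abs=2e-3)  # 64-gon circle approximation
        assert drought_flag(ls, [ev], 2011) == 1

    def test_severity_filter_and_order(self):
        ls = _ls("a", -84.0, 35.0, 80.0)
        ev = self._half_plane_event(ls, 2011)
        mild = DroughtEvent(
            august_year=2010, severity="moderate", footprint=ev.footprint
        )
        assert drought_flag(ls, [mild], 2011) == 0
        assert drought_flag(ls, [mild, ev], 2011) == drought_flag(ls, [ev, mild], 2011)


class TestPopulation:
    def test_sum_inside_in_thousands(self):
        ls = _ls("a", -84.0, 35.0, 80.0)
        pts = np.array([[-84.0, 35.1], [-84.1, 35.0], [-70.0, 45.0]])
        counts = np.array([10_000.0, 5_000.0, 999_999.0])
        assert population_in_landscape(ls, pts, counts) == pytest.approx(15.0)

    def test_boundary_excluded_and_empty(self):
        ls = _ls("a", -84.0, 35.0, 80.0)
        lat_on_edge = 35.0 + 80.0 / (R * math.pi / 180.0)
        assert population_in_landscape(ls, np.array([[-84.0, lat_on_edge]]), np.array([7.0])) == 0.0
        assert population_in_landscape(ls, np.empty((0, 2)), np.empty(0)) == 0.0

    def test_negative_counts_rejected(self):
        ls = _ls("a", -84.0, 35.0, 80.0)
        with pytest.raises(ValueError):
            population_in_landscape(ls, np.array([[-84.0, 35.0]]), np.array([-1.0]))


class TestLandscapeInvariants:
    def test_circle_area(self):
        ls = _ls("a", -84.0, 35.0, 80.0)
        assert ls.circle_area_km2 == pytest.approx(math.pi * 80.0**2, rel=1e-12)

    def test_intersection_symmetric(self):
        a = _ls("a", -84.0, 35.0, 48.0)
        b = _ls("b", -83.4, 35.3, 121.0)
        assert circle_intersection_area(a, b) == pytest.approx(
            circle_intersection_area(b, a), rel=1e-12
        )
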