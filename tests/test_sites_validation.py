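"""Site summaries, random null sites, and rank-sum testing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import box

from _oracles import enumerate_rank_sum
from satoyama import (
    SiteRecord,
    generate_random_sites,
    nine_neighbors,
    rank_sum_test,
    site_summary,
    validation_report,
)
from satoyama.index_core import LandUnitIndexGrid
from satoyama.landcover_raster import LandUnitGridSpec
from satoyama.sites_validation import (
    read_point_sites,
    read_polygon_sites,
    write_point_sites,
    write_polygon_sites,
)


def make_spec(rows=6, cols=6, unit=1.0):
    return LandUnitGridSpec(aggregation_factor=1, unit_rows=rows, unit_cols=cols,
                            west=0.0, north=float(rows), unit_size=unit)


def make_index(si_values: np.ndarray) -> LandUnitIndexGrid:
    si = np.asarray(si_values, dtype=float)
    defined = np.isfinite(si)
    nan = np.full_like(si, np.nan)
    return LandUnitIndexGrid(
        sdi=nan.copy(), p=nan.copy(), p_raw=nan.copy(), si=si,
        n_valid=np.where(defined, 144, 0),
        defined=defined, spec=make_spec(*si.shape),
    )


class TestNineNeighbors:
    def test_interior_center_gives_3x3_block(self):
        spec = make_spec()
        keys = nine_neighbors((2.5, 3.5), spec)
        assert len(keys) == 9
        rows = {r for r, _ in keys}
        cols = {c for _, c in keys}
        assert rows == {1, 2, 3} and cols == {1, 2, 3}

    def test_corner_center_truncates_to_4(self):
        keys = nine_neighbors((0.2, 5.8), make_spec())
        assert sorted(keys) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_boundary_point_uses_half_open_convention(self):
        spec = make_spec()
        # (2.0, 4.0) lies on the shared corner of four cells: belongs to (2, 2)
        keys = nine_neighbors((2.0, 4.0), spec)
        assert (2, 2) in keys and len(keys) == 9
        assert spec.unit_of_point(2.0, 4.0) == (2, 2)

    def test_outside_grid_raises(self):
        with pytest.raises(ValueError):
            nine_neighbors((-1.0, 3.0), make_spec())


class TestSiteSummary:
    def test_single_defined_neighbor(self):
        si = np.full((6, 6), np.nan)
        si[2, 2] = 0.1
        summary = site_summary(SiteRecord(id="s", point=(2.5, 3.5)), make_index(si))
        assert summary.n_defined == 1
        assert summary.median_si == summary.max_si == 0.1

    def test_order_statistics(self):
        si = np.full((6, 6), np.nan)
        si[1, 1], si[1, 2], si[1, 3] = 0.2, 0.4, 0.6
        summary = site_summary(SiteRecord(id="s", point=(2.5, 4.5)), make_index(si))
        assert summary.n_defined == 3
        assert summary.median_si == pytest.approx(0.4)
        assert summary.max_si == pytest.approx(0.6)
        assert summary.max_si >= summary.median_si

    def test_no_defined_member_is_not_evaluable(self):
        summary = site_summary(SiteRecord(id="s", point=(2.5, 3.5)),
                               make_index(np.full((6, 6), np.nan)))
        assert not summary.evaluable
        assert summary.median_si is None and summary.max_si is None

    def test_polygon_membership_matches_center_scan(self):
        rng = np.random.default_rng(0)
        si = rng.uniform(size=(6, 6))
        index = make_index(si)
        rect = box(0.7, 1.2, 4.3, 4.9)
        summary = site_summary(SiteRecord(id="s", polygon=rect), index)
        expected = set()
        for r in range(6):
            for c in range(6):
                lon, lat = index.spec.unit_center(r, c)
                if 0.7 <= lon <= 4.3 and 1.2 <= lat <= 4.9:
                    expected.add((r, c))
        assert set(summary.members) == expected


class TestRandomSites:
    def test_single_true_cell_pins_all_sites(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[3, 4] = True
        sites = generate_random_sites(5, mask, make_spec(), lat_bounds=(-90, 90), seed=1)
        assert all(s.point == make_spec().unit_center(3, 4) for s in sites)

    def test_same_seed_reproduces(self):
        mask = np.ones((6, 6), dtype=bool)
        a = generate_random_sites(20, mask, make_spec(), seed=9, lat_bounds=(-90, 90))
        b = generate_random_sites(20, mask, make_spec(), seed=9, lat_bounds=(-90, 90))
        assert [s.point for s in a] == [s.point for s in b]

    def test_centers_respect_mask_and_spread(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[:, :3] = True  # western half
        spec = make_spec()
        sites = generate_random_sites(600, mask, spec, lat_bounds=(-90, 90), seed=3)
        cols = [spec.unit_of_point(*s.point)[1] for s in sites]
        assert set(cols) <= {0, 1, 2}
        # roughly uniform over the 18 eligible cells
        _, counts = np.unique(cols, return_counts=True)
        assert counts.min() > 600 / 3 * 0.6

    def test_latitude_bounds_respected(self):
        spec = make_spec()
        sites = generate_random_sites(
            50, np.ones((6, 6), bool), spec, lat_bounds=(0.0, 3.0), seed=4
        )
        assert all(0.0 <= s.point[1] <= 3.0 for s in sites)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            generate_random_sites(3, np.zeros((6, 6), bool), make_spec(), seed=0)


class TestRankSum:
    def test_clear_separation(self):
        res = rank_sum_test([3, 4], [1, 2])
        assert res.statistic == 4
        assert res.pvalue == pytest.approx(1 / 6)
        assert res.method == "exact"

    def test_least_favorable_ordering(self):
        res = rank_sum_test([1], [2])
        assert res.statistic == 0
        assert res.pvalue == 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("n_t,n_r", [(2, 3), (4, 4), (7, 7), (5, 7)])
    def test_matches_enumeration_oracle(self, n_t, n_r):
        rng = np.random.default_rng(n_t * 100 + n_r)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n_t + n_r + 1))
            t, r = pooled[:n_t], pooled[n_t:]
            w, p = enumerate_rank_sum(t, r)
            res = rank_sum_test(t, r)
            assert res.statistic == w
            assert res.pvalue == pytest.approx(p, abs=1e-12)

    def test_normal_approximation_with_ties(self):
        # values verified against R wilcox.test (asymptotic, continuity-corrected)
        res = rank_sum_test([1.2, 3.4, 3.4, 5.6, 2.2], [0.5, 3.4, 2.2, 1.1, 0.9, 4.4])
        assert res.method == "normal-approx"
        assert res.statistic == pytest.approx(21.5)
        assert res.pvalue == pytest.approx(0.1339072, abs=1e-6)

    @given(
        st.lists(st.integers(0, 10_000), min_size=1, max_size=10, unique=True),
        st.lists(st.integers(10_001, 20_000), min_size=1, max_size=10, unique=True),
    )
    def test_swap_identity(self, t, r):
        t = [float(x) for x in t]
        r = [float(x) + 0.5 for x in r]
        w_fwd = rank_sum_test(t, r).statistic
        w_rev = rank_sum_test(r, t).statistic
        assert w_fwd + w_rev == len(t) * len(r)

    def test_p_decreases_under_positive_shift(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=12)
        r = rng.normal(size=15)
        pvals = [rank_sum_test(t + shift, r).pvalue for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_type_one_error_at_rank_sum_level(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            t = rng.normal(size=15)
            r = rng.normal(size=15)
            rejections += rank_sum_test(t, r).pvalue < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestValidationReport:
    def _summaries(self, values, region="g"):
        return [
            site_summary(SiteRecord(id=str(i), region=region, point=(2.5, 3.5)),
                         make_index(np.full((6, 6), v)))
            for i, v in enumerate(values)
        ]

    def test_complete_separation_maximizes_w(self):
        report = validation_report(
            {"g": self._summaries([0.8, 0.9])},
            {"g": self._summaries([0.1, 0.2, 0.3])},
        )
        max_row = report[report.statistic == "max"].iloc[0]
        assert max_row.W == 6
        assert max_row.p == pytest.approx(1 / 10)

    def test_bookkeeping_columns(self):
        report = validation_report(
            {"g": self._summaries([0.5])},
            {"g": self._summaries([0.1, 0.6, 0.3])},
        )
        assert set(report.group) == {"g"}
        assert set(report.statistic) == {"median", "max"}
        assert (report.n_treatment == 1).all()
        assert (report.n_random == 3).all()

    def test_missing_random_group_raises(self):
        with pytest.raises(KeyError, match="g"):
            validation_report({"g": self._summaries([0.5])}, {})

    def test_group_without_evaluable_site_raises(self):
        bad = [site_summary(SiteRecord(id="x", point=(2.5, 3.5)),
                            make_index(np.full((6, 6), np.nan)))]
        with pytest.raises(ValueError, match="evaluable"):
            validation_report({"g": bad}, {"g": self._summaries([0.1])})


class TestSiteIO:
    def test_point_round_trip(self, tmp_path):
        sites = [SiteRecord(id="a", region="asia", point=(10.25, -3.5)),
                 SiteRecord(id="b", region="", point=(0.0, 0.0))]
        path = tmp_path / "sites.csv"
        write_point_sites(sites, path)
        back = read_point_sites(path)
        assert [(s.id, s.region, s.point) for s in back] == [
            (s.id, s.region, s.point) for s in sites
        ]

    def test_polygon_round_trip(self, tmp_path):
        sites = [SiteRecord(id="p1", region="r", polygon=box(0, 0, 2, 3))]
        path = tmp_path / "sites.geojson"
        write_polygon_sites(sites, path)
        back = read_polygon_sites(path)
        assert back[0].id == "p1"
        assert back[0].polygon.equals(sites[0].polygon)
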