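"""Trait-pair selection, gridding, earliest-per-cell-year, decade filters,
bandwidth and KDE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenokit.analysis import (
    TraitQuery,
    decade_summary,
    earliest_per_cell_year,
    filter_decades,
    grid_cell,
    kde_density,
    rule_of_thumb_bandwidth,
    select_observations,
)
from phenokit.errors import (
    DegenerateDataError,
    InsufficientDataError,
    RangeError,
    UnknownTermError,
)

FLOWERS = "flower_presence:present"
SENESCED = "senesced_flower_presence:present"


def rows_frame(specs):
    """Build a harmonized-rows frame from (oid, classes, genus, lat, lon, date)."""
    return pd.DataFrame(
        [
            {
                "observation_id": oid,
                "subject_id": f"subj_{oid}",
                "genus": genus,
                "species": "",
                "latitude": lat,
                "longitude": lon,
                "date": pd.Timestamp(date),
                "inferred_classes": frozenset(classes),
                "source": "other",
            }
            for oid, classes, genus, lat, lon, date in specs
        ]
    )


class TestSelectObservations:
    def test_require_without_exclude_kept(self):
        rows = rows_frame([("o1", {FLOWERS}, "Acer", 45.0, -93.0, "2010-05-01")])
        q = TraitQuery(FLOWERS, SENESCED)
        assert len(select_observations(rows, q)) == 1

    def test_excluded_class_dropped(self):
        """Rows also bearing the senesced-flower class do not count as
        flowering onsets."""
        rows = rows_frame(
            [("o1", {FLOWERS, SENESCED}, "Acer", 45.0, -93.0, "2010-09-01")]
        )
        q = TraitQuery(FLOWERS, SENESCED)
        assert len(select_observations(rows, q)) == 0

    def test_empty_input(self):
        rows = rows_frame([])
        assert len(select_observations(rows, TraitQuery(FLOWERS))) == 0

    def test_genus_filter_case_insensitive(self):
        rows = rows_frame(
            [
                ("o1", {FLOWERS}, "ACER", 45.0, -93.0, "2010-05-01"),
                ("o2", {FLOWERS}, "Quercus", 45.0, -93.0, "2010-05-01"),
            ]
        )
        out = select_observations(rows, TraitQuery(FLOWERS, genus="acer"))
        assert out["observation_id"].tolist() == ["o1"]

    def test_unknown_class_raises_with_catalog(self, default_catalog):
        rows = rows_frame([("o1", {FLOWERS}, "Acer", 45.0, -93.0, "2010-05-01")])
        with pytest.raises(UnknownTermError):
            select_observations(rows, TraitQuery("ghost:present"), default_catalog)

    def test_exclusion_soundness_random(self):
        rng = np.random.default_rng(17)
        pool = [FLOWERS, SENESCED, "other:present"]
        specs = []
        for i in range(200):
            classes = {c for c in pool if rng.random() < 0.5}
            specs.append((f"o{i}", classes, "Acer", 45.0, -93.0, "2010-05-01"))
        out = select_observations(rows_frame(specs), TraitQuery(FLOWERS, SENESCED))
        assert all(FLOWERS in s and SENESCED not in s for s in out["inferred_classes"])


class TestGridCell:
    @pytest.mark.parametrize(
        "lat, lon, expected",
        [
            ((48.2082), 16.3738, (48.2, 16.4)),
            (0.05, -0.05, (0.1, -0.1)),  # ties round away from zero
            (45.0, -93.0, (45.0, -93.0)),
            (-33.8688, 151.2093, (-33.9, 151.2)),
        ],
    )
    def test_examples(self, lat, lon, expected):
        assert grid_cell(lat, lon) == expected

    def test_out_of_bounds(self):
        with pytest.raises(RangeError):
            grid_cell(91.0, 0.0)
        with pytest.raises(RangeError):
            grid_cell(0.0, -180.5)

    def test_cells_are_tenth_degree_multiples(self):
        """Scaled-integer oracle: 10 * cell is integral to 1e-9."""
        rng = np.random.default_rng(31)
        lats = rng.uniform(-90, 90, 1000)
        lons = rng.uniform(-180, 180, 1000)
        for lat, lon in zip(lats, lons):
            clat, clon = grid_cell(float(lat), float(lon))
            assert abs(round(clat * 10) - clat * 10) < 1e-9
            assert abs(round(clon * 10) - clon * 10) < 1e-9
            assert abs(clat - lat) <= 0.05 + 1e-9
            assert abs(clon - lon) <= 0.05 + 1e-9


class TestEarliestPerCellYear:
    def test_group_minimum(self):
        rows = rows_frame(
            [
                ("o1", {FLOWERS}, "Acer", 45.01, -93.01, "2010-04-05"),  # DOY 95
                ("o2", {FLOWERS}, "Acer", 45.02, -93.02, "2010-03-28"),  # DOY 87
                ("o3", {FLOWERS}, "Acer", 52.01, 13.01, "2010-04-20"),   # DOY 110
            ]
        )
        est = earliest_per_cell_year(rows)
        assert len(est) == 2
        by_cell = est.set_index(["cell_lat", "cell_lon"])["day_of_year"].to_dict()
        assert by_cell[(45.0, -93.0)] == 87
        assert by_cell[(52.0, 13.0)] == 110

    def test_single_row_identity(self):
        rows = rows_frame([("o1", {FLOWERS}, "Acer", 45.0, -93.0, "2010-04-05")])
        est = earliest_per_cell_year(rows)
        assert len(est) == 1 and est.loc[0, "day_of_year"] == 95

    def test_ties_break_by_observation_id(self):
        rows = rows_frame(
            [
                ("b", {FLOWERS}, "Acer", 45.0, -93.0, "2010-04-05"),
                ("a", {FLOWERS}, "Acer", 45.0, -93.0, "2010-04-05"),
            ]
        )
        est = earliest_per_cell_year(rows)
        assert est.loc[0, "observation_id"] == "a"

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(23)
        specs = []
        for i in range(5000):
            lat = float(rng.uniform(40, 42))
            lon = float(rng.uniform(-90, -88))
            year = int(rng.integers(2000, 2005))
            doy = int(rng.integers(1, 300))
            date = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=doy - 1)
            specs.append((f"o{i:04d}", {FLOWERS}, "Acer", lat, lon, date))
        rows = rows_frame(specs)
        est = earliest_per_cell_year(rows)
        # independent nested-loop minimum
        oracle: dict = {}
        for oid, _, _, lat, lon, date in specs:
            key = (grid_cell(lat, lon), date.year)
            doy = date.dayofyear
            if key not in oracle or doy < oracle[key]:
                oracle[key] = doy
        got = {
            ((r.cell_lat, r.cell_lon), r.year): r.day_of_year
            for r in est.itertuples()
        }
        assert got == oracle

    def test_idempotence(self):
        rng = np.random.default_rng(29)
        specs = []
        for i in range(300):
            date = pd.Timestamp(2010, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 320)))
            specs.append(
                (f"o{i:03d}", {FLOWERS}, "Acer", float(rng.uniform(40, 41)),
                 float(rng.uniform(-90, -89)), date)
            )
        est = earliest_per_cell_year(rows_frame(specs))
        # recast estimates as rows and re-apply
        recast = pd.DataFrame(
            {
                "observation_id": est["observation_id"],
                "latitude": est["cell_lat"],
                "longitude": est["cell_lon"],
                "date": [
                    pd.Timestamp(year=int(y), month=1, day=1) + pd.Timedelta(days=int(d) - 1)
                    for y, d in zip(est["year"], est["day_of_year"])
                ],
            }
        )
        again = earliest_per_cell_year(recast)
        pd.testing.assert_frame_equal(
            est.sort_values(["cell_lat", "cell_lon", "year"]).reset_index(drop=True),
            again.sort_values(["cell_lat", "cell_lon", "year"]).reset_index(drop=True),
        )


def estimates_frame(decade_to_doys):
    rows = []
    i = 0
    for decade, doys in decade_to_doys.items():
        for j, doy in enumerate(doys):
            rows.append(
                {
                    "cell_lat": 40.0 + i * 0.1,
                    "cell_lon": -90.0 - j * 0.1,
                    "year": decade + (j % 10),
                    "day_of_year": int(doy),
                    "observation_id": f"o{decade}_{j}",
                }
            )
        i += 1
    return pd.DataFrame(rows)


class TestFilterDecades:
    def test_thousand_record_threshold(self):
        est = estimates_frame({1960: [100] * 999, 1970: [100] * 1000})
        kept = filter_decades(est, 1000)
        assert set(kept["year"] // 10 * 10) == {1970}

    def test_four_hundred_record_threshold(self):
        est = estimates_frame({1990: [100] * 399, 2000: [100] * 401})
        kept = filter_decades(est, 400)
        assert set(kept["year"] // 10 * 10) == {2000}

    def test_zero_threshold_is_identity(self):
        est = estimates_frame({1960: [100, 110], 1970: [90]})
        pd.testing.assert_frame_equal(filter_decades(est, 0), est)

    def test_raising_threshold_never_adds_decades(self):
        rng = np.random.default_rng(41)
        est = estimates_frame(
            {1950 + 10 * d: [100] * int(rng.integers(1, 50)) for d in range(6)}
        )
        previous = None
        for threshold in (0, 5, 10, 20, 40, 60):
            kept = set(filter_decades(est, threshold)["year"] // 10 * 10)
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestBandwidth:
    def test_frozen_arithmetic_example(self):
        """h for {100,105,110,115,120}: sd≈7.9057, IQR/1.34≈7.4627,
        5^(-1/5)≈0.72478 → h≈4.8679 (recomputed independently)."""
        h = rule_of_thumb_bandwidth([100, 105, 110, 115, 120])
        assert h == pytest.approx(0.9 * (10 / 1.34) * 5 ** (-0.2), rel=1e-12)
        assert h == pytest.approx(4.8679, abs=1e-3)

    def test_scale_equivariance(self):
        values = [3.0, 7.0, 8.5, 12.0, 20.0]
        h = rule_of_thumb_bandwidth(values)
        assert rule_of_thumb_bandwidth([v * 3.5 for v in values]) == pytest.approx(3.5 * h)

    def test_duplication_shrinks_by_fifth_root_of_two(self):
        # heavy tails keep the IQR branch active for both sample sizes, so
        # the only change is the n**(-1/5) factor
        values = [50.0, 99.0, 100.0, 101.0, 150.0]
        h1 = rule_of_thumb_bandwidth(values)
        h2 = rule_of_thumb_bandwidth(values * 2)
        assert h2 / h1 == pytest.approx(2 ** (-0.2))

    def test_zero_iqr_falls_back_to_sd(self):
        # middle half identical, tails spread: IQR = 0 but sd > 0
        values = [0.0] + [50.0] * 8 + [100.0]
        h = rule_of_thumb_bandwidth(values)
        sd = np.std(values, ddof=1)
        assert h == pytest.approx(0.9 * sd * 10 ** (-0.2))

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            rule_of_thumb_bandwidth([1.0])
        with pytest.raises(DegenerateDataError):
            rule_of_thumb_bandwidth([5.0, 5.0, 5.0])


class TestKde:
    def test_unimodal_peak_near_cluster_center(self):
        rng = np.random.default_rng(43)
        values = rng.normal(120, 2, size=400)
        curve = kde_density(values)
        h = rule_of_thumb_bandwidth(values)
        peak = curve[np.argmax(curve[:, 1]), 0]
        assert abs(peak - 120) < h

    def test_separated_clusters_give_equal_peaks(self):
        rng = np.random.default_rng(47)
        a = rng.normal(100, 1.0, size=2000)
        b = rng.normal(200, 1.0, size=2000)
        curve = kde_density(np.concatenate([a, b]))
        x, y = curve[:, 0], curve[:, 1]
        peak_a = y[(x > 80) & (x < 120)].max()
        peak_b = y[(x > 180) & (x < 220)].max()
        assert peak_a == pytest.approx(peak_b, rel=0.01)

    def test_large_sample_matches_true_normal_density(self):
        rng = np.random.default_rng(53)
        values = rng.normal(120, 5, size=5000)
        curve = kde_density(values)
        truth = stats.norm.pdf(curve[:, 0], 120, 5)
        assert np.max(np.abs(curve[:, 1] - truth)) < 0.01

    def test_normalization(self):
        rng = np.random.default_rng(59)
        for sample in (rng.normal(120, 5, 50), rng.uniform(0, 300, 500)):
            curve = kde_density(sample)
            integral = np.trapezoid(curve[:, 1], curve[:, 0])
            assert integral == pytest.approx(1.0, abs=1e-3)


class TestDecadeSummary:
    def test_odd_median(self):
        s = decade_summary(estimates_frame({1980: [80, 90, 100]}), 0)
        assert s[0].median_doy == 90

    def test_even_median_midpoint(self):
        s = decade_summary(estimates_frame({1980: [80, 90, 100, 110]}), 0)
        assert s[0].median_doy == 95

    def test_density_attached_and_normalized(self):
        rng = np.random.default_rng(61)
        s = decade_summary(
            estimates_frame({1980: list(rng.integers(90, 150, size=200))}), 0
        )
        xy = np.array(s[0].density)
        assert np.trapezoid(xy[:, 1], xy[:, 0]) == pytest.approx(1.0, abs=1e-3)

    def test_shifting_means_recovered_in_order(self):
        """Simulated decades with increasing true means give medians in the
        same order."""
        rng = np.random.default_rng(67)
        data = {
            1960 + 10 * k: list(
                np.clip(rng.normal(100 + 5 * k, 6, size=300).round(), 1, 366).astype(int)
            )
            for k in range(4)
        }
        s = decade_summary(estimates_frame(data), 100)
        medians = [x.median_doy for x in sorted(s, key=lambda d: d.decade)]
        assert medians == sorted(medians)
        assert len(s) == 4
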