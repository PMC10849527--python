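"""Occurrence cleaning: dedupe, seasonal windows, M clipping, rarefaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from progniche.occurrence_prep import (
    AccessibleArea,
    OccurrenceSet,
    SeasonWindow,
    assign_population,
    clip_to_m,
    dedupe,
    haversine_km,
    prepare,
    rarefy,
    read_accessible_areas,
    season_filter,
    write_accessible_areas,
)


def make_set(lons, lats, taxon="t", months=None):
    df = pd.DataFrame({"lon": lons, "lat": lats})
    if months is not None:
        df["month"] = months
    return OccurrenceSet(taxon, df)


class TestDedupe:
    def test_exact_duplicates_collapse_to_one(self):
        occ = make_set([10.0, 10.0, 10.0], [5.0, 5.0, 5.0])
        assert len(dedupe(occ)) == 1

    def test_distinct_coordinates_unchanged(self):
        occ = make_set([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert len(dedupe(occ)) == 3

    def test_count_equals_unique_pairs(self, rng):
        lons = rng.choice([0.0, 1.0], size=10)
        lats = rng.choice([0.0, 1.0], size=10)
        occ = make_set(lons, lats)
        expected = len({(x, y) for x, y in zip(lons, lats)})
        assert len(dedupe(occ)) == expected

    def test_first_seen_record_retained(self):
        df = pd.DataFrame({"lon": [1.0, 1.0], "lat": [2.0, 2.0],
                           "source_id": ["first", "second"]})
        out = dedupe(OccurrenceSet("t", df))
        assert out.records["source_id"].tolist() == ["first"]

    def test_empty_input_warns(self):
        occ = make_set([], [])
        with pytest.warns(UserWarning):
            out = dedupe(occ)
        assert len(out) == 0


class TestSeasonFilter:
    def test_northern_may_kept(self):
        occ = make_set([0.0], [45.0], months=[5])
        assert len(season_filter(occ, SeasonWindow.northern())) == 1

    def test_southern_december_kept(self):
        occ = make_set([0.0], [-30.0], months=[12])
        assert len(season_filter(occ, SeasonWindow.southern())) == 1

    def test_northern_september_removed(self):
        occ = make_set([0.0], [45.0], months=[9])
        assert len(season_filter(occ, SeasonWindow.northern())) == 0

    def test_hemisphere_rule_from_latitude(self):
        north = make_set([0.0, 0.0], [40.0, 50.0], months=[5, 11])
        south = make_set([0.0, 0.0], [-40.0, -50.0], months=[5, 11])
        assert season_filter(north).records["month"].tolist() == [5]
        assert season_filter(south).records["month"].tolist() == [11]

    def test_undated_records_follow_flag(self):
        occ = make_set([0.0, 0.0], [45.0, 45.0], months=[5, None])
        assert len(season_filter(occ, drop_undated=True)) == 1
        assert len(season_filter(occ, drop_undated=False)) == 2


class TestClipToM:
    square = AccessibleArea("t", (box(0.0, 0.0, 10.0, 10.0),))

    def test_interior_point_kept(self):
        kept, out = clip_to_m(make_set([5.0], [5.0]), self.square)
        assert len(kept) == 1 and len(out) == 0

    def test_boundary_point_kept(self):
        kept, _ = clip_to_m(make_set([0.0], [5.0]), self.square)
        assert len(kept) == 1

    def test_no_record_lost(self, rng):
        occ = make_set(rng.uniform(-5, 15, 50), rng.uniform(-5, 15, 50))
        kept, out = clip_to_m(occ, self.square)
        assert len(kept) + len(out) == len(occ)
        merged = pd.concat([kept.records, out.records])[["lon", "lat"]]
        recovered = merged.sort_values(["lon", "lat"]).reset_index(drop=True)
        original = occ.records[["lon", "lat"]].sort_values(["lon", "lat"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(recovered, original)

    def test_simulated_vagrant_fraction_removed(self, sim_dataset):
        # generator adds ~5% out-of-M vagrants; the clip removes about that many
        ds = sim_dataset
        taxon = "sp1"
        occ = ds.occurrences[taxon]
        kept, out = clip_to_m(occ, ds.areas[taxon])
        n_vagrant = occ.provenance[0]["n_vagrant"]
        assert len(out) == n_vagrant
        assert len(kept) == len(occ) - n_vagrant


class TestRarefy:
    def test_two_close_points_one_kept(self):
        # ~10 km apart along a meridian (1 deg lat ~ 111 km)
        occ = make_set([0.0, 0.0], [0.0, 0.09])
        assert len(rarefy(occ, 20.0)) == 1

    def test_two_distant_points_both_kept(self):
        occ = make_set([0.0, 0.0], [0.0, 0.225])  # ~25 km
        assert len(rarefy(occ, 20.0)) == 2

    def test_grid_matches_bruteforce_greedy(self):
        # 5x5 grid with ~10 km spacing at the equator
        step = 0.09
        lons, lats = np.meshgrid(np.arange(5) * step, np.arange(5) * step)
        occ = make_set(lons.ravel(), lats.ravel())
        out = rarefy(occ, 20.0)
        # independent greedy pass over the same canonical order
        df = occ.records.sort_values(["lon", "lat"], kind="mergesort")
        kept = []
        for _, row in df.iterrows():
            if all(haversine_km(row.lon, row.lat, k[0], k[1]) >= 20.0 for k in kept):
                kept.append((row.lon, row.lat))
        assert len(out) == len(kept)
        got = set(zip(out.records["lon"], out.records["lat"]))
        assert got == set(kept)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
                    min_size=1, max_size=40))
    def test_pairwise_property_and_idempotence(self, pts):
        occ = make_set([p[0] for p in pts], [p[1] for p in pts])
        out = rarefy(occ, 20.0)
        lon = out.records["lon"].to_numpy()
        lat = out.records["lat"].to_numpy()
        for i in range(len(out)):
            d = haversine_km(lon[i], lat[i], np.delete(lon, i), np.delete(lat, i))
            assert np.all(d >= 20.0)
        again = rarefy(out, 20.0)
        assert len(again) == len(out)
        assert again.records[["lon", "lat"]].reset_index(drop=True).equals(
            out.records[["lon", "lat"]].reset_index(drop=True))

    def test_min_km_must_be_positive(self):
        with pytest.raises(ValueError):
            rarefy(make_set([0.0], [0.0]), 0.0)


class TestAssignPopulation:
    ms = [AccessibleArea("west", (box(0, 0, 10, 10),)),
          AccessibleArea("east", (box(10, 0, 20, 10),))]

    def test_point_in_one_m(self):
        pops, un = assign_population(make_set([5.0], [5.0]), self.ms)
        assert len(pops["west"]) == 1 and len(pops["east"]) == 0 and len(un) == 0

    def test_point_in_no_m_unassigned(self):
        pops, un = assign_population(make_set([50.0], [5.0]), self.ms)
        assert len(un) == 1

    def test_overlapping_interiors_raise(self):
        bad = [AccessibleArea("a", (box(0, 0, 10, 10),)),
               AccessibleArea("b", (box(5, 5, 15, 15),))]
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            assign_population(make_set([7.0], [7.0]), bad)

    def test_five_population_layout_matches_pip_oracle(self, rng):
        ms = [AccessibleArea(f"p{i}", (box(10 * i, 0, 10 * i + 10, 10),)) for i in range(5)]
        lons = rng.uniform(-5, 55, 200)
        lats = rng.uniform(-5, 15, 200)
        pops, un = assign_population(make_set(lons, lats), ms)
        polys = [Polygon([(10 * i, 0), (10 * i + 10, 0), (10 * i + 10, 10), (10 * i, 10)])
                 for i in range(5)]
        for i, m in enumerate(ms):
            got = set(zip(pops[m.taxon].records["lon"], pops[m.taxon].records["lat"]))
            from shapely.geometry import Point
            expect = set()
            for x, y in zip(lons, lats):
                hits = [j for j, p in enumerate(polys)
                        if p.covers(Point(x, y))]
                if hits and hits[0] == i:
                    expect.add((x, y))
            assert got == expect


class TestProvenanceChain:
    def test_counts_non_increasing_and_reproducible(self, sim_dataset):
        ds = sim_dataset
        occ = ds.occurrences["sp2"]
        cleaned, _ = prepare(occ, ds.areas["sp2"])
        counts = [step["n_out"] for step in cleaned.provenance if step["step"] != "clip_to_m_outliers"]
        filter_counts = counts[1:]  # first entry is the simulation step
        assert all(b <= a for a, b in zip(filter_counts, filter_counts[1:]))
        cleaned2, _ = prepare(occ, ds.areas["sp2"])
        assert cleaned.provenance == cleaned2.provenance


def test_accessible_area_geojson_roundtrip(tmp_path, sim_dataset):
    areas = [sim_dataset.areas[t] for t in sorted(sim_dataset.areas)]
    path = tmp_path / "ms.geojson"
    write_accessible_areas(areas, path)
    back = read_accessible_areas(path)
    assert [a.taxon for a in back] == [a.taxon for a in areas]
    for a, b in zip(areas, back):
        assert a.geometry.equals(b.geometry)


def test_invalid_polygon_rejected():
    bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
    with pytest.raises(ValueError, match="invalid"):
        AccessibleArea("t", (bowtie,))


def test_coordinate_range_validation():
    with pytest.raises(ValueError):
        make_set([200.0], [0.0])
    with pytest.raises(ValueError):
        make_set([0.0], [95.0])
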