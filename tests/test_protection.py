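"""MPA categorisation, spatial intersection and protection accounting."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from oracles import brute_force_intersection

from kelpmhw.geo import spherical_area_ha
from kelpmhw.protection import (
    KelpFeature,
    MPAFeature,
    categorize_lfp,
    coastline_buffer_filter,
    feature_category_areas,
    hierarchical_intersection,
    prefilter_overlaps,
    protection_summary,
    resolve_overlaps,
    threat_vs_protection,
)
from kelpmhw.synthetic import GeometrySimConfig, simulate_geometries


def kelp_square(fid="k0", lon=-120.5, lat=35.0, size_deg=0.001, **attrs):
    attrs.setdefault("country", "country0")
    attrs.setdefault("realm", "realm0")
    attrs.setdefault("ecoregion", "eco0")
    geom = box(lon, lat, lon + size_deg, lat + size_deg)
    return KelpFeature(feature_id=fid, geometry=geom,
                       area_ha=spherical_area_ha(geom), **attrs)


def mpa(mid="m0", lon=-121.0, lat=34.5, w=1.0, h=1.0, score=5, country="country0"):
    return MPAFeature(mpa_id=mid, geometry=box(lon, lat, lon + w, lat + h),
                      lfp_score=score, category=categorize_lfp(score), country=country)


class TestLFP:
    @pytest.mark.parametrize("score,category", [
        (1, "less"), (2, "less"), (3, "moderate"), (4, "high"), (5, "high"),
    ])
    def test_score_mapping(self, score, category):
        assert categorize_lfp(score) == category

    @pytest.mark.parametrize("score", [0, 6, -1, 2.5, None])
    def test_out_of_range_rejected(self, score):
        with pytest.raises((ValueError, TypeError)):
            categorize_lfp(score)

    def test_inconsistent_category_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MPAFeature("m", box(0, 0, 1, 1), lfp_score=5, category="less", country="c")


class TestCoastlineBuffer:
    coast = LineString([(-120.5, 34.0), (-120.5, 36.0)])

    def test_offshore_feature_kept(self):
        f = kelp_square(lon=-120.51, source="global")  # ~1 km offshore
        kept, excluded = coastline_buffer_filter([f], self.coast)
        assert kept == [f] and excluded == []

    def test_feature_on_coastline_excluded(self):
        f = kelp_square(lon=-120.5005, source="global")
        kept, excluded = coastline_buffer_filter([f], self.coast, buffer_m=100)
        assert kept == [] and excluded == [f]

    def test_zero_buffer_excludes_only_touching(self):
        touching = kelp_square("k1", lon=-120.5005, source="global")
        near = kelp_square("k2", lon=-120.5015, source="global")
        kept, excluded = coastline_buffer_filter([touching, near], self.coast, buffer_m=0)
        assert [f.feature_id for f in excluded] == ["k1"]
        assert [f.feature_id for f in kept] == ["k2"]

    def test_landsat_features_exempt(self):
        f = kelp_square(lon=-120.5005, source="landsat")
        kept, excluded = coastline_buffer_filter([f], self.coast, buffer_m=100)
        assert kept == [f]

    def test_missing_coastline_with_global_features_rejected(self):
        f = kelp_square(source="global")
        with pytest.raises(ValueError, match="coastline"):
            coastline_buffer_filter([f], None)


class TestPrefilter:
    def test_disjoint_layers_all_unprotected(self):
        kelp = [kelp_square(f"k{i}", lon=-120.0 + 0.01 * i) for i in range(5)]
        mpas = [mpa(lon=-130.0)]
        cand, unprot, live = prefilter_overlaps(kelp, mpas)
        assert cand == [] and len(unprot) == 5 and live == []

    def test_all_inside_one_mpa(self):
        kelp = [kelp_square(f"k{i}", lon=-120.9 + 0.01 * i) for i in range(5)]
        mpas = [mpa(lon=-121.0, lat=34.5, w=1.0, h=1.0)]
        cand, unprot, live = prefilter_overlaps(kelp, mpas)
        assert len(cand) == 5 and unprot == [] and len(live) == 1

    def test_bbox_hit_without_true_overlap_is_allowed_candidate(self):
        # an L-shaped MPA whose bbox covers the kelp but whose geometry
        # does not: conservative prefilter keeps it as a candidate
        from shapely.geometry import Polygon

        ell = Polygon([(0, 0), (3, 0), (3, 1), (1, 1), (1, 3), (0, 3)])
        m = MPAFeature("mL", ell, lfp_score=4, category="high", country="country0")
        k = kelp_square("k0", lon=2.0, lat=2.0, size_deg=0.5)
        cand, unprot, _ = prefilter_overlaps([k], [m])
        assert cand == [k]
        records = hierarchical_intersection([k], [m])
        assert [r for r in records if r.mpa_id != "none"] == []


class TestHierarchicalIntersection:
    def test_kelp_wholly_inside_high_mpa(self):
        k = kelp_square()
        records = hierarchical_intersection([k], [mpa(score=5)])
        (rec,) = [r for r in records if r.mpa_id != "none"]
        assert rec.category == "high"
        assert rec.area_ha == pytest.approx(k.area_ha, rel=1e-9)

    def test_half_covered_square_matches_analytic_area(self):
        k = kelp_square(size_deg=0.001)
        half = mpa(lon=-121.0, lat=35.0, w=0.5 + 0.0005, h=1.0)  # covers west half
        records = hierarchical_intersection([k], [half])
        (rec,) = [r for r in records if r.mpa_id != "none"]
        assert rec.area_ha == pytest.approx(k.area_ha / 2, rel=1e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_all_pairs(self, seed):
        layers = simulate_geometries(
            GeometrySimConfig(seed=seed, n_kelp_pixels=80, n_mpas=10,
                              n_countries=2, n_ecoregions=4)
        )
        records = hierarchical_intersection(layers["kelp"], layers["mpas"])
        got = {(r.feature_id, r.mpa_id): r.area_ha for r in records}
        want = {(f, m): a for f, m, a in
                brute_force_intersection(layers["kelp"], layers["mpas"])}
        assert set(got) == set(want)
        for key, area in want.items():
            assert got[key] == pytest.approx(area, abs=1e-6)

    def test_parallel_equals_sequential(self):
        layers = simulate_geometries(
            GeometrySimConfig(seed=9, n_kelp_pixels=60, n_mpas=8, n_countries=3,
                              n_ecoregions=6)
        )
        par = hierarchical_intersection(layers["kelp"], layers["mpas"], parallel=True)
        seq = hierarchical_intersection(layers["kelp"], layers["mpas"], parallel=False)
        assert [(r.feature_id, r.mpa_id, r.area_ha) for r in par] == [
            (r.feature_id, r.mpa_id, r.area_ha) for r in seq
        ]

    def test_prefilter_soundness_no_false_not_protected(self):
        layers = simulate_geometries(
            GeometrySimConfig(seed=13, n_kelp_pixels=100, n_mpas=12)
        )
        records = hierarchical_intersection(layers["kelp"], layers["mpas"])
        unprotected = {r.feature_id for r in records if r.mpa_id == "none"}
        truly_hit = {f for f, m, a in
                     brute_force_intersection(layers["kelp"], layers["mpas"])
                     if m != "none" and a > 0}
        assert unprotected.isdisjoint(truly_hit)


class TestResolveOverlaps:
    def test_double_coverage_counts_highest_only(self):
        k = kelp_square()
        records = hierarchical_intersection([k], [mpa("m5", score=5), mpa("m2", score=2)])
        areas = resolve_overlaps(records, k)
        assert areas["high"] == pytest.approx(k.area_ha, rel=1e-9)
        assert areas["less"] == 0.0

    def test_disjoint_mpas_add(self):
        k = kelp_square(size_deg=0.001)
        west = mpa("mw", lon=-121.0, lat=34.5, w=0.5 + 0.0004, h=1.0, score=5)
        east = mpa("me", lon=-120.4996 + 0.0001, lat=34.5, w=0.5, h=1.0, score=5)
        records = hierarchical_intersection([k], [west, east])
        areas = resolve_overlaps(records, k)
        got = areas["high"]
        west_part = k.geometry.intersection(west.geometry)
        east_part = k.geometry.intersection(east.geometry)
        assert got == pytest.approx(
            spherical_area_ha(west_part) + spherical_area_ha(east_part), rel=1e-6
        )

    def test_nested_same_category_no_double_count(self):
        k = kelp_square()
        outer = mpa("mo", score=4)
        inner = MPAFeature("mi", k.geometry.buffer(-0.0002), lfp_score=5,
                           category="high", country="country0")
        records = hierarchical_intersection([k], [outer, inner])
        areas = resolve_overlaps(records, k)
        assert areas["high"] == pytest.approx(k.area_ha, rel=1e-9)  # union, not sum


class TestProtectionSummary:
    def summary_for(self, layers, **kwargs):
        records = hierarchical_intersection(layers["kelp"], layers["mpas"])
        areas = feature_category_areas(records, layers["kelp"])
        return areas, protection_summary(areas, **kwargs)

    def test_area_conservation_per_region(self):
        layers = simulate_geometries(GeometrySimConfig(seed=21, n_kelp_pixels=80, n_mpas=10))
        _, summary = self.summary_for(layers)
        parts = summary[["ha_high", "ha_moderate", "ha_less", "ha_unprotected"]].sum(axis=1)
        assert np.allclose(parts, summary["total_kelp_ha"], rtol=1e-6)
        pct = summary[["pct_high", "pct_moderate", "pct_less", "pct_unprotected"]].sum(axis=1)
        assert np.allclose(pct, 100.0, atol=1e-6)

    def test_hierarchy_consistency(self):
        layers = simulate_geometries(
            GeometrySimConfig(seed=22, n_kelp_pixels=60, n_mpas=8, n_countries=3,
                              n_ecoregions=6)
        )
        _, summary = self.summary_for(layers)
        g = summary[summary.region_level == "global"]["total_kelp_ha"].sum()
        for level in ("country", "realm", "ecoregion"):
            lv = summary[summary.region_level == level]["total_kelp_ha"].sum()
            assert lv == pytest.approx(g, rel=1e-9)

    def test_no_mpas_everything_unprotected(self):
        layers = simulate_geometries(GeometrySimConfig(seed=23, n_kelp_pixels=30, n_mpas=0))
        _, summary = self.summary_for(layers)
        row = summary[summary.region_level == "global"].iloc[0]
        assert row["pct_unprotected"] == pytest.approx(100.0)
        assert not row["meets_10"]

    def test_domain_wide_high_mpa_protects_everything(self):
        cfg = GeometrySimConfig(seed=24, n_kelp_pixels=30, n_mpas=0)
        layers = simulate_geometries(cfg)
        whole = MPAFeature("big", box(*cfg.bbox), lfp_score=5, category="high",
                           country="country0")
        layers["mpas"] = [whole]
        _, summary = self.summary_for(layers)
        row = summary[summary.region_level == "global"].iloc[0]
        assert row["pct_high"] == pytest.approx(100.0)
        assert row["meets_10"] and row["meets_30"]

    def test_quarter_protected_meets_only_10(self):
        areas = pd.DataFrame(
            {"feature_id": ["f"] * 4, "country": "c", "realm": "r",
             "ecoregion": "e",
             "category": ["high", "moderate", "less", "not protected"],
             "area_ha": [25.0, 0.0, 0.0, 75.0]}
        )
        summary = protection_summary(areas, levels=("global",))
        row = summary.iloc[0]
        assert row["pct_high"] == 25.0 and row["meets_10"] and not row["meets_30"]

    def test_combined_effective_categories(self):
        areas = pd.DataFrame(
            {"feature_id": ["f"] * 4, "country": "c", "realm": "r",
             "ecoregion": "e",
             "category": ["high", "moderate", "less", "not protected"],
             "area_ha": [20.0, 15.0, 0.0, 65.0]}
        )
        only_high = protection_summary(areas, levels=("global",)).iloc[0]
        combined = protection_summary(
            areas, levels=("global",), effective_categories=("high", "moderate")
        ).iloc[0]
        assert not only_high["meets_30"] and combined["meets_30"]

    def test_enlarging_mpa_never_lowers_its_tier(self):
        layers = simulate_geometries(GeometrySimConfig(seed=25, n_kelp_pixels=50, n_mpas=5))
        _, before = self.summary_for(layers)
        grown = layers["mpas"][0]
        grown.geometry = grown.geometry.buffer(0.2)
        _, after = self.summary_for(layers)
        col = f"pct_{grown.category}"
        b = before[before.region_level == "global"].iloc[0][col]
        a = after[after.region_level == "global"].iloc[0][col]
        assert a >= b - 1e-9


class TestThreatVsProtection:
    def exposure(self, rows):
        return pd.DataFrame(
            [{"region_id": r, "region_level": "ecoregion", "scenario": "SSP2-4.5",
              "period": "mid", "mean": v, "p5": v, "p95": v, "n_pixels": 3}
             for r, v in rows]
        )

    def protection(self, rows):
        return pd.DataFrame(
            [{"region_id": r, "region_level": "ecoregion", "pct_high": h,
              "pct_high_moderate": hm, "total_kelp_ha": 10.0}
             for r, h, hm in rows]
        )

    def test_most_threatened_least_protected_sorts_first(self):
        out = threat_vs_protection(
            self.exposure([("a", 50.0), ("b", 10.0)]),
            self.protection([("a", 0.0, 0.0), ("b", 40.0, 60.0)]),
        )
        assert out.iloc[0]["region_id"] == "a"

    def test_refugium_flag(self):
        out = threat_vs_protection(
            self.exposure([("a", 50.0), ("b", 10.0), ("c", 30.0)]),
            self.protection([("a", 0.0, 0.0), ("b", 40.0, 60.0), ("c", 5.0, 10.0)]),
        )
        flags = out.set_index("region_id")["refugium_candidate"]
        assert bool(flags["b"]) and not bool(flags["a"])

    def test_one_sided_regions_get_missing_markers(self):
        out = threat_vs_protection(
            self.exposure([("a", 50.0)]), self.protection([("b", 40.0, 60.0)])
        )
        assert out.set_index("region_id").loc["b", "mhw_exposure"] != out.set_index(
            "region_id"
        ).loc["b", "mhw_exposure"]  # NaN
        assert len(out) == 2

    def test_empty_protection_input_no_crash(self):
        out = threat_vs_protection(self.exposure([("a", 50.0)]),
                                   self.protection([]))
        assert len(out) == 1 and np.isnan(out.iloc[0]["pct_high"])
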