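"""Islet composition, densities, infiltration, insulitis, cohort aggregation."""

import numpy as np
import pandas as pd
import pytest
import shapely.geometry as sgeom
from hypothesis import given
from hypothesis import strategies as st

from isletpath.islets import IsletObject
from isletpath.published import slide_characterization_table
from isletpath.quantify import (aggregate_slides,
                                compute_density, infiltration_stats,
                                islet_composition, pi_ins_ratio,
                                population_sd, score_insulitis)


def islet_with_cells(labels: list[dict], area_um2=5000.0):
    cells = pd.DataFrame([{"cell_id": i, **lab}
                          for i, lab in enumerate(labels)])
    islet = IsletObject(id=0, polygon=sgeom.Point(0, 0).buffer(
        np.sqrt(area_um2 / np.pi), quad_segs=64))
    islet.cell_ids = list(range(len(labels)))
    return islet, cells


class TestComposition:
    def test_seven_of_ten_beta_is_seventy_percent(self):
        labels = [{"beta": i < 7, "alpha": False} for i in range(10)]
        islet, cells = islet_with_cells(labels)
        comp = islet_composition(islet, cells)
        assert comp.pct("beta") == 70.0

    def test_zero_alpha_allows_hundred_percent_beta(self):
        labels = [{"beta": True, "GCG+": False} for _ in range(12)]
        islet, cells = islet_with_cells(labels)
        comp = islet_composition(islet, cells)
        assert comp.pct("GCG+") == 0.0
        assert comp.pct("beta") == 100.0

    def test_per_lineage_enzyme_percentage(self):
        labels = ([{"beta": True, "alpha": False, "PC2+": True}] * 3
                  + [{"beta": True, "alpha": False, "PC2+": False}] * 1
                  + [{"beta": False, "alpha": True, "PC2+": True}] * 6)
        islet, cells = islet_with_cells(labels)
        comp = islet_composition(islet, cells)
        assert comp.pct_of("PC2+|beta", "beta") == 75.0
        assert comp.pct_of("PC2+|alpha", "alpha") == 100.0

    def test_cohort_beta_percent_tracks_generator_fraction(self, small_run):
        _, gt, result, oracle = small_run
        n = oracle.n_islet_cells
        se = 100 * np.sqrt(0.65 * 0.35 / n)
        assert abs(oracle.pct_beta - 65.0) <= 3 * se


class TestPiInsRatio:
    def test_equal_counts_give_ratio_one(self):
        islet, cells = islet_with_cells(
            [{"INS+": True, "PI+": True}] * 40)
        assert pi_ins_ratio(islet_composition(islet, cells)) == 1.0

    def test_zero_ins_is_undefined(self):
        islet, cells = islet_with_cells([{"INS+": False, "PI+": True}] * 10)
        assert pi_ins_ratio(islet_composition(islet, cells)) is None

    def test_median_over_islets_matches_sort_oracle(self, rng):
        ratios = rng.uniform(0.5, 1.5, 31)
        srt = np.sort(ratios)
        assert np.median(ratios) == srt[15]


class TestDensity:
    def test_published_cd3_density(self):
        assert round(compute_density(8643, 75.0), 1) == 115.2

    def test_published_cd8_density(self):
        assert round(compute_density(3911, 75.0), 1) == 52.1

    def test_zero_cells_zero_density(self):
        assert compute_density(0, 12.0) == 0.0

    def test_zero_area_undefined(self):
        assert np.isnan(compute_density(5, 0.0))


class TestInfiltration:
    @staticmethod
    def records(distances, islet_ids):
        return pd.DataFrame({"cell_id": np.arange(len(distances)),
                             "distance_um": distances,
                             "nearest_islet_id": islet_ids})

    @staticmethod
    def islets(n):
        return [IsletObject(id=i, polygon=sgeom.Point(i * 500, 0).buffer(50))
                for i in range(n)]

    def test_four_of_241_is_1_7_percent(self):
        rec = self.records([0.0, 3.0, 0.0, 10.0, 400.0], [0, 1, 2, 3, 4])
        n_inf, pct, _ = infiltration_stats(self.islets(241), rec, 15.0)
        assert n_inf == 4
        assert round(pct, 1) == 1.7

    def test_no_immune_cells_no_infiltration(self):
        rec = self.records([], [])
        n_inf, pct, counts = infiltration_stats(self.islets(10), rec)
        assert n_inf == 0 and pct == 0.0
        assert counts["endocrine_strict"] == 0

    def test_matches_brute_force_double_loop(self, rng):
        islets = self.islets(8)
        pts = rng.uniform(-200, 3800, size=(150, 2))
        from isletpath.spatial import distance_to_islets
        cells = pd.DataFrame({"cell_id": np.arange(150),
                              "centroid_x_um": pts[:, 0],
                              "centroid_y_um": pts[:, 1]})
        rec = distance_to_islets(cells, islets)
        n_inf, _, _ = infiltration_stats(islets, rec, 15.0)
        hit = set()                               # enumeration oracle
        for islet in islets:
            for x, y in pts:
                if islet.polygon.distance(sgeom.Point(x, y)) <= 15.0:
                    hit.add(islet.id)
        # nearest-islet attribution can only differ for cells adjacent to two
        # islets at once; islets here are 400 µm apart, so the sets agree
        assert n_inf == len(hit)


def donor_islet_stats(n=241, max_cd45=18, pseudoatrophic=False):
    """Per-islet profile shaped like a healthy donor: sparse CD45, INS present."""
    rng = np.random.default_rng(0)
    cd45 = np.zeros(n)
    cd45[:6] = rng.integers(1, max_cd45 // 3, size=6)
    cd45[0] = max_cd45 // 2
    stats = pd.DataFrame({
        "islet_id": np.arange(n),
        "equivalent_diameter_um": rng.uniform(60, 260, n),
        "n_cells": rng.integers(10, 200, n),
        "cd45_count": cd45,
        "cd3_count": np.zeros(n),
        "n_INS": rng.integers(5, 100, n),
    })
    if pseudoatrophic:
        stats.loc[0, "n_INS"] = 0
    return stats


class TestInsulitis:
    def test_healthy_donor_profile_is_negative(self):
        # at most 18 CD45+ cells spread over all islets, no insulin-deficient
        # islets: no insulitis under the consensus definition
        verdict = score_insulitis(donor_islet_stats())
        assert verdict["assessable"]
        assert verdict["insulitis"] is False
        assert verdict["pseudoatrophic_islet_ids"] == []

    def test_constructed_positive_case(self):
        stats = donor_islet_stats(pseudoatrophic=True)
        stats.loc[1:3, "cd3_count"] = 6
        stats.loc[1:3, "equivalent_diameter_um"] = 180.0
        verdict = score_insulitis(stats)
        assert verdict["insulitis"] is True
        assert len(verdict["qualifying_islet_ids"]) >= 3

    def test_two_qualifying_islets_is_negative(self):
        stats = donor_islet_stats(pseudoatrophic=True)
        stats.loc[1:2, "cd3_count"] = 10
        stats.loc[1:2, "equivalent_diameter_um"] = 180.0
        assert score_insulitis(stats)["insulitis"] is False

    def test_small_islets_do_not_qualify(self):
        stats = donor_islet_stats(pseudoatrophic=True)
        stats.loc[1:3, "cd3_count"] = 10
        stats.loc[1:3, "equivalent_diameter_um"] = 100.0   # under 150 µm
        assert score_insulitis(stats)["insulitis"] is False

    def test_missing_markers_not_assessable(self):
        stats = donor_islet_stats().drop(columns=["cd45_count", "cd3_count"])
        verdict = score_insulitis(stats)
        assert verdict["insulitis"] is None
        assert not verdict["assessable"]


class TestAggregation:
    def test_six_section_means_match_published_row(self):
        agg = aggregate_slides(slide_characterization_table())
        assert round(agg.loc["mean", "tissue_area_mm2"], 1) == 89.3
        assert round(agg.loc["mean", "n_islet_cells"], 1) == 15611.5
        # NA exclusion: slide #6 has no beta count
        assert round(agg.loc["mean", "n_beta"], 1) == 11090.6
        assert round(agg.loc["mean", "n_alpha"], 1) == 4822.2

    def test_population_sd_matches_published_not_sample_sd(self):
        islets = slide_characterization_table()["n_islets"].to_numpy()
        assert round(population_sd(islets), 1) == 67.6
        assert round(float(np.std(islets, ddof=1)), 1) != 67.6

    def test_constant_column_sd_zero(self):
        agg = aggregate_slides(pd.DataFrame({"a": [3.0, 3.0, 3.0]}))
        assert agg.loc["sd", "a"] == 0.0

    def test_all_null_column_stays_na(self):
        agg = aggregate_slides(pd.DataFrame({"a": [1.0, 2.0],
                                             "b": [np.nan, np.nan]}))
        assert np.isnan(agg.loc["mean", "b"])

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False), min_size=1, max_size=30))
    def test_mean_and_sd_match_numpy(self, vals):
        agg = aggregate_slides(pd.DataFrame({"x": vals}))
        assert agg.loc["mean", "x"] == pytest.approx(np.mean(vals), rel=1e-9,
                                                     abs=1e-9)
        assert agg.loc["sd", "x"] == pytest.approx(np.std(vals, ddof=0),
                                                   rel=1e-9, abs=1e-9)
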