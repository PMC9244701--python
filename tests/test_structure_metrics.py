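"""DBH classes, age grades, density, canopy cover and population fits."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from standpattern.stand_model import TreeRecord, Window
from standpattern.structure_metrics import (
    FitError,
    GRADES,
    assign_age_grade,
    assign_dbh_class,
    classify_population_trend,
    crown_projection_area,
    dbh_class_histogram,
    fit_population_model,
    stand_density_index,
    stand_summary,
)


def _tree(x, y, cd, dbh=20.0, th=8.0, tid=None):
    return TreeRecord(tree_id=tid or f"t{x}_{y}", x=x, y=y, th=th, dbh=dbh, cd=cd)


class TestClassification:
    @pytest.mark.parametrize(
        "dbh,expected",
        [(4.0, 1), (4.1, 2), (0.5, 1), (80.0, 20), (80.1, 21), (85.0, 21), (300.0, 21)],
    )
    def test_class_boundaries_closed_right(self, dbh, expected):
        assert assign_dbh_class(dbh) == expected

    @pytest.mark.parametrize(
        "dbh,expected",
        [(15.0, "young"), (15.1, "near_mature"), (30.0, "near_mature"),
         (30.1, "mature"), (50.0, "mature"), (50.1, "old"), (1.1, "young")],
    )
    def test_grade_boundaries_closed_right(self, dbh, expected):
        assert assign_age_grade(dbh) == expected

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_dbh_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_dbh_class(bad)

    def test_grade_floor_rejected(self):
        with pytest.raises(ValueError):
            assign_age_grade(1.0)

    def test_partition_on_fine_grid(self):
        """Every DBH > 1 maps to exactly one class and one grade; the
        class->grade map is consistent along the whole 0.1-cm grid."""
        grid = np.round(np.arange(1.1, 100.01, 0.1), 10)
        for dbh in grid:
            k = assign_dbh_class(float(dbh))
            g = assign_age_grade(float(dbh))
            assert 1 <= k <= 21
            # classes 1-3 lie entirely inside the young grade
            if k <= 3:
                assert g == "young"
            if k >= 14:
                assert g == "old"


class TestSdi:
    @pytest.mark.parametrize(
        "n,area,expected", [(681, 1.5, 454), (573, 1.5, 382), (394, 1.5, 263), (0, 1.5, 0)]
    )
    def test_rounded_values(self, n, area, expected):
        assert round(stand_density_index(n, area)) == expected

    @given(st.integers(min_value=0, max_value=10_000), st.floats(0.01, 100))
    def test_linearity_before_rounding(self, n, area):
        assert stand_density_index(2 * n, area) == pytest.approx(
            2 * stand_density_index(n, area)
        )

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            stand_density_index(10, 0.0)


class TestCpa:
    def test_no_trees_zero(self, window50):
        assert crown_projection_area([], window50) == 0.0

    def test_single_crown_covering_window_saturates(self, window50):
        t = _tree(25.0, 25.0, cd=160.0)  # radius 80 m covers the 50 m plot
        assert crown_projection_area([t], window50) == pytest.approx(100.0)

    def test_overlapping_duplicate_crowns_not_double_counted(self, window50):
        t1 = _tree(25.0, 25.0, cd=10.0, tid="a")
        t2 = _tree(25.0, 25.0, cd=10.0, tid="b")
        one = crown_projection_area([t1], window50)
        two = crown_projection_area([t1, t2], window50)
        assert two == pytest.approx(one)
        # interior disc of radius 5: pi 25 / 2500 = 3.1416%
        assert one == pytest.approx(100 * math.pi * 25 / 2500, abs=0.05)

    def test_enlarging_a_crown_never_decreases_cpa(self, window50, rng):
        trees = [
            _tree(float(x), float(y), cd=float(c), tid=str(i))
            for i, (x, y, c) in enumerate(
                zip(rng.uniform(0, 50, 15), rng.uniform(0, 50, 15), rng.uniform(1, 8, 15))
            )
        ]
        base = crown_projection_area(trees, window50)
        grown = list(trees)
        grown[4] = TreeRecord(tree_id="g", x=trees[4].x, y=trees[4].y,
                              th=trees[4].th, dbh=trees[4].dbh, cd=trees[4].cd + 3.0)
        assert crown_projection_area(grown, window50) >= base

    def test_monte_carlo_oracle_agreement(self, window50):
        """Rasterised union area agrees with uniform point sampling within
        0.5 percentage points over random synthetic plots."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = int(r.integers(5, 25))
            trees = [
                _tree(float(x), float(y), cd=float(c), tid=str(i))
                for i, (x, y, c) in enumerate(
                    zip(r.uniform(0, 50, n), r.uniform(0, 50, n), r.uniform(0.5, 10, n))
                )
            ]
            cpa = crown_projection_area(trees, window50)
            pts = r.uniform(0, 50, size=(200_000, 2))
            centres = np.array([[t.x, t.y] for t in trees])
            radii = np.array([t.cd / 2 for t in trees])
            d2 = ((pts[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
            covered = (d2 <= radii[None, :] ** 2).any(1)
            mc = 100.0 * covered.mean()
            assert abs(cpa - mc) < 0.5, f"seed {seed}: raster {cpa} vs MC {mc}"

    def test_cell_larger_than_window_rejected(self, window50):
        with pytest.raises(ValueError):
            crown_projection_area([_tree(1, 1, 2.0)], window50, cell=60.0)


class TestHistogram:
    def test_small_example(self):
        counts, grades = dbh_class_histogram([10.0, 10.0, 40.0])
        assert counts[2] == 2 and counts[9] == 1 and counts.sum() == 3
        assert grades == {"young": 2, "near_mature": 0, "mature": 1, "old": 0}

    def test_empty_all_zero(self):
        counts, grades = dbh_class_histogram([])
        assert counts.sum() == 0 and all(v == 0 for v in grades.values())

    def test_grade_percentages_from_printed_counts(self):
        # 197 young of 681 -> 29%, 34 old of 681 -> 5%
        assert round(100 * 197 / 681) == 29
        dbhs = [10.0] * 197 + [20.0] * 450 + [60.0] * 34
        _, grades = dbh_class_histogram(dbhs)
        assert round(100 * grades["young"] / len(dbhs)) == 29
        assert round(100 * grades["old"] / len(dbhs)) == 5

    def test_counts_and_grades_consistent(self, default_study):
        for plot in default_study:
            counts, grades = dbh_class_histogram(plot.trees)
            assert counts.sum() == plot.n == sum(grades.values())


class TestPopulationFit:
    def test_exact_gaussian_recovered(self):
        k = np.arange(1, 22)
        counts = 120 * np.exp(-((k - 6.0) ** 2) / (2 * 2.5**2))
        fit = fit_population_model(counts)
        assert fit.model == "gaussian"
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
        a, mu, sigma = fit.parameters
        assert mu == pytest.approx(6.0, abs=1e-3)
        assert sigma == pytest.approx(2.5, abs=1e-3)

    def test_reversed_j_counts_select_logistic(self):
        """Counts generated from the decreasing-logistic form with seeded
        noise select the logistic in at least 95% of 200 replicates."""
        k = np.arange(1, 22)
        truth = 150.0 / (1 + np.exp(1.2 * (k - 9.0)))
        wins = 0
        for rep in range(200):
            r = np.random.default_rng(rep)
            noisy = np.clip(truth + r.normal(0, 0.05 * truth.max(), len(k)), 0, None)
            fit = fit_population_model(noisy)
            if fit.model == "logistic_decreasing":
                assert fit.r_squared >= fit.candidates["gaussian"][1]
                wins += 1
        assert wins >= 190

    def test_too_few_classes_rejected(self):
        with pytest.raises(FitError):
            fit_population_model([0, 100, 0, 0, 3, 0])

    def test_upper_transect_default_selects_logistic(self, default_study):
        pooled = [t for p in default_study if p.transect == "upper" for t in p.trees]
        counts, _ = dbh_class_histogram(pooled)
        assert fit_population_model(counts).model == "logistic_decreasing"


class TestTrend:
    @pytest.mark.parametrize(
        "pct,model,expected",
        [
            ({"young": 29, "near_mature": 43, "mature": 23, "old": 5},
             "logistic_decreasing", "growing"),
            ({"young": 18, "near_mature": 45, "mature": 26, "old": 11},
             "gaussian", "stable"),
            ({"young": 14, "near_mature": 48, "mature": 29, "old": 9},
             "gaussian", "temporarily_stable"),
            # degenerate histogram: no fit available, rule fallback applies
            ({"young": 40, "near_mature": 30, "mature": 20, "old": 10},
             None, "stable"),
        ],
    )
    def test_labels(self, pct, model, expected):
        assert classify_population_trend(pct, model) == expected


class TestStandSummary:
    def test_percentages_sum_to_100_and_sdi(self, default_study):
        plot = default_study[0]
        s = stand_summary(plot.trees, plot.window)
        assert sum(s.grade_percentages.values()) == pytest.approx(100.0)
        assert s.sdi == pytest.approx(plot.n / 0.25)
        assert 0.0 <= s.cpa <= 100.0
        assert set(s.grade_percentages) == set(GRADES)
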