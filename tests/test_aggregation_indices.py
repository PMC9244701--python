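"""Aggregation indices against hand values, closed forms and brute-force
nearest-neighbour oracles."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from standpattern.aggregation_indices import (
    ann_index,
    david_moore,
    hopkins_skellam,
    morisita,
    nearest_neighbor_distances,
    quadrat_counts,
)
from standpattern.stand_model import Window
from standpattern.synthetic_stands import simulate_csr, simulate_inhibition, simulate_thomas


class TestNearestNeighbor:
    def test_matches_all_pairs_scan(self, window50, rng):
        pts = rng.uniform(0, 50, size=(500, 2))
        d = nearest_neighbor_distances(pts)
        diff = pts[:, None, :] - pts[None, :, :]
        dm = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dm, np.inf)
        np.testing.assert_allclose(d, dm.min(axis=1), rtol=0, atol=0)


class TestAnn:
    def test_square_lattice_approaches_two(self):
        """On a square lattice with spacing s and a matched window the NN
        distance is s while the CSR expectation is s/2, so ANN -> 2."""
        s = 2.0
        m = 32
        xs, ys = np.meshgrid(np.arange(m) * s + s / 2, np.arange(m) * s + s / 2)
        pts = np.column_stack((xs.ravel(), ys.ravel()))
        w = Window(0, m * s, 0, m * s)
        res = ann_index(pts, w)
        assert res.value == pytest.approx(2.0, rel=0.05)
        assert res.label == "regular" and res.score > 0

    def test_tight_cluster_hand_value(self):
        """50 pairs of points 0.5 m apart: mean NN distance 0.5 m versus the
        CSR expectation 0.5 sqrt(2500/100) = 2.5 m gives ANN = 0.2."""
        gx, gy = np.meshgrid(2.5 + 5.0 * np.arange(10), 5.0 + 9.0 * np.arange(5))
        anchors = np.column_stack((gx.ravel(), gy.ravel()))
        pts = np.vstack((anchors, anchors + [0.5, 0.0]))
        res = ann_index(pts, Window(0, 50, 0, 50))
        assert res.value == pytest.approx(0.2, rel=1e-6)
        assert res.label == "aggregated" and res.score < 0

    def test_csr_mean_near_one(self, window50):
        vals = [ann_index(simulate_csr(500, window50, s), window50).value for s in range(50)]
        assert 0.97 < np.mean(vals) < 1.03

    def test_single_point_rejected(self, window50):
        with pytest.raises(ValueError):
            ann_index(np.array([[1.0, 1.0]]), window50)


class TestHopkinsSkellam:
    def test_corner_cluster_aggregated(self, window50):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 5, size=(120, 2))  # dense corner cluster
        res = hopkins_skellam(pts, window50, seed=0)
        assert res.value > 1.0
        assert res.label == "aggregated"

    def test_inhibition_below_one(self, window50):
        pts = simulate_inhibition(100, 4.0, window50, 2)
        res = hopkins_skellam(pts, window50, seed=0)
        assert res.value < 1.0

    def test_oversized_sample_clamped_with_warning(self, window50):
        pts = simulate_csr(20, window50, 0)
        with pytest.warns(UserWarning, match="clamped"):
            hopkins_skellam(pts, window50, n_sample=50, seed=0, n_sim=29)

    def test_csr_mean_within_band(self, window50):
        vals = [
            hopkins_skellam(simulate_csr(300, window50, s), window50, seed=s, n_sim=19).value
            for s in range(30)
        ]
        assert 0.85 < np.mean(vals) < 1.15


class TestQuadratCounts:
    def test_grid_shape_and_total(self, window50):
        pts = simulate_csr(200, window50, 0)
        qc = quadrat_counts(pts, window50, 10.0)
        assert qc.q == 25 and qc.shape == (5, 5)
        assert qc.n == 200

    def test_all_points_one_quadrat(self, window50):
        pts = np.full((30, 2), 3.0) + np.random.default_rng(0).uniform(0, 1, (30, 2))
        qc = quadrat_counts(pts, window50, 10.0)
        assert sorted(qc.counts)[-1] == 30 and qc.counts.sum() == 30

    def test_non_divisor_side_rejected(self, window50):
        with pytest.raises(ValueError, match="valid sides"):
            quadrat_counts(np.zeros((2, 2)), window50, 7.0)

    @given(st.integers(min_value=0, max_value=400), st.integers(min_value=0, max_value=2**31 - 1))
    def test_count_conservation(self, n, seed):
        w = Window(0, 50, 0, 50)
        pts = simulate_csr(n, w, seed)
        assert quadrat_counts(pts, w, 5.0).n == n


class TestDavidMoore:
    def test_equal_counts_zero_and_regular(self, window50):
        from standpattern.aggregation_indices import QuadratCounts

        qc = QuadratCounts(counts=np.full(25, 4), quadrat_side=10.0, shape=(5, 5))
        res = david_moore(qc, seed=0)
        assert res.value == 0.0
        assert res.label == "regular"

    def test_hand_value_single_hot_quadrat(self):
        """25 quadrats, one holding all 100 trees:
        DMI = (96^2 + 24 * 16) / (4 * 24) = 100."""
        from standpattern.aggregation_indices import QuadratCounts

        counts = np.zeros(25, dtype=int)
        counts[7] = 100
        qc = QuadratCounts(counts=counts, quadrat_side=10.0, shape=(5, 5))
        res = david_moore(qc, seed=0)
        assert res.value == pytest.approx(100.0)
        assert res.label == "aggregated" and res.significant

    def test_poisson_counts_mean_near_one(self):
        """i.i.d. Poisson quadrat counts have variance/mean 1."""
        from standpattern.aggregation_indices import QuadratCounts, _dmi_value

        rng = np.random.default_rng(3)
        vals = [_dmi_value(rng.poisson(8.0, 25).astype(float)) for _ in range(500)]
        assert 0.93 < np.mean(vals) < 1.07

    def test_zero_mean_rejected(self, window50):
        from standpattern.aggregation_indices import QuadratCounts

        qc = QuadratCounts(counts=np.zeros(25, dtype=int), quadrat_side=10.0, shape=(5, 5))
        with pytest.raises(ValueError):
            david_moore(qc)


class TestMorisita:
    def test_maximal_aggregation_equals_q(self, window50):
        pts = np.full((40, 2), 2.0) + np.random.default_rng(0).uniform(0, 1, (40, 2))
        qc = quadrat_counts(pts, window50, 10.0)
        res = morisita(qc, seed=0)
        assert res.value == pytest.approx(25.0)
        assert res.label == "aggregated" and res.significant

    @pytest.mark.parametrize("x", [2, 5])
    def test_equal_counts_closed_form(self, x):
        """Equal counts x in each of q quadrats: I = q(x-1)/(qx-1) < 1."""
        from standpattern.aggregation_indices import QuadratCounts

        q = 25
        qc = QuadratCounts(counts=np.full(q, x), quadrat_side=10.0, shape=(5, 5))
        res = morisita(qc, seed=0)
        assert res.value == pytest.approx(q * x * (x - 1) * q / ((q * x) * (q * x - 1)))
        assert res.value < 1.0

    def test_csr_mean_near_one(self, window50):
        vals = [
            morisita(quadrat_counts(simulate_csr(500, window50, s), window50), seed=s).value
            for s in range(50)
        ]
        assert 0.97 < np.mean(vals) < 1.03


class TestDirectionalConcordance:
    """Strongly clustered patterns trip all four indices towards aggregated;
    hardcore patterns towards regular."""

    def test_clustered_extreme(self, window50):
        pts = simulate_thomas(0.0008, 1.0, 80.0, window50, 5)
        qc = quadrat_counts(pts, window50)
        assert ann_index(pts, window50).label == "aggregated"
        assert david_moore(qc, seed=0).label == "aggregated"
        assert morisita(qc, seed=0).label == "aggregated"
        assert hopkins_skellam(pts, window50, seed=0).label == "aggregated"

    def test_hardcore_extreme(self, window50):
        pts = simulate_inhibition(110, 4.0, window50, 6)
        qc = quadrat_counts(pts, window50)
        assert ann_index(pts, window50).label == "regular"
        assert david_moore(qc, seed=0).label == "regular"
        assert hopkins_skellam(pts, window50, seed=0).label == "regular"

    def test_ann_agrees_with_g_labels_on_default_study(self, default_study):
        """Plot-level ANN labels agree with the g(r) envelope label on at
        least 14 of the 18 default plots."""
        from standpattern.pattern_functions import csr_envelope

        agree = 0
        for p in default_study:
            pts = p.coords()
            ann = ann_index(pts, p.window).label
            g = csr_envelope(pts, p.window, n_sim=99, seed=11).overall_label
            agree += ann == g
        assert agree >= 14
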