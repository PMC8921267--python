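"""Success-probability, cost-function and recommendation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kurafit.evaluation import (
    CostMatrix,
    GridTop,
    RunSet,
    SuccessCurve,
    aggregate_costs,
    cost_components,
    estimate_grid_cost,
    recommend,
    runs_for_level,
    success_curve,
    success_probability,
    success_probability_exact,
)


def runset(fits, points, time=None, subject="s0", method="m"):
    fits = np.asarray(fits, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] != fits.shape[0]:
        pts = pts.T
    t = np.full(fits.shape, 1.0) if time is None else np.asarray(time, dtype=float)
    return RunSet(fits=fits, points=pts, time_proxy=t, subject_id=subject, method=method)


class TestSuccessProbability:
    def test_closed_form_hand_case(self):
        # m=1 of 15 passing, r=3: 1 - C(14,3)/C(15,3) = 1 - 364/455 = 0.2
        assert success_probability_exact(1, 15, 3) == pytest.approx(0.2)

    def test_all_or_none_passing(self):
        fits_all = [np.full(15, 0.99)]
        fits_none = [np.full(15, 0.10)]
        for r in (1, 7, 15):
            p_all, _ = success_probability(fits_all, [1.0], r, seed=0)
            p_none, _ = success_probability(fits_none, [1.0], r, seed=0)
            assert p_all == 1.0 and p_none == 0.0
            assert success_probability_exact(15, 15, r) == 1.0
            assert success_probability_exact(0, 15, r) == 0.0

    def test_resampled_matches_closed_form_hand_case(self):
        fits = np.array([0.99] + [0.1] * 14)  # m = 1 passing run
        p, _ = success_probability([fits], [1.0], 3, n_resamples=500, seed=7)
        assert abs(p - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / 500)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(m=st.integers(0, 15), r=st.integers(1, 15))
    def test_resampling_converges_to_hypergeometric(self, m, r):
        fits = np.array([0.99] * m + [0.1] * (15 - m))
        exact = success_probability_exact(m, 15, r)
        p, _ = success_probability([fits], [1.0], r, n_resamples=500, seed=m * 31 + r)
        se = np.sqrt(max(exact * (1 - exact), 0.0) / 500)
        # 3 MC standard errors plus the binomial continuity correction 1/(2n)
        assert abs(p - exact) <= 3 * se + 1.0 / (2 * 500)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(m=st.integers(0, 24), r_max=st.integers(1, 24))
    def test_closed_form_monotone_in_r(self, m, r_max):
        m = min(m, r_max)
        probs = [success_probability_exact(m, r_max, r) for r in range(1, r_max + 1)]
        assert np.all(np.diff(probs) >= -1e-12)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError, match="r"):
            success_probability([np.ones(5)], [1.0], 6)


class TestRunsForLevel:
    def _curve(self, probs):
        probs = np.asarray(probs, dtype=float)
        r = np.arange(1, probs.size + 1)
        return SuccessCurve(r, probs, np.zeros_like(probs))

    def test_simple_threshold(self):
        assert runs_for_level(self._curve([0.6, 0.9, 0.95]), 0.8) == (2, True)

    def test_unreached_level_charges_r_max(self):
        curve = self._curve(np.full(24, 0.4))
        assert runs_for_level(curve, 0.8) == (24, False)

    def test_closed_form_level_half(self):
        # m=8 of 15: a single draw passes with probability 8/15 >= 0.5
        probs = [success_probability_exact(8, 15, r) for r in range(1, 16)]
        assert runs_for_level(self._curve(probs), 0.5) == (1, True)


class TestCostComponents:
    def toy(self):
        rs = runset([0.2, 0.3, 0.4], [[0.1], [0.2], [0.4]])
        gtop = GridTop(points=np.array([[0.2]]), fits=np.array([0.5]), best_fit=0.5)
        return cost_components(rs, gtop, time_for_80=10.0)

    def test_toy_component_values(self):
        bd = self.toy()
        assert bd.comp_fit == pytest.approx(0.6)
        assert bd.comp_sd == pytest.approx(0.081650, abs=1e-6)
        assert bd.comp_spread == pytest.approx(0.2)
        assert bd.comp_dist == pytest.approx(0.1)
        product = (bd.comp_fit * bd.comp_sd * bd.comp_time * bd.comp_spread
                   * bd.comp_dist)
        assert product == pytest.approx(0.009798, abs=1e-6)

    def test_spread_uses_105_pairs_for_15_runs(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, (15, 2))
        rs = runset(np.linspace(0.1, 0.5, 15), pts)
        gtop = GridTop(points=np.array([[0.5, 0.5]]), fits=np.array([0.9]), best_fit=0.9)
        bd = cost_components(rs, gtop, 1.0)
        manual = np.mean([
            np.linalg.norm(pts[i] - pts[j]) for i in range(15) for j in range(i + 1, 15)
        ])
        assert len([1 for i in range(15) for j in range(i + 1, 15)]) == 105
        assert bd.comp_spread == pytest.approx(manual)

    def test_perfect_runs_give_zero_cost(self):
        rs = runset([1.0, 1.0, 1.0], [[0.2], [0.2], [0.2]])
        gtop = GridTop(points=np.array([[0.2]]), fits=np.array([1.0]), best_fit=1.0)
        bd = cost_components(rs, gtop, 10.0)
        assert bd.comp_fit == bd.comp_sd == bd.comp_spread == bd.comp_dist == 0.0

    def test_mean_distance_mode(self):
        rs = runset([0.2, 0.3], [[0.0], [0.4]])
        gtop = GridTop(points=np.array([[0.1], [0.3]]), fits=np.array([0.6, 0.5]),
                       best_fit=0.6)
        bd_min = cost_components(rs, gtop, 1.0, distance_mode="min")
        bd_mean = cost_components(rs, gtop, 1.0, distance_mode="mean")
        assert bd_min.comp_dist == pytest.approx((0.1 + 0.1) / 2)
        assert bd_mean.comp_dist == pytest.approx((0.1 + 0.3 + 0.3 + 0.1) / 4)

    def test_single_run_rejected(self):
        rs = runset([0.2], [[0.1]])
        gtop = GridTop(points=np.array([[0.2]]), fits=np.array([0.5]), best_fit=0.5)
        with pytest.raises(ValueError, match="at least 2"):
            cost_components(rs, gtop, 1.0)


class TestAggregateAndRecommend:
    def breakdowns(self, time_scale=1.0):
        out = {}
        vals = {
            ("s0", "a"): (0.2, 0.05, 4.0, 0.3, 0.1),
            ("s0", "b"): (0.4, 0.10, 2.0, 0.1, 0.2),
            ("s1", "a"): (0.3, 0.02, 4.0, 0.2, 0.3),
            ("s1", "b"): (0.1, 0.08, 2.0, 0.4, 0.1),
        }
        from kurafit.evaluation import CostBreakdown

        for (s, m), (f, sd, t, sp, d) in vals.items():
            out[(s, m)] = CostBreakdown(f, sd, t * time_scale, sp, d)
        return out

    def test_two_method_toy_matches_hand_computation(self):
        costs = aggregate_costs(self.breakdowns())
        # hand normalization: maxima are fit 0.4, sd 0.10, time 4, spread 0.4, dist 0.3
        psi_s0_a = (0.2 / 0.4) * (0.05 / 0.1) * (4 / 4) * (0.3 / 0.4) * (0.1 / 0.3)
        i, j = costs.subjects.index("s0"), costs.methods.index("a")
        assert costs.psi[i, j] == pytest.approx(psi_s0_a)
        for c, arr in costs.normalized.items():
            assert arr.max() == pytest.approx(1.0)

    def test_common_time_rescaling_cancels(self):
        a = aggregate_costs(self.breakdowns(1.0)).psi
        b = aggregate_costs(self.breakdowns(2.0)).psi
        assert np.allclose(a, b)

    def test_recommendations_partition_cohort(self):
        costs = aggregate_costs(self.breakdowns())
        recs = recommend(costs)
        assert sum(recs.tally.values()) == len(costs.subjects)
        assert recs.winner in costs.methods

    def test_dominant_method_sweeps(self):
        rng = np.random.default_rng(0)
        psi = rng.uniform(0.5, 1.0, (6, 3))
        psi[:, 1] = 0.01
        costs = CostMatrix(
            subjects=[f"s{i}" for i in range(6)], methods=["a", "b", "c"],
            psi=psi, normalized={}, maxima={}, raw_time=np.ones((6, 3)),
        )
        recs = recommend(costs)
        assert recs.tally == {"a": 0, "b": 6, "c": 0}
        assert recs.winner == "b"

    def test_tie_broken_by_time_then_name(self):
        psi = np.array([[0.2, 0.1, 0.3, 0.1]])
        costs = CostMatrix(
            subjects=["s0"], methods=["a", "b", "c", "d"], psi=psi,
            normalized={}, maxima={}, raw_time=np.ones((1, 4)),
        )
        recs = recommend(costs)
        assert recs.per_subject["s0"] == "b"  # equal time -> lexicographic
        assert recs.tie_notes

    def test_missing_cell_rejected(self):
        bds = self.breakdowns()
        del bds[("s1", "b")]
        with pytest.raises(ValueError, match="missing"):
            aggregate_costs(bds)


class TestGridCostExtrapolation:
    def test_printed_example(self):
        assert estimate_grid_cost(100.0, 48, 3, 1) == pytest.approx(64.0)

    def test_one_dimensional_sweep_ignores_p(self):
        assert estimate_grid_cost(50.0, 7, 1, 1) == pytest.approx(50.0 / 3600.0)
        assert estimate_grid_cost(50.0, 99, 1, 1) == pytest.approx(50.0 / 3600.0)

    def test_linear_in_subjects(self):
        assert estimate_grid_cost(100.0, 48, 3, 100) == pytest.approx(6400.0)


def test_success_curve_over_subjects():
    fits = [np.array([0.99] + [0.1] * 14), np.full(15, 0.99)]
    curve = success_curve(fits, [1.0, 1.0], n_resamples=300, seed=5)
    assert curve.r_values[0] == 1 and curve.r_values[-1] == 15
    # subject 2 always passes; subject 1 follows the hypergeometric curve
    expected = 0.5 * (1 + np.array(
        [success_probability_exact(1, 15, r) for r in range(1, 16)]
    ))
    assert np.max(np.abs(curve.probabilities - expected)) < 0.1
    assert np.all(np.diff(curve.probabilities) >= -0.05)  # monotone up to MC noise
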