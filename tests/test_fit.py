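"""Goal-function and grid-search tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kurafit._seeds import SeedPolicy
from kurafit.cohort import CohortConfig, generate_connectome, make_ground_truth_subject
from kurafit.fc import FCMatrix
from kurafit.fit import (
    EvaluationCounter,
    SimSettings,
    fc_similarity,
    goal_function,
    make_goal,
    make_grid,
    run_grid_search,
)
from kurafit.model import ModelParams


def fc_from_triangle(tri, n=3) -> FCMatrix:
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = tri
    return FCMatrix(m + m.T - np.diag(np.diag(m)))


class TestFCSimilarity:
    def test_identical_matrices(self):
        fcm = fc_from_triangle([0.1, 0.2, 0.3])
        assert fc_similarity(fcm, fcm) == pytest.approx(1.0, abs=1e-12)

    def test_reversed_triangle_is_minus_one(self):
        a = fc_from_triangle([0.1, 0.2, 0.3])
        b = fc_from_triangle([0.3, 0.2, 0.1])
        assert fc_similarity(a, b) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_value(self):
        a = fc_from_triangle([0.1, 0.4, 0.2])
        b = fc_from_triangle([0.0, 0.5, 0.1])
        assert fc_similarity(a, b) == pytest.approx(0.9897, abs=1e-4)

    def test_mismatched_sizes_rejected(self):
        a = fc_from_triangle([0.1, 0.2, 0.3])
        b = FCMatrix(np.eye(4))
        with pytest.raises(ValueError, match="sizes differ"):
            fc_similarity(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        tri_a = rng.uniform(-0.9, 0.9, n * (n - 1) // 2)
        tri_b = rng.uniform(-0.9, 0.9, n * (n - 1) // 2)
        a, b = fc_from_triangle(tri_a, n), fc_from_triangle(tri_b, n)
        r = fc_similarity(a, b)
        assert fc_similarity(b, a) == pytest.approx(r, abs=1e-12)
        perm = rng.permutation(n)
        ap = FCMatrix(a.values[np.ix_(perm, perm)])
        bp = FCMatrix(b.values[np.ix_(perm, perm)])
        assert fc_similarity(ap, bp) == pytest.approx(r, abs=1e-12)


class TestMakeGrid:
    def test_default_2dim(self):
        g = make_grid(2)
        assert g.n_nodes == 3072
        assert g.c_axis.size == 64 and g.tau_axis.size == 48
        assert np.diff(g.c_axis)[0] == pytest.approx(0.945 / 63)
        assert g.c_axis[-1] == pytest.approx(0.945)
        assert g.tau_axis[-1] == pytest.approx(94.0)

    def test_default_3dim(self):
        g = make_grid(3)
        assert g.n_nodes == 85536
        assert (g.c_axis.size, g.tau_axis.size, g.sigma_axis.size) == (48, 22, 81)

    def test_3dim_tau_axis_denser_near_zero(self):
        g = make_grid(3)
        tau = g.tau_axis
        assert tau[0] == 0.0 and tau[-1] == pytest.approx(48.0)
        gaps = np.diff(tau)
        assert np.all(gaps > 0)
        assert np.all(np.diff(gaps) >= -1e-12)  # nondecreasing spacing

    def test_non_increasing_override_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_grid(2, c_axis=[0.5, 0.5, 0.9])

    def test_bad_dim_rejected(self):
        with pytest.raises(ValueError, match="dim"):
            make_grid(4)


class TestGridSearch:
    def test_single_node_grid(self):
        g = make_grid(2, c_axis=[0.5], tau_axis=[10.0])
        res = run_grid_search(None, None, g, goal=lambda p: 0.25)
        assert res.n_evaluations == 1
        assert res.best_point == (0.5, 10.0)
        assert res.top_points == [((0.5, 10.0), 0.25)]

    def test_surrogate_peak_found_on_default_grid(self):
        # brute-force argmax of a concave surrogate must be the node nearest (0.5, 40)
        g = make_grid(2)

        def goal(p):
            return -((p[0] - 0.5) ** 2) - ((p[1] - 40.0) / 94.0) ** 2

        res = run_grid_search(None, None, g, goal=goal)
        nearest_c = g.c_axis[np.argmin(np.abs(g.c_axis - 0.5))]
        nearest_t = g.tau_axis[np.argmin(np.abs(g.tau_axis - 40.0))]
        assert res.best_point == (pytest.approx(nearest_c), pytest.approx(nearest_t))
        assert len(res.top_points) == 5
        fits = [f for _, f in res.top_points]
        assert fits == sorted(fits, reverse=True)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(nc=st.integers(1, 5), nt=st.integers(1, 5), ns=st.integers(1, 4))
    def test_evaluation_count_is_axis_product(self, nc, nt, ns):
        g = make_grid(
            3, c_axis=np.linspace(0, 1, nc), tau_axis=np.linspace(0, 10, nt),
            sigma_axis=np.linspace(0, 2, ns),
        )
        counter = EvaluationCounter()
        res = run_grid_search(None, None, g, counter=counter, goal=lambda p: p[0])
        assert res.n_evaluations == nc * nt * ns == counter.n

    def test_dry_run_counts_without_simulating(self):
        counter = EvaluationCounter()
        g = make_grid(2)
        res = run_grid_search(None, None, g, counter=counter, dry_run=True)
        assert counter.n == 3072 and res.n_evaluations == 3072


GOAL_SIM = SimSettings(duration=90.0, transient=9.0)


@pytest.fixture(scope="module")
def problem(small_connectome):
    freqs = np.linspace(0.03, 0.08, 6)
    params = ModelParams(0.5, 2.0, 0.3, freqs, duration=GOAL_SIM.duration,
                         transient=GOAL_SIM.transient)
    emp = make_ground_truth_subject(small_connectome, params, 123)
    return small_connectome, emp, freqs


class TestGoalFunction:
    SIM = GOAL_SIM

    def test_fit_in_pearson_range_and_counter_increments(self, problem):
        conn, emp, freqs = problem
        counter = EvaluationCounter()
        ev = goal_function(conn, emp, (0.3, 5.0), freqs, self.SIM,
                           SeedPolicy(1, "fresh"), counter=counter)
        assert -1.0 <= ev.fit <= 1.0
        assert counter.n == 1
        assert ev.n_sim_seconds == self.SIM.duration

    def test_fresh_seed_policy_varies_fit(self, problem):
        conn, emp, freqs = problem
        policy = SeedPolicy(2, "fresh")
        fits = [
            goal_function(conn, emp, (0.3, 5.0), freqs, self.SIM, policy).fit
            for _ in range(3)
        ]
        assert len(set(fits)) > 1
        assert len(set(policy.issued)) == 3

    def test_truth_beats_decoupled_model(self, study_connectome):
        # mean fit at the generating parameters separates clearly from C=0
        freqs = np.linspace(0.025, 0.09, 20)
        truth = (0.6, 4.0)
        params = ModelParams(*truth, 0.3, freqs, duration=self.SIM.duration,
                             transient=self.SIM.transient)
        emp = make_ground_truth_subject(study_connectome, params, 55)
        goal_truth = make_goal(study_connectome, emp, freqs, self.SIM, SeedPolicy(3))
        goal_null = make_goal(study_connectome, emp, freqs, self.SIM, SeedPolicy(4))
        f_truth = np.array([goal_truth(truth) for _ in range(10)])
        f_null = np.array([goal_null((0.0, 0.0)) for _ in range(10)])
        se = np.sqrt(f_truth.var(ddof=1) / 10 + f_null.var(ddof=1) / 10)
        assert f_truth.mean() - f_null.mean() > 5 * se

    def test_out_of_box_point_rejected(self, problem):
        from kurafit.optimizers import BoxBounds

        conn, emp, freqs = problem
        with pytest.raises(ValueError, match="outside"):
            goal_function(conn, emp, (1.5, 5.0), freqs, self.SIM,
                          SeedPolicy(1), bounds=BoxBounds.default(2))


class TestGridSearchOnSimulator:
    SIM = SimSettings(duration=90.0, transient=9.0)

    def _grid(self):
        return make_grid(2, c_axis=np.linspace(0.0, 0.945, 4),
                         tau_axis=np.linspace(0.0, 10.0, 3))

    def _problem(self, conn, seed):
        freqs = np.linspace(0.03, 0.08, conn.n_regions)
        params = ModelParams(0.5, 2.0, 0.3, freqs, duration=self.SIM.duration,
                             transient=self.SIM.transient)
        emp = make_ground_truth_subject(conn, params, seed)
        return emp, freqs

    def test_fixed_seed_grid_is_deterministic(self, small_connectome):
        emp, freqs = self._problem(small_connectome, 31)
        kw = dict(frequencies=freqs, sim_settings=self.SIM)
        r1 = run_grid_search(small_connectome, emp, self._grid(),
                             seed_policy=SeedPolicy(31, "fixed"), **kw)
        r2 = run_grid_search(small_connectome, emp, self._grid(),
                             seed_policy=SeedPolicy(31, "fixed"), **kw)
        assert np.array_equal(r1.fits, r2.fits)
        assert r1.best_point == r2.best_point

    def test_checkpoint_resume_skips_completed_nodes(self, small_connectome, tmp_path):
        emp, freqs = self._problem(small_connectome, 32)
        ckpt = tmp_path / "grid.jsonl"
        kw = dict(frequencies=freqs, sim_settings=self.SIM)
        full = run_grid_search(small_connectome, emp, self._grid(),
                               seed_policy=SeedPolicy(32, "fixed"),
                               checkpoint=str(ckpt), **kw)
        # keep only the first half of the records and resume
        lines = ckpt.read_text().strip().splitlines()
        ckpt.write_text("\n".join(lines[: len(lines) // 2]) + "\n")
        counter = EvaluationCounter()
        resumed = run_grid_search(small_connectome, emp, self._grid(),
                                  seed_policy=SeedPolicy(32, "fixed"),
                                  checkpoint=str(ckpt), counter=counter, **kw)
        assert np.array_equal(full.fits, resumed.fits)
        assert counter.n == len(lines) - len(lines) // 2

    def test_parameter_recovery_within_one_grid_cell(self, study_connectome):
        # fixed-seed mode: the best node of a 16x12 grid stays within one
        # cell of the generating parameters in >= 9 of 10 seeds
        grid = make_grid(2, c_axis=np.linspace(0.0, 0.945, 16),
                         tau_axis=np.linspace(0.0, 20.0, 12))
        c_step = np.diff(grid.c_axis)[0]
        t_step = np.diff(grid.tau_axis)[0]
        freqs = np.linspace(0.025, 0.09, 20)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            truth = (rng.uniform(0.15, 0.8), rng.uniform(2.0, 18.0))
            params = ModelParams(*truth, 0.3, freqs, duration=self.SIM.duration,
                                 transient=self.SIM.transient)
            emp = make_ground_truth_subject(study_connectome, params, seed)
            res = run_grid_search(study_connectome, emp, grid, freqs, self.SIM,
                                  seed_policy=SeedPolicy(seed, "fixed"))
            if (abs(res.best_point[0] - truth[0]) <= c_step
                    and abs(res.best_point[1] - truth[1]) <= t_step):
                hits += 1
        assert hits >= 9
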