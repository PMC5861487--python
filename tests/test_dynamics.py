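import numpy as np
import pytest

from regennet import (
    ExpressionMatrix,
    InferenceConfig,
    TimeDesign,
    aic_score,
    assemble_regression,
    fit_constrained_ls,
    infer_network,
    prune_by_aic,
    spline_densify,
)
from regennet.benchmarks import benchmark_instance
from regennet.candidate import candidate_from_edges
from regennet.dynamics import DenseTrajectory, RegressionProblem, RSS_FLOOR
from regennet.errors import ParameterError
from regennet.synthetic import simulate_expression, spike_false_positives

from oracles import exhaustive_aic_min, natural_spline_eval


def dense_from(values: dict[str, np.ndarray], grid=None) -> DenseTrajectory:
    ids = tuple(values)
    arr = np.vstack([values[i] for i in ids])
    grid = np.arange(arr.shape[1], dtype=float) if grid is None else grid
    return DenseTrajectory(ids, grid, arr)


class TestSplineDensify:
    def test_linear_function_reproduced(self):
        design = TimeDesign.uniform((0.0, 0.25, 1.0, 3.0), 1)
        t = np.array(design.time_points)
        m = ExpressionMatrix(("p",), design, (2.0 * t - 1.0)[None, :])
        out = spline_densify(m, 13)
        np.testing.assert_allclose(out.values[0], 2.0 * out.grid - 1.0, atol=1e-10)

    def test_knot_values_are_replicate_means(self):
        design = TimeDesign.uniform((0.0, 1.0, 2.0), 2)
        vals = np.array([[1.0, 3.0, 4.0, 6.0, 10.0, 10.0]])
        m = ExpressionMatrix(("p",), design, vals)
        out = spline_densify(m, 5)  # grid 0, .5, 1, 1.5, 2 — knots at 0, 1, 2
        np.testing.assert_allclose(out.values[0][[0, 2, 4]], [2.0, 5.0, 10.0], atol=1e-12)

    def test_matches_tridiagonal_oracle(self):
        rng = np.random.default_rng(31)
        design = TimeDesign.uniform((0.0, 0.5, 1.2, 3.0), 1)
        y = rng.normal(size=4)
        m = ExpressionMatrix(("p",), design, y[None, :])
        out = spline_densify(m, 13)
        expected = natural_spline_eval(np.array(design.time_points), y, out.grid)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-9)

    def test_too_few_grid_points_rejected(self, small_matrix):
        with pytest.raises(ParameterError):
            spline_densify(small_matrix, 3)

    def test_two_point_linear_fallback(self):
        design = TimeDesign((0.0, 2.0), (1, 1))
        m = ExpressionMatrix(("p",), design, np.array([[1.0, 5.0]]))
        out = spline_densify(m, 5)
        np.testing.assert_allclose(out.values[0], [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_grid_spans_observed_range(self, small_matrix):
        out = spline_densify(small_matrix, 9)
        assert out.grid[0] == small_matrix.design.time_points[0]
        assert out.grid[-1] == small_matrix.design.time_points[-1]


class TestAssembleRegression:
    def test_self_only_layout(self):
        dense = dense_from({"i": np.array([1.0, 2.0, 4.0, 8.0])})
        p = assemble_regression("i", (), dense)
        assert p.design.shape == (3, 2)
        np.testing.assert_array_equal(p.design[:, 0], [1, 2, 4])
        np.testing.assert_array_equal(p.design[:, 1], [1, 1, 1])
        np.testing.assert_array_equal(p.response, [2, 4, 8])

    def test_two_interactor_layout(self):
        rng = np.random.default_rng(5)
        vals = {k: rng.normal(size=11) for k in ("x1", "x2", "i")}
        p = assemble_regression("i", ("x1", "x2"), dense_from(vals))
        assert p.design.shape == (10, 4)
        np.testing.assert_array_equal(
            p.design[0], [vals["x1"][0], vals["x2"][0], vals["i"][0], 1.0]
        )
        assert p.response[0] == vals["i"][1]

    def test_entries_match_index_arithmetic(self):
        rng = np.random.default_rng(6)
        vals = {k: rng.normal(size=9) for k in ("a", "b", "c", "i")}
        p = assemble_regression("i", ("b", "a", "c"), dense_from(vals))
        for t in range(8):
            np.testing.assert_array_equal(
                p.design[t],
                [vals["b"][t], vals["a"][t], vals["c"][t], vals["i"][t], 1.0],
            )
            assert p.response[t] == vals["i"][t + 1]

    def test_target_among_interactors_rejected(self):
        dense = dense_from({"i": np.zeros(6), "j": np.zeros(6)})
        with pytest.raises(ParameterError):
            assemble_regression("i", ("i", "j"), dense)

    def test_identifiability_margin_enforced(self):
        dense = dense_from({k: np.zeros(4) for k in ("i", "a", "b", "c")})
        with pytest.raises(ValueError, match="equations"):
            assemble_regression("i", ("a", "b", "c"), dense)


def simulate_target(a, lam, k, interactor_traj, x0=1.0):
    """Iterate the dynamic update exactly to make a noiseless target row."""
    n_steps = interactor_traj.shape[1]
    x = np.empty(n_steps)
    x[0] = x0
    for t in range(n_steps - 1):
        x[t + 1] = x[t] + a @ interactor_traj[:, t] - lam * x[t] + k
    return x


class TestFitConstrainedLs:
    def test_noiseless_parameter_recovery(self):
        rng = np.random.default_rng(8)
        traj = rng.uniform(0.5, 2.0, size=(2, 10))
        x = simulate_target(np.array([0.3, -0.2]), 0.1, 0.5, traj)
        dense = dense_from({"j1": traj[0], "j2": traj[1], "i": x})
        est = fit_constrained_ls(assemble_regression("i", ("j1", "j2"), dense))
        np.testing.assert_allclose(est.abilities, [0.3, -0.2], atol=1e-6)
        assert est.degradation == pytest.approx(0.1, abs=1e-6)
        assert est.basal == pytest.approx(0.5, abs=1e-6)
        assert np.linalg.norm(est.residuals) < 1e-9

    def test_all_zero_degenerate_case(self):
        dense = dense_from({"i": np.zeros(6)})
        est = fit_constrained_ls(assemble_regression("i", (), dense))
        assert est.basal == 0.0
        assert est.degenerate
        assert np.linalg.norm(est.residuals) == 0.0

    def test_bounds_enforced_when_active(self):
        # response forces a strongly negative basal in the unconstrained fit
        rng = np.random.default_rng(12)
        x = rng.uniform(1.0, 2.0, size=8)
        dense = dense_from({"i": x - np.linspace(0, 5, 8)})
        est = fit_constrained_ls(assemble_regression("i", (), dense))
        assert est.basal >= 0.0
        assert 0.0 <= est.degradation <= 1.0

    def test_dominates_random_feasible_points(self):
        rng = np.random.default_rng(21)
        traj = rng.uniform(0.2, 3.0, size=(3, 12))
        x = simulate_target(np.array([0.2, -0.4, 0.1]), 0.3, 0.2, traj)
        x += rng.normal(0, 0.2, size=x.size)  # noise so the optimum is interior-ish
        dense = dense_from({"a": traj[0], "b": traj[1], "c": traj[2], "i": x})
        problem = assemble_regression("i", ("a", "b", "c"), dense)
        est = fit_constrained_ls(problem)
        for _ in range(100):
            theta = np.concatenate(
                [rng.normal(0, 1, 3), [rng.uniform(0, 1)], [rng.uniform(0, 2)]]
            )
            rss_rand = float(np.sum((problem.response - problem.design @ theta) ** 2))
            assert est.rss <= rss_rand + 1e-9

    def test_non_subset_interactors_get_zero(self):
        rng = np.random.default_rng(3)
        vals = {k: rng.normal(size=10) for k in ("a", "b", "i")}
        problem = assemble_regression("i", ("a", "b"), dense_from(vals))
        est = fit_constrained_ls(problem, subset=("b",))
        assert est.ability_of("a") == 0.0
        assert est.subset == ("b",)


class TestAicScore:
    def test_unit_residuals(self):
        assert aic_score(np.ones(4), n_params=2, n_equations=4) == pytest.approx(1.0)

    def test_perfect_fit_floor(self):
        expected = np.log(RSS_FLOOR) + 1.0
        assert aic_score(np.zeros(4), n_params=2, n_equations=4) == pytest.approx(expected)

    def test_random_residuals_match_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            r = rng.normal(size=rng.integers(3, 12))
            n_params = int(rng.integers(2, 6))
            expected = np.log(max((r @ r) / r.size, RSS_FLOOR)) + 2 * n_params / r.size
            assert aic_score(r, n_params, r.size) == pytest.approx(expected, rel=1e-12)

    def test_penalty_strictly_increasing_in_params(self):
        r = np.full(5, 0.7)
        scores = [aic_score(r, p, 5) for p in range(2, 7)]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestPruneByAic:
    def test_no_interactors_trivial(self):
        dense = dense_from({"i": np.array([1.0, 1.5, 1.7, 1.8, 1.9])})
        sel = prune_by_aic(assemble_regression("i", (), dense))
        assert sel.selected_order == 0
        assert len(sel.aic_trace) == 1

    def test_noiseless_single_true_interactor_found(self):
        rng = np.random.default_rng(41)
        traj = rng.uniform(0.5, 2.0, size=(4, 12))
        x = simulate_target(np.array([0.5, 0.0, 0.0, 0.0]), 0.2, 0.3, traj)
        names = ("j1", "j2", "j3", "j4")
        dense = dense_from(dict(zip(names, traj)) | {"i": x})
        problem = assemble_regression("i", names, dense)
        sel = prune_by_aic(problem)
        assert sel.retained_interactors == ("j1",)
        # nested scan attains the exhaustive-subset minimum on noiseless data
        assert sel.aic_trace[sel.selected_order] == pytest.approx(
            exhaustive_aic_min(problem), abs=1e-9
        )

    def test_selected_never_worse_than_full_or_empty(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            traj = rng.normal(1.0, 0.5, size=(3, 11))
            x = rng.normal(1.0, 0.5, size=11)
            dense = dense_from({"a": traj[0], "b": traj[1], "c": traj[2], "i": x})
            sel = prune_by_aic(assemble_regression("i", ("a", "b", "c"), dense))
            k_sel = sel.aic_trace[sel.selected_order]
            assert k_sel <= sel.aic_trace[0] + 1e-12
            assert k_sel <= sel.aic_trace[-1] + 1e-12

    def test_retained_set_invariant_to_interactor_order(self):
        rng = np.random.default_rng(47)
        traj = rng.uniform(0.5, 2.0, size=(3, 12))
        x = simulate_target(np.array([0.4, -0.3, 0.0]), 0.1, 0.2, traj)
        x += rng.normal(0, 0.05, x.size)
        names = ("a", "b", "c")
        dense = dense_from(dict(zip(names, traj)) | {"i": x})
        base = prune_by_aic(assemble_regression("i", names, dense))
        perm = ("c", "a", "b")
        dense2 = dense_from({k: dict(zip(names, traj))[k] for k in perm} | {"i": x})
        other = prune_by_aic(assemble_regression("i", perm, dense2))
        assert set(base.retained_interactors) == set(other.retained_interactors)


class TestInferNetwork:
    def test_empty_candidate_empty_refined(self, small_matrix):
        cand = candidate_from_edges([])
        refined = infer_network(cand, small_matrix)
        assert refined.edges == frozenset() and refined.nodes == frozenset()

    def test_missing_nodes_aggregated_error(self, small_matrix):
        cand = candidate_from_edges([("ghost1", "ghost2"), ("ghost2", "prot0")])
        with pytest.raises(KeyError, match="ghost1.*ghost2"):
            infer_network(cand, small_matrix)

    def test_refined_subset_of_candidate(self):
        for seed in range(3):
            model, cand, _, matrix, m = benchmark_instance(seed, 0.1, 1.0, n_nodes=10)
            refined = infer_network(cand, matrix, InferenceConfig(m_points=m))
            assert refined.edges <= cand.edges
            assert refined.nodes == {n for e in refined.edges for n in e}

    def test_both_merge_subset_of_union(self):
        model, cand, _, matrix, m = benchmark_instance(0, 0.05, 1.0, n_nodes=12)
        union = infer_network(cand, matrix, InferenceConfig(m_points=m, merge="union"))
        both = infer_network(cand, matrix, InferenceConfig(m_points=m, merge="both"))
        assert both.edges <= union.edges

    def test_noiseless_identifiability_small(self):
        """sigma=0 with an aligned, identifiable design recovers the exact
        edge set and parameters (the pipeline's principal property)."""
        from regennet.benchmarks import run_recovery

        report = run_recovery(seed=3, sigma=0.0, fp_ratio=0.5, n_nodes=10)
        assert report.metrics.precision == 1.0
        assert report.metrics.recall == 1.0
        assert report.max_param_error < 1e-6

    def test_parameter_error_shrinks_with_noise(self):
        """Mean absolute parameter error is non-increasing through
        sigma = 0.5, 0.1, 0.02 (30 seeded replicates per level)."""
        from regennet.benchmarks import run_recovery

        means = []
        for sigma in (0.5, 0.1, 0.02):
            errs = [
                run_recovery(seed, sigma, 0.0, n_nodes=8).max_param_error
                for seed in range(30)
            ]
            means.append(np.mean(errs))
        assert means[0] >= means[1] >= means[2]
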