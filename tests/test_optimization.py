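import numpy as np
import pytest

from mlcpen import (OptimizationProblem, ParetoFront, ParetoPoint, ga_pareto,
                    local_optimize, multistart, penumbra_stats,
                    sample_positions, scalarize, select_optimal)


@pytest.fixture(scope="module")
def ell_problem(scene, src, tst):
    return OptimizationProblem(family="elliptical", scene=scene, src=src,
                               tst=tst)


@pytest.fixture(scope="module")
def bez_problem_small(scene, src, tst):
    """Bezier problem on a short sweep: fast enough for evolutionary tests."""
    return OptimizationProblem(family="bezier", scene=scene, src=src, tst=tst,
                               n_positions=5)


def test_sample_positions_spacing():
    pos = sample_positions(-20.0, 20.0, 17)
    assert len(pos) == 17
    assert np.allclose(np.diff(pos), 2.5)
    assert np.allclose(sample_positions(-20.0, 20.0, 2), [-20.0, 20.0])
    rev = sample_positions(20.0, -20.0, 17)
    assert np.allclose(sorted(rev), pos)
    with pytest.raises(ValueError):
        sample_positions(-20.0, 20.0, 1)


def test_scalarize():
    assert scalarize(0.2, 0.01, 1.0) == 0.2
    assert scalarize(0.2, 0.01, 0.0) == 0.01
    assert np.isclose(scalarize(0.2, 0.01, 0.5), 0.105)
    with pytest.raises(ValueError):
        scalarize(0.2, 0.01, 1.2)


def test_constant_sweep_has_zero_std(scene, src, tst, circ_opt):
    """A degenerate sweep at a single repeated position has sigma = 0."""
    problem = OptimizationProblem(family="circular", scene=scene, src=src,
                                  tst=tst, t_w=0.0, t_p=0.0, n_positions=5)
    _, sigma = penumbra_stats(circ_opt, problem)
    assert sigma == 0.0


def test_solver_sanity_on_quadratic(ell_problem):
    """The constrained solver reaches the analytic minimiser of a convex
    quadratic within tight tolerance."""
    res = local_optimize(ell_problem, x0=[1.0],
                         objective=lambda p: (p[0] - 2.3) ** 2 + 0.7)
    assert abs(res.p[0] - 2.3) < 1e-6


def test_infeasible_start_rejected(scene, src, tst):
    problem = OptimizationProblem(family="circular", scene=scene, src=src,
                                  tst=tst)
    with pytest.raises(ValueError):
        local_optimize(problem, x0=[3.0, 0.0])


def test_elliptical_optimum_and_edge_effect(ell_problem):
    """The mean-optimal semiminor axis; shrinking b below it degrades both
    objectives sharply (edge effect)."""
    res = local_optimize(ell_problem, x0=[2.0], objective="mean")
    assert abs(res.p[0] - 0.728) < 0.05
    mu_opt, sd_opt = ell_problem.stats([0.728])
    mu_lo, sd_lo = ell_problem.stats([0.4])
    assert mu_lo > mu_opt + 0.01
    assert sd_lo > sd_opt * 1.5


def test_weighted_sum_endpoint_consistency(ell_problem):
    """lambda: 1 -> 0 trades mean for standard deviation monotonically."""
    pts = []
    for lam in (1.0, 0.5, 0.0):
        res = local_optimize(ell_problem, x0=[2.0], objective=lam)
        pts.append((res.mu, res.sigma))
    mus = [p[0] for p in pts]
    sds = [p[1] for p in pts]
    assert mus[0] <= mus[1] + 1e-9 <= mus[2] + 2e-9
    assert sds[2] <= sds[1] + 1e-9 <= sds[0] + 2e-9


def test_pareto_front_nondominated():
    pts = [ParetoPoint(np.array([0.0]), 0.2, 0.01),
           ParetoPoint(np.array([1.0]), 0.21, 0.005),
           ParetoPoint(np.array([2.0]), 0.22, 0.02)]  # dominated by the first
    front = ParetoFront(points=pts)
    assert len(front) == 2


def test_ga_pareto_bezier(bez_problem_small):
    front = ga_pareto(bez_problem_small, population=20, generations=12, seed=5)
    assert len(front) >= 1
    F = front.objectives()
    # dominance audit: every returned pair mutually nondominated
    for i in range(len(F)):
        for j in range(len(F)):
            if i != j:
                assert not ((F[i] <= F[j]).all() and (F[i] < F[j]).any())
    # feasibility of every member
    for pt in front.points:
        assert bez_problem_small.is_feasible(pt.p)
    # reproducibility
    front2 = ga_pareto(bez_problem_small, population=20, generations=12,
                       seed=5)
    assert np.allclose(front.objectives(), front2.objectives())


def test_ga_front_brackets_local_optimum(bez_problem_small):
    """The front's min-mean endpoint is consistent with a gradient run."""
    front = ga_pareto(bez_problem_small, population=30, generations=30, seed=1)
    res = local_optimize(bez_problem_small, objective="mean")
    assert front.objectives()[:, 0].min() <= res.mu * 1.01


def test_multistart_single_equals_local(ell_problem):
    outs = multistart(ell_problem, n_starts=1, seed=11)
    assert len(outs) == 1
    res = local_optimize(ell_problem, x0=outs[0].p, objective="mean")
    assert abs(res.J - outs[0].J) < 1e-8


def test_multistart_convex_family_converges_to_one_optimum(ell_problem):
    outs = multistart(ell_problem, n_starts=3, seed=2, merge_radius=0.05)
    assert len(outs) == 1


def test_select_optimal_band_rule():
    near = ParetoPoint(np.array([0.0]), 0.197, 0.01)
    vertex = ParetoPoint(np.array([1.0]), 0.210, 0.0005)
    front = ParetoFront(points=[near, vertex])
    # 5% band excludes 0.210 (>1.05 * 0.197): the min-mean point wins
    assert select_optimal(front, band=0.05) is near
    # a 7% band admits the vertex point, which has the smaller sigma
    assert select_optimal(front, band=0.07) is vertex
    single = ParetoFront(points=[near])
    assert select_optimal(single) is near
    with pytest.raises(ValueError):
        select_optimal(ParetoFront(points=[]))


def test_select_optimal_equal_mean_prefers_min_sigma():
    a = ParetoPoint(np.array([0.0]), 0.2, 0.02)
    b = ParetoPoint(np.array([1.0]), 0.2, 0.01)
    front = ParetoFront.__new__(ParetoFront)
    front.points = [a, b]  # degenerate equal-mean front
    assert select_optimal(front) is b


def test_circular_optimum_hessian_psd(scene, src, tst):
    """Numeric Hessian of the sweep mean at the mean-optimal circular arc is
    positive semidefinite (convex objective space)."""
    problem = OptimizationProblem(family="circular", scene=scene, src=src,
                                  tst=tst)
    p0 = np.array([16.29, -0.664])
    h = np.array([1e-2, 1e-2])
    f = lambda p: problem.stats(p)[0]
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = (f(p0 + ei + ej) - f(p0 + ei - ej)
                       - f(p0 - ei + ej) + f(p0 - ei - ej)) / (4 * h[i] * h[j])
    eig = np.linalg.eigvalsh((H + H.T) / 2)
    assert eig.min() >= -1e-6 * max(1.0, abs(eig).max())
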