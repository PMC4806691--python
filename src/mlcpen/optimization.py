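"""Mean-variance leaf-end shape optimization.

The design objective is the pair ``(mu, sigma)``: mean and sample standard
deviation of the penumbra width over a uniform sweep of leaf positions.  A
weighted-sum scalarization ``J = lambda mu + (1 - lambda) sigma`` supports
single-objective runs; the Pareto frontier of the biobjective problem is
approximated either by sweeping ``lambda`` with the gradient-based local
solver (convex families) or by a seeded NSGA-II evolutionary run (Bezier and
B-spline families, whose objective landscapes carry multiple local optima).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .leafgeom import LeafEndCurve, MachineScene, leaf_end
from .source_model import SourceDistribution
from .tst_core import TSTParams, position_sweep

__all__ = ["OptimizationProblem", "ParetoPoint", "ParetoFront",
           "sample_positions", "penumbra_stats", "scalarize",
           "local_optimize", "ga_pareto", "multistart", "select_optimal",
           "OptimResult"]


def sample_positions(t_w: float, t_p: float, n: int) -> np.ndarray:
    """Uniformly sampled leaf positions between the fully withdrawn (``t_w``)
    and fully protruded (``t_p``) scoring-plane positions."""
    if n < 2:
        raise ValueError("need at least 2 sample positions")
    return t_w + np.arange(n) / (n - 1) * (t_p - t_w)


def scalarize(mu: float, sigma: float, lam: float) -> float:
    """Weighted-sum composite objective ``lambda mu + (1 - lambda) sigma``."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    return lam * mu + (1.0 - lam) * sigma


@dataclass
class OptimizationProblem:
    """A leaf-end shape design problem over one parametric family.

    Fixed ingredients: machine scene, source model, TST parameters and the
    position sweep.  Design variables, bounds and the Table-style linear /
    concavity constraints are derived from the family.
    """

    family: str
    scene: MachineScene
    src: SourceDistribution
    tst: TSTParams
    t_w: float = -20.0
    t_p: float = 20.0
    n_positions: int = 17
    r_max: float = 100.0  # numerical cap standing in for R < infinity

    def __post_init__(self):
        self.positions = sample_positions(self.t_w, self.t_p, self.n_positions)
        lh = self.scene.lh
        if self.family == "circular":
            self.bounds = [(lh / 2, self.r_max), (-lh / 2, lh / 2)]
            self.constraints = [lambda p: p[0] - p[1] - lh / 2,
                                lambda p: p[0] + p[1] - lh / 2]
            self.x0 = np.array([lh / 2, 0.0])
        elif self.family == "elliptical":
            self.bounds = [(1e-3, lh / 2)]
            self.constraints = []
            self.x0 = np.array([lh / 4])
        elif self.family == "bezier":
            self.bounds = [(-lh / 2, 0.0), (0.0, lh / 2),
                           (0.0, lh / 2), (0.0, lh / 2)]
            # concavity with fixed y0 = y3 = 0: y2 <= 2 y1 and y1 <= 2 y2
            self.constraints = [lambda p: 2 * p[1] - p[3],
                                lambda p: 2 * p[3] - p[1]]
            self.x0 = np.array([-lh / 4, lh / 8, lh / 4, lh / 8])
        elif self.family == "bspline":
            n = 8
            self.bounds = [(0.0, lh / 2)] * n
            self.constraints = [
                (lambda i: lambda p: 2 * p[i + 1] - p[i]
                 - (p[i + 2] if i + 2 < n else 0.0))(i)
                for i in range(n - 1)]
            self.x0 = np.full(n, lh / 8)
        else:
            raise ValueError(f"unsupported design family {self.family!r}")

    def spec_of(self, p) -> LeafEndCurve:
        p = np.asarray(p, dtype=float)
        lh = self.scene.lh
        if self.family == "circular":
            return leaf_end("circular", lh, R=p[0], d=p[1])
        if self.family == "elliptical":
            return leaf_end("elliptical", lh, b=p[0])
        if self.family == "bezier":
            return leaf_end("bezier", lh, control=[(p[0], p[1]), (p[2], p[3])])
        return leaf_end("bspline", lh, y=p)

    def violation(self, p) -> float:
        """Total constraint violation (0 when feasible)."""
        p = np.asarray(p, dtype=float)
        v = 0.0
        for (lo, hi), x in zip(self.bounds, p):
            v += max(0.0, lo - x) + max(0.0, x - hi)
        for g in self.constraints:
            v += max(0.0, -g(p))
        return v

    def is_feasible(self, p, tol: float = 1e-9) -> bool:
        return self.violation(p) <= tol

    def stats(self, p) -> tuple[float, float]:
        return penumbra_stats(self.spec_of(p), self)


def penumbra_stats(spec: LeafEndCurve, problem: OptimizationProblem):
    """Mean and sample standard deviation (1/(N-1)) of the sweep widths."""
    W = position_sweep(spec, problem.positions, problem.tst, problem.scene,
                       problem.src)
    return float(W.mean()), float(W.std(ddof=1))


@dataclass
class OptimResult:
    p: np.ndarray
    J: float
    mu: float
    sigma: float
    n_iter: int
    n_evals: int
    success: bool
    message: str = ""


def _objective(problem: OptimizationProblem, objective):
    if callable(objective):
        return objective
    if objective == "mean":
        return lambda p: problem.stats(p)[0]
    if objective == "std":
        return lambda p: problem.stats(p)[1]
    lam = float(objective)
    return lambda p: scalarize(*problem.stats(p), lam)


def local_optimize(problem: OptimizationProblem, x0=None,
                   objective="mean", eps: float = 1e-6,
                   max_iter: int = 300) -> OptimResult:
    """Constrained gradient descent (SLSQP, central-difference-scale FD step).

    ``objective`` is ``"mean"``, ``"std"``, a weight ``lambda in [0, 1]``
    for the scalarized composite, or a callable ``f(p)`` (used for solver
    sanity checks).  The start must be feasible.
    """
    x0 = problem.x0 if x0 is None else np.asarray(x0, dtype=float)
    if not problem.is_feasible(x0, tol=1e-7):
        raise ValueError("infeasible start point")
    fun = _objective(problem, objective)
    cons = [{"type": "ineq", "fun": g} for g in problem.constraints]
    res = minimize(fun, x0, method="SLSQP", bounds=problem.bounds,
                   constraints=cons,
                   options={"eps": eps, "ftol": 1e-12, "maxiter": max_iter})
    mu, sigma = problem.stats(res.x)
    return OptimResult(p=res.x, J=float(res.fun), mu=mu, sigma=sigma,
                       n_iter=int(res.nit), n_evals=int(res.nfev),
                       success=bool(res.success), message=res.message)


@dataclass
class ParetoPoint:
    p: np.ndarray
    mu: float
    sigma: float
    tag: str = ""


@dataclass
class ParetoFront:
    points: list[ParetoPoint] = field(default_factory=list)

    def __post_init__(self):
        self.points = _nondominated(self.points)

    def __len__(self):
        return len(self.points)

    def objectives(self) -> np.ndarray:
        return np.array([(pt.mu, pt.sigma) for pt in self.points])


def _dominates(a: ParetoPoint, b: ParetoPoint) -> bool:
    return (a.mu <= b.mu and a.sigma <= b.sigma
            and (a.mu < b.mu or a.sigma < b.sigma))


def _nondominated(points):
    out = []
    for p in points:
        if not any(_dominates(q, p) for q in points if q is not p):
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# NSGA-II (simulated binary crossover, polynomial mutation,
# feasibility-dominance constraint handling)
# ---------------------------------------------------------------------------

def _fast_nondominated_sort(F):
    n = len(F)
    S = [[] for _ in range(n)]
    counts = np.zeros(n, dtype=int)
    fronts = [[]]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (F[i] <= F[j]).all() and (F[i] < F[j]).any():
                S[i].append(j)
            elif (F[j] <= F[i]).all() and (F[j] < F[i]).any():
                counts[i] += 1
        if counts[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt = []
        for i in fronts[k]:
            for j in S[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
        k += 1
    return fronts[:-1]


def _crowding(F, idx):
    m = len(idx)
    if m <= 2:
        return np.full(m, np.inf)
    dist = np.zeros(m)
    sub = F[idx]
    for k in range(F.shape[1]):
        order = np.argsort(sub[:, k])
        lo, hi = sub[order[0], k], sub[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi > lo:
            dist[order[1:-1]] += (sub[order[2:], k] - sub[order[:-2], k]) / (hi - lo)
    return dist


def _sbx(rng, a, b, lo, hi, eta=15.0):
    u = rng.random(len(a))
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutate(rng, x, lo, hi, eta=20.0, pm=None):
    x = x.copy()
    if pm is None:
        pm = 1.0 / len(x)
    for i in range(len(x)):
        if rng.random() < pm:
            u = rng.random()
            delta = ((2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5
                     else 1 - (2 * (1 - u)) ** (1 / (eta + 1)))
            x[i] = np.clip(x[i] + delta * (hi[i] - lo[i]), lo[i], hi[i])
    return x


def _sample_feasible(problem, rng, max_tries=2000):
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    for _ in range(max_tries):
        x = lo + rng.random(len(lo)) * (hi - lo)
        if problem.is_feasible(x, tol=0.0):
            return x
    raise RuntimeError("could not sample a feasible design point")


def ga_pareto(problem: OptimizationProblem, population: int = 80,
              generations: int = 150, seed: int = 0) -> ParetoFront:
    """Approximate the mean-variance Pareto frontier with NSGA-II.

    Reproducible for a given seed.  Infeasible offspring are handled by
    feasibility dominance: a feasible design always beats an infeasible one,
    and among infeasible designs the smaller total violation wins.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    pop = [_sample_feasible(problem, rng) for _ in range(population)]

    def evaluate(xs):
        F, cv = [], []
        for x in xs:
            v = problem.violation(x)
            cv.append(v)
            F.append(problem.stats(x) if v <= 1e-9 else (np.inf, np.inf))
        return np.array(F), np.array(cv)

    F, CV = evaluate(pop)

    def rank_all(F, CV):
        feas = np.flatnonzero(CV <= 1e-9)
        infeas = np.flatnonzero(CV > 1e-9)
        rank = np.empty(len(F), dtype=int)
        crowd = np.zeros(len(F))
        if len(feas):
            fronts = _fast_nondominated_sort(F[feas])
            for r, fr in enumerate(fronts):
                rank[feas[fr]] = r
                crowd[feas[fr]] = _crowding(F[feas], fr)
        base = 10**6
        order = np.argsort(CV[infeas])
        for r, i in enumerate(infeas[order]):
            rank[i] = base + r
        return rank, crowd

    rank, crowd = rank_all(F, CV)

    def tourney():
        i, j = rng.integers(0, len(pop), 2)
        if rank[i] != rank[j]:
            return i if rank[i] < rank[j] else j
        return i if crowd[i] >= crowd[j] else j

    for _ in range(generations):
        children = []
        while len(children) < population:
            a, b = pop[tourney()], pop[tourney()]
            c1, c2 = _sbx(rng, a, b, lo, hi)
            children.append(_poly_mutate(rng, c1, lo, hi))
            if len(children) < population:
                children.append(_poly_mutate(rng, c2, lo, hi))
        Fc, CVc = evaluate(children)
        pool = pop + children
        Fp = np.vstack([F, Fc])
        CVp = np.concatenate([CV, CVc])
        rank_p, crowd_p = rank_all(Fp, CVp)
        order = np.lexsort((-crowd_p, rank_p))[:population]
        pop = [pool[i] for i in order]
        F, CV = Fp[order], CVp[order]
        rank, crowd = rank_all(F, CV)

    pts = [ParetoPoint(p=pop[i], mu=F[i, 0], sigma=F[i, 1], tag="ga")
           for i in range(len(pop)) if CV[i] <= 1e-9 and np.isfinite(F[i, 0])]
    return ParetoFront(points=pts)


def multistart(problem: OptimizationProblem, n_starts: int, seed: int = 0,
               objective="mean", merge_radius: float = 1e-2):
    """Local optimization from random feasible starts, deduplicated in
    design space by ``merge_radius``."""
    if n_starts < 1:
        raise ValueError("need at least one start")
    rng = np.random.default_rng(seed)
    results: list[OptimResult] = []
    for _ in range(n_starts):
        x0 = _sample_feasible(problem, rng)
        try:
            res = local_optimize(problem, x0=x0, objective=objective)
        except ValueError:
            continue
        if not any(np.linalg.norm(res.p - r.p) < merge_radius for r in results):
            results.append(res)
    return sorted(results, key=lambda r: r.J)


def select_optimal(front: ParetoFront, band: float = 0.05) -> ParetoPoint:
    """A-priori near-vertex selection: among points whose mean lies within a
    relative ``band`` of the front's minimum mean, pick the one with the
    smallest standard deviation."""
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    mu_min = min(pt.mu for pt in front.points)
    shortlist = [pt for pt in front.points if pt.mu <= mu_min * (1.0 + band)]
    return min(shortlist, key=lambda pt: pt.sigma)
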