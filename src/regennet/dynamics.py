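"""Dynamic-model identification and AIC pruning of candidate interactions.

The expression level of a target protein i is modelled by the discrete-time
linear update

    x_i[t+1] = x_i[t] + sum_j a_ij x_j[t] - lambda_i x_i[t] + k_i + eps_i[t]

where the sum runs over the N_i candidate interactors of i, a_ij is the
interaction ability of interactor j on i, lambda_i in [0, 1] is the
per-step degradation, k_i >= 0 the basal production, and eps_i[t] noise.
Writing theta_i = (a_i1, ..., a_iN, 1 - lambda_i, k_i) this is a linear
regression of x_i[t+1] on the regression vector
phi_i[t] = (x_1[t], ..., x_N[t], x_i[t], 1); stacking the equations for
consecutive grid points gives X_i = Phi_i theta_i + E_i with M - 1 equations
on an M-point grid.

Because the regeneration time courses have very few observed time points,
the observed replicate means are first interpolated with a natural cubic
spline and the model is identified on a uniform dense grid; the discrete
step of the model is the grid step.  Parameters are estimated by bounded
least squares (1 - lambda_i in [0, 1], k_i >= 0, a_ij free), and the number
of retained interactions is selected by minimizing

    K_AIC(n) = log(RSS / n_eq) + 2 (n + 2) / n_eq

over a magnitude-ranked nested scan n = 0..N_i, where n_eq = M - 1 and the
+2 counts the self/degradation and basal parameters.  Everything in this
module is deterministic; all ties break lexicographically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import lsq_linear

from .candidate import CandidateNetwork, neighborhood
from .errors import ParameterError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

#: floor applied to RSS / n_eq before the log, so perfect fits stay finite
RSS_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DenseTrajectory:
    """Per-protein expression on a uniform dense time grid (one grid per
    condition, shared by every protein)."""

    protein_ids: tuple[str, ...]
    grid: np.ndarray
    values: np.ndarray  # (n_proteins, M)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", vals)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing 1-D")
        if vals.shape != (len(self.protein_ids), grid.size):
            raise ValueError("values shape must be (n_proteins, len(grid))")

    @property
    def n_points(self) -> int:
        return self.grid.size

    def row(self, protein: str) -> np.ndarray:
        try:
            i = self.protein_ids.index(protein)
        except ValueError:
            raise KeyError(protein) from None
        return self.values[i]


@dataclass(frozen=True)
class RegressionProblem:
    """Stacked per-target linear system.

    ``design`` has one row per grid step t = t_1 .. t_{M-1}, laid out as
    (x_1[t], ..., x_N[t], x_i[t], 1); ``response`` is (x_i[t_2], ...,
    x_i[t_M]).  The identifiability margin ``n_equations >= N_i + 2`` is
    enforced at construction (the dense-grid sizing rule guarantees it).
    """

    target_id: str
    interactor_ids: tuple[str, ...]
    response: np.ndarray
    design: np.ndarray

    def __post_init__(self) -> None:
        resp = np.asarray(self.response, dtype=float)
        des = np.asarray(self.design, dtype=float)
        object.__setattr__(self, "response", resp)
        object.__setattr__(self, "design", des)
        n = len(self.interactor_ids)
        if des.shape != (resp.size, n + 2):
            raise ValueError(
                f"design shape {des.shape} != ({resp.size}, {n + 2})"
            )
        if resp.size < n + 2:
            raise ValueError(
                f"{self.target_id}: {resp.size} equations cannot identify "
                f"{n + 2} parameters; use a denser grid"
            )

    @property
    def n_interactors(self) -> int:
        return len(self.interactor_ids)

    @property
    def n_equations(self) -> int:
        return self.response.size


@dataclass(frozen=True)
class ParameterEstimate:
    """Fitted model parameters for one target protein.

    ``abilities`` aligns with the problem's full interactor order; entries
    outside the fitted subset are exactly 0.  ``degenerate`` flags a
    rank-deficient active design, in which case the minimum-norm optimum is
    returned.
    """

    target_id: str
    interactor_ids: tuple[str, ...]
    abilities: np.ndarray
    degradation: float  # lambda_i in [0, 1]
    basal: float  # k_i >= 0
    residuals: np.ndarray
    fitted: np.ndarray
    subset: tuple[str, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.degradation <= 1.0:
            raise ValueError(f"lambda={self.degradation} outside [0, 1]")
        if self.basal < 0.0:
            raise ValueError(f"k={self.basal} negative")

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    def ability_of(self, interactor: str) -> float:
        return float(self.abilities[self.interactor_ids.index(interactor)])


@dataclass(frozen=True)
class AICSelection:
    """Result of the nested AIC scan for one target.

    ``aic_trace[n]`` is K_AIC of the top-n model, n = 0..N_i; the selected
    order is the argmin (smallest n on ties) and ``estimate`` is the refit
    on the retained subset.
    """

    target_id: str
    retained_interactors: tuple[str, ...]
    aic_trace: tuple[float, ...]
    selected_order: int
    estimate: ParameterEstimate

    def __post_init__(self) -> None:
        if len(self.retained_interactors) != self.selected_order:
            raise ValueError("retained set size must equal selected order")
        k = self.aic_trace[self.selected_order]
        if k > min(self.aic_trace) + 1e-12:
            raise ValueError("selected K_AIC is not the trace minimum")


@dataclass(frozen=True)
class RefinedNetwork:
    """AIC-pruned undirected network with per-direction abilities.

    ``abilities[(i, j)]`` is a_ij — the fitted ability of j on target i —
    for every direction some regression retained; an undirected edge may
    carry one or both directions.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    abilities: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        object.__setattr__(self, "abilities", dict(self.abilities))
        if self.nodes != {n for e in self.edges for n in e}:
            raise ValueError("nodes must be exactly the retained-edge endpoints")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, protein: str) -> int:
        return sum(1 for e in self.edges if protein in e)


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the per-condition inference run.

    m_points
        Dense grid size, or ``"auto"`` for
        ``max(densify_factor * n_observed_times, N_max + 6)`` where N_max is
        the largest candidate degree — this keeps the equation count at
        least N_i + 2 plus margin for every target.
    merge
        ``"union"`` keeps an undirected edge retained by either direction's
        regression; ``"both"`` requires both.
    """

    m_points: int | str = "auto"
    merge: str = "union"
    densify_factor: int = 4

    def __post_init__(self) -> None:
        if self.merge not in ("union", "both"):
            raise ValueError(f"merge must be 'union' or 'both', got {self.merge!r}")
        if isinstance(self.m_points, str) and self.m_points != "auto":
            raise ValueError(f"m_points must be an int or 'auto', got {self.m_points!r}")

    def resolve_m_points(self, n_observed: int, n_max_degree: int) -> int:
        if self.m_points == "auto":
            return max(self.densify_factor * n_observed, n_max_degree + 6)
        return int(self.m_points)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def spline_densify(matrix: ExpressionMatrix, m_points: int) -> DenseTrajectory:
    """Average replicates per time point and interpolate onto a uniform grid.

    A natural cubic spline (zero second derivative at both ends) is fit
    through the per-time-point replicate means of every protein and
    evaluated at ``m_points`` uniformly spaced times spanning exactly
    [t_first, t_last].  With only two observed time points the spline
    degenerates to linear interpolation (logged).
    """
    n_obs = matrix.design.n_times
    if m_points < n_obs:
        raise ParameterError(
            f"m_points={m_points} < {n_obs} observed time points"
        )
    t_obs = np.asarray(matrix.design.time_points)
    knots = matrix.replicate_means()  # (n_proteins, n_obs)
    grid = np.linspace(t_obs[0], t_obs[-1], m_points)
    if n_obs == 2:
        logger.info("only 2 observed time points: falling back to linear interpolation")
        frac = (grid - t_obs[0]) / (t_obs[1] - t_obs[0])
        dense = knots[:, [0]] + frac[None, :] * (knots[:, [1]] - knots[:, [0]])
    else:
        spline = CubicSpline(t_obs, knots, axis=1, bc_type="natural")
        dense = spline(grid)
    return DenseTrajectory(matrix.protein_ids, grid, dense)


def assemble_regression(
    target: str, interactors: Sequence[str], dense: DenseTrajectory
) -> RegressionProblem:
    """Build the stacked system X_i = Phi_i theta_i for one target.

    Design columns follow the given interactor order, then the target's own
    level, then the constant 1; rows are grid steps t_1 .. t_{M-1} and the
    response is the target's level one step ahead.
    """
    if target in interactors:
        raise ParameterError(f"target {target!r} listed among its own interactors")
    x_i = dense.row(target)
    cols = [dense.row(j)[:-1] for j in interactors]
    cols.append(x_i[:-1])
    cols.append(np.ones(dense.n_points - 1))
    design = np.column_stack(cols)
    return RegressionProblem(target, tuple(interactors), x_i[1:], design)


def _subset_columns(problem: RegressionProblem, subset: Sequence[str]) -> tuple[np.ndarray, list[int]]:
    idx = [problem.interactor_ids.index(j) for j in subset]
    keep = idx + [problem.n_interactors, problem.n_interactors + 1]
    return problem.design[:, keep], idx


def fit_constrained_ls(
    problem: RegressionProblem, subset: Sequence[str] | None = None
) -> ParameterEstimate:
    """Bounded least squares on a subset of the candidate interactors.

    Minimizes ||X_i - Phi_i^(subset) theta||^2 subject to the physical
    bounds 1 - lambda_i in [0, 1] and k_i >= 0 (interaction abilities are
    unconstrained).  The unconstrained solution is used directly when it is
    feasible; otherwise scipy's BVLS active-set solver handles the bounds.
    A rank-deficient active design yields the minimum-norm optimum and is
    flagged ``degenerate`` rather than raising.
    """
    if subset is None:
        subset = problem.interactor_ids
    subset = tuple(subset)
    a_sub, idx = _subset_columns(problem, subset)
    b = problem.response
    n_cols = a_sub.shape[1]

    degenerate = np.linalg.matrix_rank(a_sub) < n_cols
    theta, *_ = np.linalg.lstsq(a_sub, b, rcond=None)  # min-norm on deficiency
    # clip sub-roundoff bound violations instead of invoking the bounded solver
    eps = 1e-10
    if -eps <= theta[-2] <= 1.0 + eps and theta[-1] >= -eps:
        theta[-2] = min(max(theta[-2], 0.0), 1.0)
        theta[-1] = max(theta[-1], 0.0)
    else:
        lb = np.full(n_cols, -np.inf)
        ub = np.full(n_cols, np.inf)
        lb[-2], ub[-2] = 0.0, 1.0
        lb[-1] = 0.0
        try:
            res = lsq_linear(a_sub, b, bounds=(lb, ub), method="bvls")
        except Exception:  # bvls rejects some degenerate systems
            res = lsq_linear(a_sub, b, bounds=(lb, ub), method="trf")
        theta = res.x
        theta[-2] = min(max(theta[-2], 0.0), 1.0)
        theta[-1] = max(theta[-1], 0.0)

    fitted = a_sub @ theta
    residuals = b - fitted
    abilities = np.zeros(problem.n_interactors)
    abilities[idx] = theta[:-2]
    return ParameterEstimate(
        target_id=problem.target_id,
        interactor_ids=problem.interactor_ids,
        abilities=abilities,
        degradation=1.0 - theta[-2],
        basal=theta[-1],
        residuals=residuals,
        fitted=fitted,
        subset=subset,
        degenerate=bool(degenerate),
    )


def aic_score(estimate, n_params: int, n_equations: int) -> float:
    """K_AIC = log(RSS / n_eq) + 2 n_params / n_eq (natural log).

    ``estimate`` may be a :class:`ParameterEstimate` or a raw residual
    vector.  ``n_params`` counts retained interactions plus 2 (the
    self/degradation term and the basal level).  RSS / n_eq is floored at
    ``RSS_FLOOR`` so perfect fits score finitely.
    """
    if n_equations < 1:
        raise ParameterError("n_equations must be >= 1")
    resid = np.asarray(getattr(estimate, "residuals", estimate), dtype=float)
    rss = float(resid @ resid)
    return math.log(max(rss / n_equations, RSS_FLOOR)) + 2.0 * n_params / n_equations


def prune_by_aic(problem: RegressionProblem) -> AICSelection:
    """Select the interactor subset minimizing K_AIC by a nested scan.

    The full model is fit once and interactors ranked by |a_ij| descending
    (ties: lexicographic id).  For n = 0..N_i the top-n subset is refit and
    scored with n_params = n + 2; the smallest n attaining the minimum
    K_AIC wins.  O(N_i) fits; the exhaustive 2^N_i search is a test oracle
    only.
    """
    full = fit_constrained_ls(problem)
    ranked = sorted(
        problem.interactor_ids,
        key=lambda j: (-abs(full.ability_of(j)), j),
    )
    n_eq = problem.n_equations
    trace: list[float] = []
    estimates: list[ParameterEstimate] = []
    for n in range(problem.n_interactors + 1):
        est = fit_constrained_ls(problem, ranked[:n])
        estimates.append(est)
        trace.append(aic_score(est, n + 2, n_eq))
    selected = int(np.argmin(trace))  # argmin takes the smallest n on ties
    return AICSelection(
        target_id=problem.target_id,
        retained_interactors=tuple(ranked[:selected]),
        aic_trace=tuple(trace),
        selected_order=selected,
        estimate=estimates[selected],
    )


def infer_network(
    candidate: CandidateNetwork,
    matrix: ExpressionMatrix,
    config: InferenceConfig | None = None,
    return_selections: bool = False,
):
    """Run the per-target identification over a whole candidate network.

    The condition's trajectories are densified once; every candidate node is
    then regressed on its candidate neighborhood and pruned by AIC.  An
    undirected edge {i, j} is retained iff interactor j survived in the
    i-regression or i survived in the j-regression (``merge="union"``, the
    default) or in both (``merge="both"``).  Retained directions carry their
    fitted ability a_ij in the result.
    """
    config = config or InferenceConfig()
    missing = sorted(candidate.nodes - set(matrix.protein_ids))
    if missing:
        raise KeyError(
            f"candidate node(s) missing from the expression matrix: {missing}"
        )
    if not candidate.edges:
        refined = RefinedNetwork(frozenset(), frozenset(), {})
        return (refined, {}) if return_selections else refined

    nbrs = {i: neighborhood(candidate, i) for i in candidate.nodes}
    n_max = max(len(v) for v in nbrs.values())
    m_points = config.resolve_m_points(matrix.design.n_times, n_max)
    dense = spline_densify(matrix, m_points)

    selections: dict[str, AICSelection] = {}
    for i in sorted(candidate.nodes):
        problem = assemble_regression(i, nbrs[i], dense)
        selections[i] = prune_by_aic(problem)

    edges: set[tuple[str, str]] = set()
    abilities: dict[tuple[str, str], float] = {}
    for a, b in candidate.edges:
        in_a = b in selections[a].retained_interactors
        in_b = a in selections[b].retained_interactors
        keep = (in_a or in_b) if config.merge == "union" else (in_a and in_b)
        if not keep:
            continue
        edges.add((a, b))
        if in_a:
            abilities[(a, b)] = selections[a].estimate.ability_of(b)
        if in_b:
            abilities[(b, a)] = selections[b].estimate.ability_of(a)
    nodes = frozenset(n for e in edges for n in e)
    refined = RefinedNetwork(nodes, frozenset(edges), abilities)
    logger.info(
        "inference: %d/%d candidate edges retained (%d nodes)",
        len(edges),
        candidate.n_edges,
        len(nodes),
    )
    return (refined, selections) if return_selections else refined
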