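"""Independent brute-force / textbook oracles used by the test suite.

Each oracle re-derives an expected value by a different route than the
implementation under test: explicit tridiagonal algebra for natural cubic
splines, hand sums of squares for one-way ANOVA, exhaustive subset
enumeration for AIC model selection, and naive set/loop constructions for
the network operations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from regennet.dynamics import RegressionProblem, aic_score, fit_constrained_ls


def natural_spline_eval(x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Natural cubic spline via the textbook tridiagonal system.

    Solves for the knot second derivatives m_i with m_0 = m_{n-1} = 0 and
    h_{i-1} m_{i-1} + 2 (h_{i-1} + h_i) m_i + h_i m_{i+1}
        = 6 ((y_{i+1}-y_i)/h_i - (y_i-y_{i-1})/h_{i-1}),
    then evaluates the standard piecewise-cubic form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    h = np.diff(x)
    m = np.zeros(n)
    if n > 2:
        a = np.zeros((n - 2, n - 2))
        rhs = np.zeros(n - 2)
        for row, i in enumerate(range(1, n - 1)):
            if i - 1 >= 1:
                a[row, row - 1] = h[i - 1]
            a[row, row] = 2.0 * (h[i - 1] + h[i])
            if i + 1 <= n - 2:
                a[row, row + 1] = h[i]
            rhs[row] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
        m[1:-1] = np.linalg.solve(a, rhs)

    out = np.empty_like(np.asarray(xq, dtype=float))
    for idx, t in enumerate(np.atleast_1d(xq)):
        i = int(np.clip(np.searchsorted(x, t, side="right") - 1, 0, n - 2))
        hi = h[i]
        dx1 = x[i + 1] - t
        dx0 = t - x[i]
        out[idx] = (
            m[i] * dx1**3 / (6 * hi)
            + m[i + 1] * dx0**3 / (6 * hi)
            + (y[i] / hi - m[i] * hi / 6) * dx1
            + (y[i + 1] / hi - m[i + 1] * hi / 6) * dx0
        )
    return out


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA by explicit sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def exhaustive_aic_min(problem: RegressionProblem) -> float:
    """Minimum K_AIC over all 2^N interactor subsets (refit each)."""
    best = np.inf
    for n in range(problem.n_interactors + 1):
        for sub in combinations(problem.interactor_ids, n):
            est = fit_constrained_ls(problem, sub)
            best = min(best, aic_score(est, n + 2, problem.n_equations))
    return float(best)


def brute_force_neighbors(edges, node) -> tuple[str, ...]:
    out = set()
    for a, b in edges:
        if a == node:
            out.add(b)
        elif b == node:
            out.add(a)
    return tuple(sorted(out))


def brute_force_degrees(edges) -> dict[str, int]:
    deg: dict[str, int] = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg


def brute_force_projection(human_edges, pairs) -> set[tuple[str, str]]:
    """Exhaustive double loop over ortholog tuples for every human edge."""
    out = set()
    for h1, h2 in human_edges:
        for za, ha in pairs:
            for zb, hb in pairs:
                if (ha, hb) in ((h1, h2), (h2, h1)) and za != zb:
                    out.add(tuple(sorted((za, zb))))
    return out
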