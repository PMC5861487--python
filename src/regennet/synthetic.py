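"""Synthetic benchmark generation and edge-recovery scoring.

Generates ground-truth interaction networks, simulates their discrete-time
expression dynamics (the same linear update the inference module fits),
samples sparse noisy time courses with replicates, spikes the candidate
edge set with known false positives, and scores how well an inferred
network recovers the truth.  Every operation is fully deterministic given
its seed, so the whole pipeline can be exercised and regression-tested
without any external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .candidate import CandidateNetwork, candidate_from_edges
from .dynamics import RefinedNetwork
from .errors import GenerationError, ParameterError
from .io_formats import ExpressionMatrix, TimeDesign, _canonical_edge

Edge = tuple[str, str]

#: stability guard: spectral radius bound of the update matrix I + A - diag(lambda)
STABILITY_RADIUS = 1.05


@dataclass(frozen=True)
class GroundTruthModel:
    """A known dynamic interaction model to benchmark inference against.

    ``abilities[(i, j)]`` is the directed ability of j on target i; every
    undirected true edge carries both directions, drawn independently.
    ``x0`` is the initial expression level per node.
    """

    nodes: tuple[str, ...]
    true_edges: frozenset[Edge]
    abilities: dict[Edge, float]
    lam: dict[str, float]
    k: dict[str, float]
    x0: dict[str, float]
    noise_sigma: float
    seed: int
    stability_radius: float = STABILITY_RADIUS

    def __post_init__(self) -> None:
        for n, v in self.lam.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"lambda[{n}]={v} outside [0, 1]")
        for n, v in self.k.items():
            if v < 0.0:
                raise ValueError(f"k[{n}]={v} negative")
        for n, v in self.x0.items():
            if v < 0.0:
                raise ValueError(f"x0[{n}]={v} negative")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be >= 0")
        rho = spectral_radius(self)
        if rho > self.stability_radius:
            raise ValueError(
                f"update-matrix spectral radius {rho:.3f} > {self.stability_radius}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def update_matrix(self) -> np.ndarray:
        """W = I + A - diag(lambda) with A[i, j] = a_ij."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        w = np.eye(self.n_nodes)
        for (i, j), a in self.abilities.items():
            w[idx[i], idx[j]] += a
        for n, lv in self.lam.items():
            w[idx[n], idx[n]] -= lv
        return w

    def max_degree(self) -> int:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.true_edges:
            deg[a] += 1
            deg[b] += 1
        return max(deg.values()) if deg else 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": list(self.nodes),
            "true_edges": sorted(list(e) for e in self.true_edges),
            "abilities": [[i, j, a] for (i, j), a in sorted(self.abilities.items())],
            "lam": self.lam,
            "k": self.k,
            "x0": self.x0,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "stability_radius": self.stability_radius,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            nodes=tuple(d["nodes"]),
            true_edges=frozenset(tuple(e) for e in d["true_edges"]),
            abilities={(i, j): a for i, j, a in d["abilities"]},
            lam=d["lam"],
            k=d["k"],
            x0=d["x0"],
            noise_sigma=d["noise_sigma"],
            seed=d["seed"],
            stability_radius=d.get("stability_radius", STABILITY_RADIUS),
        )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Undirected-edge confusion counts of an inferred network vs truth."""

    true_positive: int
    false_positive: int
    false_negative: int
    precision: float
    recall: float
    f1: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.precision <= 1.0 and 0.0 <= self.recall <= 1.0):
            raise ValueError("precision/recall must lie in [0, 1]")


def spectral_radius(model: GroundTruthModel) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(model.update_matrix()))))


def _node_names(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"P{i + 1:0{width}d}" for i in range(n))


def generate_ground_truth(
    n_nodes: int,
    edge_density: float,
    a_range: tuple[float, float] = (0.1, 0.5),
    lam_range: tuple[float, float] = (0.0, 0.3),
    k_range: tuple[float, float] = (0.0, 1.0),
    x0_range: tuple[float, float] = (0.5, 1.5),
    noise_sigma: float = 0.0,
    seed: int = 0,
    max_attempts: int = 100,
    stability_radius: float = STABILITY_RADIUS,
) -> GroundTruthModel:
    """Sample an Erdos-Renyi ground-truth model with stable dynamics.

    Each unordered pair is an edge with probability ``edge_density``; each
    true edge carries two independent directed abilities with magnitude
    uniform in ``a_range`` and random sign.  Degradation, basal level and
    initial level are uniform in their ranges.  Models whose update matrix
    has spectral radius above ``stability_radius`` are resampled (up to
    ``max_attempts``) so trajectories stay bounded over the simulated
    horizon.  The default bound is conservative; dense well-connected
    models with sizeable abilities need a larger bound (with a shorter
    simulated horizon) to be realizable at all.
    """
    if not 0.0 < edge_density <= 1.0:
        raise ParameterError(f"edge_density must be in (0, 1], got {edge_density}")
    if a_range[0] < 0 or a_range[0] > a_range[1]:
        raise ParameterError(f"invalid a_range {a_range}")
    if not (0.0 <= lam_range[0] <= lam_range[1] <= 1.0):
        raise ParameterError(f"lam_range {lam_range} outside [0, 1]")
    if k_range[0] < 0 or k_range[0] > k_range[1]:
        raise ParameterError(f"invalid k_range {k_range}")

    nodes = _node_names(n_nodes)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        edges = frozenset(
            _canonical_edge(a, b)
            for a, b in combinations(nodes, 2)
            if rng.random() < edge_density
        )
        abilities: dict[Edge, float] = {}
        for a, b in sorted(edges):
            for i, j in ((a, b), (b, a)):
                mag = rng.uniform(*a_range)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                abilities[(i, j)] = sign * mag
        model = GroundTruthModel.__new__(GroundTruthModel)
        object.__setattr__(model, "nodes", nodes)
        object.__setattr__(model, "true_edges", edges)
        object.__setattr__(model, "abilities", abilities)
        object.__setattr__(model, "lam", {n: rng.uniform(*lam_range) for n in nodes})
        object.__setattr__(model, "k", {n: rng.uniform(*k_range) for n in nodes})
        object.__setattr__(model, "x0", {n: rng.uniform(*x0_range) for n in nodes})
        object.__setattr__(model, "noise_sigma", float(noise_sigma))
        object.__setattr__(model, "seed", int(seed))
        object.__setattr__(model, "stability_radius", float(stability_radius))
        if spectral_radius(model) <= stability_radius:
            model.__post_init__()  # run full validation
            return model
    raise GenerationError(
        f"stability guard unmet after {max_attempts} attempts; "
        f"try a smaller a_range or density"
    )


def simulate_trajectory(
    model: GroundTruthModel,
    dense_steps: int,
    seed: int | None = None,
    process_sigma: float | None = None,
) -> np.ndarray:
    """Iterate the update x[t+1] = W x[t] + k + eps on a dense_steps grid.

    Returns an (n_nodes, dense_steps) array; ``eps`` is i.i.d. Gaussian
    per node and step with sd ``process_sigma`` (defaults to the model's
    ``noise_sigma``).  With sigma = 0 the trajectory is deterministic.
    """
    sigma = model.noise_sigma if process_sigma is None else process_sigma
    rng = np.random.default_rng(model.seed if seed is None else seed)
    w = model.update_matrix()
    k = np.array([model.k[n] for n in model.nodes])
    x = np.array([model.x0[n] for n in model.nodes])
    traj = np.empty((model.n_nodes, dense_steps))
    traj[:, 0] = x
    for t in range(1, dense_steps):
        eps = rng.normal(0.0, sigma, model.n_nodes) if sigma > 0 else 0.0
        x = w @ x + k + eps
        traj[:, t] = x
    return traj


def simulate_expression(
    model: GroundTruthModel,
    design: TimeDesign,
    dense_steps: int,
    seed: int | None = None,
    process_sigma: float | None = None,
    measurement_sigma: float | None = None,
    clip_nonnegative: bool = False,
    condition_label: str = "",
) -> ExpressionMatrix:
    """Simulate a replicated, sparsely sampled expression matrix.

    The dynamics run on a uniform internal grid of ``dense_steps`` points
    spanning the design's time range; each design time point is read off at
    the nearest grid point and independent Gaussian measurement noise (sd
    defaults to the model's ``noise_sigma``) is added per replicate.  No
    clipping is applied by default — the model is linear and clipping would
    bias recovery benchmarks — but ``clip_nonnegative`` is available for
    realism demonstrations.
    """
    if dense_steps < design.n_times:
        raise ParameterError(
            f"dense_steps={dense_steps} < {design.n_times} design time points"
        )
    base_seed = model.seed if seed is None else seed
    traj = simulate_trajectory(model, dense_steps, seed=base_seed, process_sigma=process_sigma)
    grid = np.linspace(design.time_points[0], design.time_points[-1], dense_steps)
    idx = [int(np.argmin(np.abs(grid - t))) for t in design.time_points]

    m_sigma = model.noise_sigma if measurement_sigma is None else measurement_sigma
    rng = np.random.default_rng((base_seed, 1))  # decouple from process noise
    cols = []
    for time_i, n_rep in zip(idx, design.replicates):
        truth = traj[:, time_i]
        for _ in range(n_rep):
            noise = rng.normal(0.0, m_sigma, model.n_nodes) if m_sigma > 0 else 0.0
            cols.append(truth + noise)
    values = np.column_stack(cols)
    if clip_nonnegative:
        values = np.clip(values, 0.0, None)
    return ExpressionMatrix(model.nodes, design, values, condition_label)


def spike_false_positives(
    model: GroundTruthModel, fp_ratio: float, seed: int = 0
) -> CandidateNetwork:
    """Candidate network = true edges plus known-spurious absent pairs.

    ``round(fp_ratio * |true edges|)`` pairs are drawn uniformly without
    replacement from the absent pairs; their true abilities are identically
    zero, making them the false positives the AIC pruning must reject.
    """
    if fp_ratio < 0:
        raise ParameterError("fp_ratio must be >= 0")
    absent = sorted(
        _canonical_edge(a, b)
        for a, b in combinations(model.nodes, 2)
        if _canonical_edge(a, b) not in model.true_edges
    )
    n_spike = round(fp_ratio * len(model.true_edges))
    if n_spike > len(absent):
        raise ParameterError(
            f"requested {n_spike} spiked edges but only {len(absent)} pairs are absent"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(absent), size=n_spike, replace=False) if n_spike else []
    spiked = {absent[i] for i in picked}
    return candidate_from_edges(model.true_edges | spiked)


def evaluate_recovery(refined: RefinedNetwork, model: GroundTruthModel) -> RecoveryMetrics:
    """Score an inferred network against the ground truth (undirected).

    Conventions: precision = 1 when nothing was predicted, recall = 1 when
    there was nothing to find, F1 = 0 when precision + recall = 0.
    """
    pred = set(refined.edges)
    truth = set(model.true_edges)
    tp = len(pred & truth)
    fp = len(pred - truth)
    fn = len(truth - pred)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return RecoveryMetrics(tp, fp, fn, precision, recall, f1)
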