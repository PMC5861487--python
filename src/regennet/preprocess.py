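"""Expression preprocessing and differential-expression filtering.

The pipeline consumes matrices that are already on a comparable scale across
samples.  Platforms that ship vendor-normalized data (GCRMA, GeneChip
Operating System) arrive pre-normalized; for the rest, per-sample 75th
percentile scaling is applied here.  Differentially expressed proteins are
then selected by one-way fixed-effects ANOVA across time-point groups with a
Bonferroni-corrected threshold, giving the per-condition protein pool that
the candidate network is restricted to.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError, DesignError
from .io_formats import ExpressionMatrix, TimeDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinPool:
    """Differentially expressed proteins of one condition.

    ``protein_ids`` holds the retained proteins (raw ANOVA p below
    ``alpha / n_tests``); ``p_values`` holds the raw p-value of every tested
    protein, retained or not.
    """

    protein_ids: frozenset[str]
    p_values: Mapping[str, float]
    alpha: float
    n_tests: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_ids", frozenset(self.protein_ids))
        object.__setattr__(self, "p_values", dict(self.p_values))
        thr = self.threshold
        for pid in self.protein_ids:
            p = self.p_values[pid]
            if not (0.0 <= p < thr):
                raise ValueError(f"pooled protein {pid} has p={p} >= threshold {thr}")
        if any(not 0.0 <= p <= 1.0 for p in self.p_values.values()):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    def __contains__(self, protein: str) -> bool:
        return protein in self.protein_ids

    def __len__(self) -> int:
        return len(self.protein_ids)

    def to_frame(self) -> pd.DataFrame:
        """Pool table: protein_id, p_raw, p_bonferroni, retained."""
        rows = [
            (
                pid,
                p,
                min(p * self.n_tests, 1.0),
                pid in self.protein_ids,
            )
            for pid, p in sorted(self.p_values.items())
        ]
        return pd.DataFrame(rows, columns=["protein_id", "p_raw", "p_bonferroni", "retained"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, alpha: float, n_tests: int) -> "ProteinPool":
        retained = frozenset(df.loc[df["retained"].astype(bool), "protein_id"].astype(str))
        p_values = dict(zip(df["protein_id"].astype(str), df["p_raw"].astype(float)))
        return cls(retained, p_values, alpha, n_tests)


def percentile_normalize(matrix: ExpressionMatrix, q: float = 75.0) -> ExpressionMatrix:
    """Divide each sample column by its own q-th percentile (default 75th).

    The percentile uses linear interpolation between closest ranks (rank
    position ``(n-1) * q / 100``).  After normalization every column's q-th
    percentile equals 1, which makes the operation idempotent.
    """
    if not 0.0 < q <= 100.0:
        raise ValueError(f"percentile q must be in (0, 100], got {q}")
    scale = np.percentile(matrix.values, q, axis=0)
    bad = np.nonzero(scale <= 0.0)[0]
    if bad.size:
        labels = [matrix.design.sample_labels()[i] for i in bad]
        raise DegenerateSampleError(
            f"sample column(s) {labels} have non-positive {q:g}th percentile"
        )
    return matrix.with_values(matrix.values / scale)


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``; values must exceed ``-offset``."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if np.any(matrix.values <= -offset):
        raise ValueError(f"values <= {-offset} cannot be log2-transformed")
    return matrix.with_values(np.log2(matrix.values + offset))


def anova_filter(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_tests: int | None = None,
) -> ProteinPool:
    """One-way ANOVA across time-point groups with Bonferroni control.

    Replicates within a time point are the group observations; a protein is
    retained iff its raw p-value is below ``alpha / n_tests``.  ``n_tests``
    defaults to the number of proteins in the matrix (per-condition family).
    Proteins with zero total variance get p = 1 (flat probes are excluded,
    never an error).
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    design = matrix.design
    thin = [t for t, r in zip(design.time_points, design.replicates) if r < 2]
    if thin:
        raise DesignError(f"time points {thin} have fewer than 2 replicates")
    if n_tests is None:
        n_tests = matrix.n_proteins

    groups = [matrix.values[:, s].T for s in design.sample_slices()]  # (reps, n_prot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled below
        _, pvals = stats.f_oneway(*groups)
    pvals = np.atleast_1d(np.asarray(pvals, dtype=float))

    flat = matrix.values.var(axis=1) == 0.0
    n_flat = int(flat.sum())
    if n_flat:
        logger.info("%d zero-variance protein(s) assigned p = 1", n_flat)
    pvals = np.where(flat | ~np.isfinite(pvals), 1.0, pvals)

    p_values = dict(zip(matrix.protein_ids, pvals))
    threshold = alpha / n_tests
    retained = frozenset(pid for pid, p in p_values.items() if p < threshold)
    return ProteinPool(retained, p_values, alpha, n_tests)


def collapse_duplicates(
    protein_ids: Sequence[str],
    values: np.ndarray,
    p_values: Sequence[float],
    design: TimeDesign,
    condition_label: str = "",
) -> ExpressionMatrix:
    """Collapse probe-level rows sharing an identifier to a single row.

    Among rows with the same id the row with the smallest p-value wins; ties
    go to the first occurrence.  Row order of the survivors follows first
    occurrence.  Returns a duplicate-free :class:`ExpressionMatrix`.
    """
    values = np.asarray(values, dtype=float)
    if len(protein_ids) != values.shape[0] or len(p_values) != values.shape[0]:
        raise ValueError("protein_ids, values rows and p_values must align")
    best: dict[str, int] = {}
    order: list[str] = []
    for i, (pid, p) in enumerate(zip(protein_ids, p_values)):
        pid = str(pid)
        if pid not in best:
            best[pid] = i
            order.append(pid)
        elif p < p_values[best[pid]]:
            best[pid] = i
    keep = [best[pid] for pid in order]
    return ExpressionMatrix(tuple(order), design, values[keep], condition_label)
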