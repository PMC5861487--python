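"""Readers, writers and core container types for every external format.

All tabular files are UTF-8, tab-separated, with ``#`` comment lines ignored
(the BioGRID/ZFIN export convention).  Every reader/writer pair is a lossless
round trip on valid data, and readers never emit objects that violate the
container invariants: malformed input raises :class:`~regennet.errors.FormatError`.

Identifiers are case-sensitive opaque strings; no symbol normalization is
performed.  Missing expression values are not representable — rows containing
NA tokens are rejected with an error listing the offending proteins, because
the downstream dynamic-model fit has no missing-data mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL"}

#: default BioGRID tab-format symbol columns
BIOGRID_COL_A = "Official Symbol Interactor A"
BIOGRID_COL_B = "Official Symbol Interactor B"


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeDesign:
    """Sampling design of a time-course experiment.

    Parameters
    ----------
    time_points
        Strictly increasing sampling times in days post injury (dpi), e.g.
        ``(0, 0.25, 1, 3)`` for the heart/cerebellum regeneration series.
    replicates
        Number of replicate arrays per time point (each ``>= 1``).
    """

    time_points: tuple[float, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        reps = tuple(int(r) for r in self.replicates)
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(self, "replicates", reps)
        if len(tp) < 2:
            raise ValueError("a time design needs at least 2 time points")
        if len(reps) != len(tp):
            raise ValueError("replicates must give one count per time point")
        if any(t2 <= t1 for t1, t2 in zip(tp, tp[1:])):
            raise ValueError(f"time points must be strictly increasing, got {tp}")
        if any(r < 1 for r in reps):
            raise ValueError("every time point needs at least one replicate")

    @classmethod
    def uniform(cls, time_points: Iterable[float], replicates: int) -> "TimeDesign":
        tp = tuple(time_points)
        return cls(tp, (replicates,) * len(tp))

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    @property
    def n_samples(self) -> int:
        return sum(self.replicates)

    def sample_labels(self) -> list[str]:
        """Time-major column labels, e.g. ``t0_r1, t0_r2, t0.25_r1, ...``."""
        return [
            f"t{t:g}_r{r + 1}"
            for t, n in zip(self.time_points, self.replicates)
            for r in range(n)
        ]

    def sample_slices(self) -> list[slice]:
        """Column slice per time point, in time order."""
        out, start = [], 0
        for n in self.replicates:
            out.append(slice(start, start + n))
            start += n
        return out


@dataclass(frozen=True)
class ExpressionMatrix:
    """Protein x sample expression values with their sampling design.

    Columns are time-major: all replicates of the first time point, then all
    replicates of the second, and so on.  Values are finite reals; duplicate
    protein ids are rejected (collapse probe-level duplicates upstream with
    :func:`regennet.preprocess.collapse_duplicates`).
    """

    protein_ids: tuple[str, ...]
    design: TimeDesign
    values: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        ids = tuple(str(p) for p in self.protein_ids)
        object.__setattr__(self, "protein_ids", ids)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(set(ids)) != len(ids):
            dups = sorted({p for p in ids if ids.count(p) > 1})
            raise ValueError(f"duplicate protein ids: {dups}")
        if vals.ndim != 2 or vals.shape != (len(ids), self.design.n_samples):
            raise ValueError(
                f"values shape {vals.shape} != "
                f"({len(ids)}, {self.design.n_samples}) from design"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def row_index(self, protein: str) -> int:
        try:
            return self.protein_ids.index(protein)
        except ValueError:
            raise KeyError(protein) from None

    def replicate_means(self) -> np.ndarray:
        """(n_proteins, n_times) matrix of per-time-point replicate means."""
        return np.column_stack(
            [self.values[:, s].mean(axis=1) for s in self.design.sample_slices()]
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.protein_ids, self.design, values, self.condition_label)


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EdgeList:
    """Undirected edge set over opaque string identifiers.

    Edges are stored as lexicographically sorted 2-tuples; self-loops and
    orientation duplicates are not representable.
    """

    edges: frozenset[tuple[str, str]]
    id_space_label: str = ""

    def __post_init__(self) -> None:
        edges = frozenset(self.edges)
        object.__setattr__(self, "edges", edges)
        for e in edges:
            if len(e) != 2 or e[0] >= e[1]:
                raise ValueError(f"edge {e!r} is not a sorted, loop-free pair")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], id_space_label: str = ""
    ) -> "EdgeList":
        """Normalize raw pairs: sort endpoints, drop self-loops, deduplicate."""
        edges = set()
        n_loops = 0
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                n_loops += 1
                continue
            edges.add(_canonical_edge(a, b))
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        return cls(frozenset(edges), id_space_label)

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class OrthologMap:
    """Many-to-many (zebrafish_id, human_id) correspondence set."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def human_to_zebrafish(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for z, h in self.pairs:
            out.setdefault(h, set()).add(z)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kw
    )


def read_expression_table(
    path: str | Path, design: TimeDesign, condition_label: str = ""
) -> ExpressionMatrix:
    """Read a wide expression TSV (first column protein id, then one column
    per sample in time-major order matching *design*)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected an id column plus sample columns")
    n_samples = df.shape[1] - 1
    if n_samples != design.n_samples:
        raise FormatError(
            f"{path}: header promises {n_samples} sample columns but the design "
            f"implies {design.n_samples}"
        )
    ids = [str(v) for v in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        dups = sorted({p for p in ids if ids.count(p) > 1})
        raise FormatError(f"{path}: duplicate protein ids {dups}")

    raw = df.iloc[:, 1:]
    na_proteins = sorted(
        {ids[i] for i, j in zip(*np.where(raw.isin(_NA_TOKENS).to_numpy()))}
    )
    if na_proteins:
        raise FormatError(
            f"{path}: missing values are not representable; offending proteins: "
            f"{na_proteins}"
        )
    probe = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(probe))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at protein {ids[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    # astype parses with full precision (to_numeric's fast path does not)
    values = raw.astype(float).to_numpy()
    return ExpressionMatrix(tuple(ids), design, values, condition_label)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a wide expression TSV readable by :func:`read_expression_table`.

    Floats are printed with 17 significant digits so the round trip is exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\t" + "\t".join(matrix.design.sample_labels()) + "\n")
        for pid, row in zip(matrix.protein_ids, matrix.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists and ortholog maps
# ---------------------------------------------------------------------------


def read_ppi_edges(
    path: str | Path,
    dialect: str = "simple_tsv",
    col_a: str = BIOGRID_COL_A,
    col_b: str = BIOGRID_COL_B,
    id_space_label: str = "human",
) -> EdgeList:
    """Read an undirected edge list.

    ``simple_tsv`` takes the first two columns of a headered TSV; ``biogrid_tab``
    takes the named interactor-symbol columns of a BioGRID tab-format export.
    Orientation duplicates are merged and self-loops dropped (count logged).
    """
    df = _read_tsv(path)
    if dialect == "simple_tsv":
        if df.shape[1] < 2:
            raise FormatError(f"{path}: simple_tsv needs at least two columns")
        a, b = df.iloc[:, 0], df.iloc[:, 1]
    elif dialect == "biogrid_tab":
        missing = [c for c in (col_a, col_b) if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing symbol column(s) {missing}")
        a, b = df[col_a], df[col_b]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return EdgeList.from_pairs(zip(a, b), id_space_label)


def write_edges(edges: EdgeList, path: str | Path, header: tuple[str, str] = ("protein_a", "protein_b")) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for a, b in sorted(edges.edges):
            fh.write(f"{a}\t{b}\n")


def read_ortholog_map(
    path: str | Path,
    zebrafish_col: str | None = None,
    human_col: str | None = None,
) -> OrthologMap:
    """Read a ZFIN-style ortholog TSV.

    By default the first column is the zebrafish id and the second the human
    id; pass column names to select others.  Duplicated tuples collapse;
    many-to-many correspondences are preserved.
    """
    df = _read_tsv(path)
    if zebrafish_col is None and human_col is None:
        if df.shape[1] < 2:
            raise FormatError(f"{path}: ortholog table needs two columns")
        z, h = df.iloc[:, 0], df.iloc[:, 1]
    else:
        missing = [c for c in (zebrafish_col, human_col) if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing ortholog column(s) {missing}")
        z, h = df[zebrafish_col], df[human_col]
    return OrthologMap(frozenset((str(a), str(b)) for a, b in zip(z, h)))


def write_ortholog_map(orthologs: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("zebrafish_id\thuman_id\n")
        for z, h in sorted(orthologs.pairs):
            fh.write(f"{z}\t{h}\n")


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------


def write_network(network, path: str | Path, fmt: str = "tsv") -> None:
    """Write a candidate or refined network deterministically.

    TSV columns: ``protein_a, protein_b, a_ab, a_ba`` where ``a_ab`` is the
    fitted interaction ability with ``protein_a`` as the regression target
    (direction b -> a) and ``a_ba`` the reverse.  Ability columns are empty
    for candidate networks and for directions the model selection did not
    retain.  GraphML output carries the same content as edge attributes.
    Byte output is identical across writes of the same network.
    """
    edges = sorted(network.edges)
    abilities: Mapping[tuple[str, str], float] = getattr(network, "abilities", {}) or {}

    def fmt_a(target: str, source: str) -> str:
        v = abilities.get((target, source))
        return "" if v is None else f"{v:.17g}"

    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\ta_ab\ta_ba\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\t{fmt_a(a, b)}\t{fmt_a(b, a)}\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(getattr(network, "nodes", ()) or {n for e in edges for n in e}))
        for a, b in edges:
            attrs = {}
            if (a, b) in abilities:
                attrs["a_ab"] = abilities[(a, b)]
            if (b, a) in abilities:
                attrs["a_ba"] = abilities[(b, a)]
            g.add_edge(a, b, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network_tsv(path: str | Path) -> tuple[frozenset[tuple[str, str]], dict[tuple[str, str], float]]:
    """Read a network TSV written by :func:`write_network`.

    Returns the edge set and the per-direction ability map (``(target, source)
    -> a``; empty for candidate networks).
    """
    df = _read_tsv(path)
    required = {"protein_a", "protein_b"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    edges = set()
    abilities: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        edges.add(_canonical_edge(a, b))
        if "a_ab" in df.columns and row["a_ab"] != "":
            abilities[(a, b)] = float(row["a_ab"])
        if "a_ba" in df.columns and row["a_ba"] != "":
            abilities[(b, a)] = float(row["a_ba"])
    return frozenset(edges), abilities
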