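"""Candidate PPI network construction.

Zebrafish has no comprehensive experimentally measured interactome, so
candidate interactions are borrowed from the human one: every human PPI is
projected through the zebrafish-human ortholog table onto all corresponding
zebrafish identifier pairs (the interolog expansion), and the projected edge
set is then restricted to the condition's differentially expressed protein
pool.  The result deliberately over-states the true interactome — the
dynamic-model AIC pruning downstream is what rejects the false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .errors import ParameterError
from .io_formats import EdgeList, OrthologMap, _canonical_edge
from .preprocess import ProteinPool

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass(frozen=True)
class CandidateNetwork:
    """Ortholog-projected candidate interactions over a protein pool.

    ``provenance`` optionally records, per projected edge, the originating
    human edges; it is reporting metadata only and never enters inference.
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]
    provenance: Mapping[Edge, frozenset[Edge]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        touched = {n for e in self.edges for n in e}
        if touched != self.nodes:
            raise ValueError(
                "candidate nodes must be exactly the endpoints of its edges"
            )
        for a, b in self.edges:
            if a >= b:
                raise ValueError(f"edge ({a}, {b}) is not a sorted, loop-free pair")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, protein: str) -> int:
        return len(neighborhood(self, protein))


def map_orthologs(
    human_edges: EdgeList,
    orthologs: OrthologMap,
    return_provenance: bool = False,
):
    """Project human PPIs onto zebrafish ids through the ortholog map.

    Each human edge (H1, H2) expands to every pair (z_a, z_b) with
    (z_a, H1) and (z_b, H2) in the map (both assignments tried, since the
    edge is unordered).  Self-pairs after projection are dropped — the
    dynamic model already carries a self term, so a projected self-loop
    would alias with the degradation coefficient.  Human edges with an
    unmapped endpoint are dropped with a logged count.
    """
    h2z = orthologs.human_to_zebrafish()
    if not orthologs.pairs:
        logger.warning("empty ortholog map: projection is empty")
    projected: set[Edge] = set()
    provenance: dict[Edge, set[Edge]] = {}
    n_unmapped = 0
    for h1, h2 in human_edges.edges:
        z1s, z2s = h2z.get(h1), h2z.get(h2)
        if not z1s or not z2s:
            n_unmapped += 1
            continue
        for za in z1s:
            for zb in z2s:
                if za == zb:
                    continue
                e = _canonical_edge(za, zb)
                projected.add(e)
                if return_provenance:
                    provenance.setdefault(e, set()).add((h1, h2))
    if n_unmapped:
        logger.info("dropped %d human edge(s) without orthologs", n_unmapped)
    out = EdgeList(frozenset(projected), id_space_label="zebrafish")
    if return_provenance:
        return out, {e: frozenset(s) for e, s in provenance.items()}
    return out


def restrict_to_pool(
    edges: EdgeList,
    pool: ProteinPool | frozenset[str] | set[str],
    provenance: Mapping[Edge, frozenset[Edge]] | None = None,
) -> CandidateNetwork:
    """Keep edges whose BOTH endpoints are in the protein pool.

    Nodes of the result are exactly the endpoints of surviving edges;
    pool proteins without any surviving interaction are not nodes.
    """
    members = pool.protein_ids if isinstance(pool, ProteinPool) else frozenset(pool)
    kept = frozenset(e for e in edges.edges if e[0] in members and e[1] in members)
    nodes = frozenset(n for e in kept for n in e)
    prov = (
        {e: provenance[e] for e in kept if e in provenance}
        if provenance is not None
        else None
    )
    return CandidateNetwork(nodes, kept, prov)


def neighborhood(network: CandidateNetwork, protein: str) -> tuple[str, ...]:
    """Lexicographically sorted unique interactors of *protein*.

    The length of this tuple is the candidate interaction count N_i that the
    dynamic model of the target protein starts from.
    """
    if protein not in network.nodes:
        raise KeyError(f"protein {protein!r} is not a network node")
    nbrs = {b if a == protein else a for a, b in network.edges if protein in (a, b)}
    return tuple(sorted(nbrs))


def candidate_from_edges(edges, provenance=None) -> CandidateNetwork:
    """Build a CandidateNetwork from raw (already loop-free) edge pairs."""
    canon = frozenset(_canonical_edge(a, b) for a, b in edges)
    if any(a == b for a, b in canon):
        raise ParameterError("candidate edges may not contain self-loops")
    nodes = frozenset(n for e in canon for n in e)
    return CandidateNetwork(nodes, canon, provenance)
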