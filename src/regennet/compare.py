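"""Cross-condition network comparison: core, organ-specific, hubs.

Core proteins are the node-set intersection across all refined networks;
each condition's core network is its edge set induced on the core proteins
(same nodes, different edges per condition).  Organ-specific proteins are
the relative complement of one condition's node set with respect to the
union of all others.  Hubs are ranked by undirected degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .dynamics import RefinedNetwork
from .errors import ParameterError

Edge = tuple[str, str]


@dataclass(frozen=True)
class ComparisonResult:
    core_proteins: frozenset[str]
    core_networks: Mapping[str, frozenset[Edge]]
    specific_proteins: Mapping[str, frozenset[str]]
    hub_tables: Mapping[str, tuple[tuple[str, int], ...]]

    def counts(self) -> dict:
        return {
            "core_proteins": len(self.core_proteins),
            "core_network_edges": {k: len(v) for k, v in sorted(self.core_networks.items())},
            "specific_proteins": {k: len(v) for k, v in sorted(self.specific_proteins.items())},
        }


def core_proteins(networks: Sequence[RefinedNetwork]) -> frozenset[str]:
    """Intersection of the node sets of all networks (>= 2 required)."""
    if len(networks) < 2:
        raise ParameterError("core extraction needs at least 2 networks")
    core = set(networks[0].nodes)
    for net in networks[1:]:
        core &= net.nodes
    return frozenset(core)


def core_network(network: RefinedNetwork, core: frozenset[str] | set[str]) -> frozenset[Edge]:
    """Edges of *network* with both endpoints among the core proteins."""
    return frozenset(e for e in network.edges if e[0] in core and e[1] in core)


def specific_proteins(networks: Mapping[str, RefinedNetwork], focal: str) -> frozenset[str]:
    """Nodes of the focal network absent from every other network."""
    if focal not in networks:
        raise KeyError(f"unknown network {focal!r}")
    if len(networks) < 2:
        raise ParameterError("specific-protein extraction needs at least 2 networks")
    others: set[str] = set()
    for name, net in networks.items():
        if name != focal:
            others |= net.nodes
    return frozenset(networks[focal].nodes - others)


def hub_ranking(network: RefinedNetwork, top_k: int) -> tuple[tuple[str, int], ...]:
    """Top-k proteins by undirected degree, ties broken alphabetically."""
    if top_k < 1:
        raise ParameterError("top_k must be positive")
    degrees: dict[str, int] = {n: 0 for n in network.nodes}
    for a, b in network.edges:
        degrees[a] += 1
        degrees[b] += 1
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(ranked[:top_k])


def compare_networks(networks: Mapping[str, RefinedNetwork], top_k: int = 10) -> ComparisonResult:
    """Run the full comparison over named refined networks."""
    names = list(networks)
    core = core_proteins([networks[n] for n in names])
    return ComparisonResult(
        core_proteins=core,
        core_networks={n: core_network(networks[n], core) for n in names},
        specific_proteins={n: specific_proteins(networks, n) for n in names},
        hub_tables={n: hub_ranking(networks[n], top_k) for n in names},
    )


def write_comparison(result: ComparisonResult, out_dir: str | Path) -> None:
    """Write core_proteins.txt, core_<name>.tsv, specific_<name>.txt,
    hubs_<name>.tsv and summary.json under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "core_proteins.txt").write_text(
        "".join(f"{p}\n" for p in sorted(result.core_proteins)), encoding="utf-8"
    )
    for name, edges in result.core_networks.items():
        with open(out / f"core_{name}.tsv", "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in sorted(edges):
                fh.write(f"{a}\t{b}\n")
    for name, prots in result.specific_proteins.items():
        (out / f"specific_{name}.txt").write_text(
            "".join(f"{p}\n" for p in sorted(prots)), encoding="utf-8"
        )
    for name, table in result.hub_tables.items():
        with open(out / f"hubs_{name}.tsv", "w", encoding="utf-8") as fh:
            fh.write("protein_id\tdegree\n")
            for pid, deg in table:
                fh.write(f"{pid}\t{deg}\n")
    (out / "summary.json").write_text(
        json.dumps(result.counts(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
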