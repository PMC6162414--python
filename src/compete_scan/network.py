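"""Bipartite RBP-miRNA competition network of significant pairs.

RBPs and miRNAs are nodes; an edge joins an RBP and a miRNA whose binding
sites co-occur significantly more often than expected under the shuffle
null. Nodes exist only through edges, so the graph is strictly bipartite
with no isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .overlap_stats import PairKey, PairTestResult


@dataclass
class CompetitionNetwork:
    """Bipartite graph wrapper; RBP side = 0, miRNA side = 1."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def rbp_nodes(self) -> set[str]:
        return {
            d["label"] for _, d in self.graph.nodes(data=True)
            if d["side"] == "rbp"
        }

    @property
    def mirna_nodes(self) -> set[str]:
        return {
            d["label"] for _, d in self.graph.nodes(data=True)
            if d["side"] == "mirna"
        }

    @property
    def edges(self) -> set[PairKey]:
        out = set()
        nodes = self.graph.nodes
        for u, v in self.graph.edges():
            if nodes[u]["side"] == "rbp":
                out.add(PairKey(nodes[u]["label"], nodes[v]["label"]))
            else:
                out.add(PairKey(nodes[v]["label"], nodes[u]["label"]))
        return out

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _node_id(name: str, side: str) -> str:
    # namespace the two sides so an RBP and a miRNA sharing a name cannot
    # collapse into one node
    return f"{side}:{name}"


def build_network(significant: Sequence[PairTestResult]) -> CompetitionNetwork:
    """One edge per significant (RBP, miRNA) pair, annotated with q and O."""
    g = nx.Graph()
    seen: set[PairKey] = set()
    for res in significant:
        if res.key in seen:
            raise ValueError(f"duplicate pair {res.key} in significant set")
        seen.add(res.key)
        u = _node_id(res.key.rbp_name, "rbp")
        v = _node_id(res.key.mirna_name, "mirna")
        g.add_node(u, side="rbp", label=res.key.rbp_name)
        g.add_node(v, side="mirna", label=res.key.mirna_name)
        g.add_edge(
            u, v,
            qvalue=float(res.qvalue) if res.qvalue is not None else float("nan"),
            pvalue=float(res.pvalue),
            observed=int(res.observed),
        )
    return CompetitionNetwork(g)


def network_summary(net: CompetitionNetwork, n_hubs: int = 5) -> dict:
    """Node/edge counts, degrees, hubs, components and connectivity fraction.

    The largest-component fraction is computed over nodes. Degree ties in
    hub reporting are broken lexicographically for determinism.
    """
    g = net.graph
    degrees = {d["label"]: g.degree(n) for n, d in g.nodes(data=True)}
    rbp_deg = {
        d["label"]: g.degree(n)
        for n, d in g.nodes(data=True) if d["side"] == "rbp"
    }
    mir_deg = {
        d["label"]: g.degree(n)
        for n, d in g.nodes(data=True) if d["side"] == "mirna"
    }

    def hubs(deg: dict[str, int]) -> list[tuple[str, int]]:
        return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))[:n_hubs]

    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    n_nodes = g.number_of_nodes()
    return {
        "n_rbps": len(rbp_deg),
        "n_mirnas": len(mir_deg),
        "n_nodes": n_nodes,
        "n_edges": g.number_of_edges(),
        "degree": degrees,
        "rbp_hubs": hubs(rbp_deg),
        "mirna_hubs": hubs(mir_deg),
        "n_components": len(components),
        "components": components,
        "largest_component_fraction": (
            len(components[0]) / n_nodes if n_nodes else 0.0
        ),
    }


def export_network(net: CompetitionNetwork, path, format: str = "graphml"):
    """Write the network as GraphML, SIF or a TSV edge list."""
    g = net.graph
    if format == "graphml":
        nx.write_graphml(g, str(path))
    elif format == "sif":
        with open(path, "w") as fh:
            for key in sorted(net.edges):
                fh.write(f"{key.rbp_name}\tcompetes\t{key.mirna_name}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("rbp\tmirna\tobserved\tpvalue\tqvalue\n")
            for key in sorted(net.edges):
                data = g.edges[_node_id(key.rbp_name, "rbp"),
                               _node_id(key.mirna_name, "mirna")]
                fh.write(
                    f"{key.rbp_name}\t{key.mirna_name}\t{data['observed']}\t"
                    f"{data['pvalue']:.6g}\t{data['qvalue']:.6g}\n"
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_graphml(path) -> CompetitionNetwork:
    """Read a network previously written by :func:`export_network`."""
    return CompetitionNetwork(nx.read_graphml(str(path)))
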