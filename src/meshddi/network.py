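"""Weighted term networks for a drug pair.

For a query drug and one of its selected interaction partners, the
network is built on the DDI-related (group A) articles that also mention
the partner: nodes are the two drugs, the selected protein and phenomena
terms and the interaction-type descriptors present in that article
subset; an edge connects two terms when they co-occur in at least
``min_weight`` of those articles, weighted by the co-occurrence count.
Exports as GraphML (with category/color attributes) or an edge-list TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from ._text import norm_term
from .cooccur import build_adjacency, build_incidence
from .corpus import INTERACTION_TERMS, PartitionedCorpus
from .vocab import TermCategory

logger = logging.getLogger(__name__)

__all__ = ["TermNetwork", "build_pair_network", "export_graph", "import_graphml",
           "CATEGORY_COLORS"]

#: Display colors by node category.
CATEGORY_COLORS = {
    "drug": "red",
    "protein": "blue",
    "phenomena": "green",
    "interaction": "orange",
}


@dataclass
class TermNetwork:
    """Nodes (term, category), weighted edges and build provenance."""

    nodes: list[tuple[str, str]] = field(default_factory=list)
    edges: list[tuple[str, str, int]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {t for t, _ in self.nodes}
        for u, v, w in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on ({u!r}, {v!r})")
            if u not in names or v not in names:
                raise ValueError(f"edge endpoint not in node list: ({u!r}, {v!r})")

    def canonical(self) -> "TermNetwork":
        """Sorted-node/edge, string-provenance form (stable across round trips)."""
        return TermNetwork(
            nodes=sorted(self.nodes),
            edges=sorted((min(u, v), max(u, v), int(w)) for u, v, w in self.edges),
            provenance={k: str(v) for k, v in self.provenance.items()},
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(**{k: str(v) for k, v in self.provenance.items()})
        for term, cat in self.nodes:
            g.add_node(term, category=cat, color=CATEGORY_COLORS.get(cat, "gray"))
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=int(w))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "TermNetwork":
        nodes = sorted((n, d.get("category", "other")) for n, d in g.nodes(data=True))
        edges = sorted(
            (min(u, v), max(u, v), int(d["weight"])) for u, v, d in g.edges(data=True)
        )
        provenance = {
            k: v for k, v in g.graph.items()
            if k not in ("node_default", "edge_default")
        }
        return cls(nodes=nodes, edges=edges, provenance=provenance)


def build_pair_network(
    corpus: PartitionedCorpus,
    partner_drug: str,
    selected_terms: Mapping[TermCategory | str, Iterable[str]],
    min_weight: int = 2,
    interaction_terms: Sequence[str] = INTERACTION_TERMS,
) -> TermNetwork:
    """Build the term network for the (query drug, partner drug) pair.

    The article subset is group A restricted to articles mentioning the
    partner drug (they carry an interaction descriptor by construction).
    ``selected_terms`` maps categories to the enrichment-selected
    descriptors; protein and phenomena entries become nodes.  Edges with
    co-occurrence count below ``min_weight`` are dropped.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be a positive integer")
    partner_key = norm_term(partner_drug)
    subset = [a for a in corpus.group_a if partner_key in a.descriptor_set()]
    provenance = {
        "query_drug": corpus.drug or "",
        "partner_drug": partner_drug,
        "n_articles": len(subset),
        "min_weight": min_weight,
    }
    if not subset:
        logger.warning(
            "partner drug %r absent from every group A article; empty network",
            partner_drug,
        )
        return TermNetwork(provenance=provenance)

    def bucket(cat: TermCategory) -> list[str]:
        for key, terms in selected_terms.items():
            if TermCategory(key) is cat:
                return sorted(set(terms))
        return []

    present = set()
    for art in subset:
        present |= art.descriptor_set()
    interactions = [t for t in interaction_terms if norm_term(t) in present]

    nodes: list[tuple[str, str]] = []
    seen: set[str] = set()
    for term, cat in (
        [(corpus.drug, "drug")] if corpus.drug else []
    ) + [(partner_drug, "drug")] + [
        (t, "protein") for t in bucket(TermCategory.PROTEIN)
    ] + [
        (t, "phenomena") for t in bucket(TermCategory.PHENOMENA)
    ] + [
        (t, "interaction") for t in interactions
    ]:
        key = norm_term(term)
        if key not in seen:
            seen.add(key)
            nodes.append((term, cat))

    names = [t for t, _ in nodes]
    adj = build_adjacency(build_incidence(subset, names))
    edges = [
        (names[i], names[j], int(adj[i, j]))
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if adj[i, j] >= min_weight
    ]
    return TermNetwork(nodes=nodes, edges=edges, provenance=provenance)


def export_graph(network: TermNetwork, fmt: str, dest) -> None:
    """Serialize as ``graphml`` or ``edgelist`` (TSV: source, target, weight)."""
    if fmt == "graphml":
        nx.write_graphml(network.to_networkx(), dest)
    elif fmt in ("edgelist", "tsv"):
        own = not hasattr(dest, "write")
        handle = Path(dest).open("w", encoding="utf-8") if own else dest
        try:
            handle.write("source\ttarget\tweight\n")
            for u, v, w in network.edges:
                handle.write(f"{u}\t{v}\t{w}\n")
        finally:
            if own:
                handle.close()
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def import_graphml(source) -> TermNetwork:
    """Read a GraphML export back into a :class:`TermNetwork`."""
    return TermNetwork.from_networkx(nx.read_graphml(source))
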