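"""Gene Ontology DAG container with OBO round-trip.

Terms are held in a :class:`networkx.DiGraph` whose edges point from child to
parent along ``is_a`` relations.  Only a single namespace is kept (biological
process by default), with exactly one root — the term with no outgoing
``is_a`` edge.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import ConfigurationError

__all__ = ["GODag"]


class GODag:
    """A rooted, acyclic ``is_a`` hierarchy of GO terms.

    Parameters
    ----------
    graph
        Directed graph with child -> parent edges. Node attributes may carry
        ``name`` and ``namespace``.
    namespace
        Namespace tag recorded for terms lacking one.
    """

    def __init__(self, graph: nx.DiGraph, namespace: str = "biological_process"):
        if not isinstance(graph, nx.DiGraph):
            graph = nx.DiGraph(graph)
        if graph.number_of_nodes() == 0:
            raise ConfigurationError("empty ontology")
        if not nx.is_directed_acyclic_graph(graph):
            raise ConfigurationError("ontology graph contains a cycle")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise ConfigurationError(f"expected a single root term, found {len(roots)}")
        self.graph = graph
        self.namespace = namespace
        self.root = roots[0]

    # -- construction ------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
        namespace: str = "biological_process",
    ) -> "GODag":
        """Build a DAG from (child, parent) ``is_a`` pairs."""
        g = nx.DiGraph()
        g.add_edges_from(edges)
        for t in g.nodes:
            g.nodes[t]["name"] = (names or {}).get(t, t)
            g.nodes[t]["namespace"] = namespace
        return cls(g, namespace=namespace)

    @classmethod
    def from_obo(cls, path: str | os.PathLike, namespace: str = "biological_process") -> "GODag":
        """Load an OBO file, keeping ``is_a`` edges of one namespace."""
        raw = obonet.read_obo(str(path))
        g = nx.DiGraph()
        for term, data in raw.nodes(data=True):
            if data.get("namespace", namespace) != namespace:
                continue
            g.add_node(term, name=data.get("name", term), namespace=namespace)
        for child, parent, key in raw.edges(keys=True):
            if key == "is_a" and child in g and parent in g:
                g.add_edge(child, parent)
        return cls(g, namespace=namespace)

    def to_obo(self, path: str | os.PathLike) -> Path:
        """Write the DAG as a minimal OBO 1.2 document."""
        path = Path(path)
        lines = ["format-version: 1.2", ""]
        for term in sorted(self.graph.nodes):
            data = self.graph.nodes[term]
            lines += [
                "[Term]",
                f"id: {term}",
                f"name: {data.get('name', term)}",
                f"namespace: {data.get('namespace', self.namespace)}",
            ]
            lines += [f"is_a: {p}" for p in sorted(self.graph.successors(term))]
            lines.append("")
        path.write_text("\n".join(lines))
        return path

    # -- queries -----------------------------------------------------------
    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via ``is_a``, excluding ``term`` itself."""
        return set(nx.descendants(self.graph, term))

    def topological_children_first(self) -> list[str]:
        """Terms ordered so every child precedes all of its ancestors."""
        return list(nx.topological_sort(self.graph))

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()
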