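"""Gene-set collections with a parent-child DAG (GO-style term hierarchy)."""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import networkx as nx


class GeneSetCollection:
    """Term -> gene-id sets plus an acyclic child->parent hierarchy.

    Terms named only by DAG edges (absent from the GMT) are kept as
    structure-only nodes with an empty gene set.
    """

    def __init__(
        self,
        terms: Mapping[str, Iterable[str]],
        dag_parents: Optional[Mapping[str, Iterable[str]]] = None,
        namespace: str = "BP",
        descriptions: Optional[Mapping[str, str]] = None,
    ):
        self.terms: dict[str, frozenset[str]] = {t: frozenset(g) for t, g in terms.items()}
        self.namespace = namespace
        self.descriptions = dict(descriptions or {})
        self.dag_parents: dict[str, tuple[str, ...]] = {}
        graph = nx.DiGraph()  # edge child -> parent
        graph.add_nodes_from(self.terms)
        if dag_parents:
            for child, parents in dag_parents.items():
                parents = tuple(parents)
                self.dag_parents[child] = parents
                for p in parents:
                    for node in (child, p):
                        if node not in self.terms:
                            warnings.warn(
                                f"DAG term {node!r} absent from gene sets; kept as structure-only node"
                            )
                            self.terms.setdefault(node, frozenset())
                    graph.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"term hierarchy contains a cycle: {cycle}")
        self._graph = graph

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id]

    def size(self, term_id: str, universe: Optional[frozenset[str]] = None) -> int:
        genes = self.terms[term_id]
        return len(genes if universe is None else genes & universe)

    # -- DAG queries (edges run child -> parent) ---------------------------

    def parents(self, term_id: str) -> set[str]:
        return set(self._graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self._graph.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        return set(nx.descendants(self._graph, term_id))

    def offspring(self, term_id: str) -> set[str]:
        return set(nx.ancestors(self._graph, term_id))

    def siblings(self, term_id: str) -> set[str]:
        """Terms sharing at least one parent (excluding the term itself)."""
        sibs: set[str] = set()
        for p in self.parents(term_id):
            sibs |= self.children(p)
        sibs.discard(term_id)
        return sibs

    def leaves(self, within: Optional[Iterable[str]] = None) -> set[str]:
        """Terms with no children (optionally: no children within a subset)."""
        if within is None:
            return {t for t in self.terms if not self.children(t)}
        within = set(within)
        return {t for t in within if not (self.children(t) & within)}

    def filter_by_size(
        self, min_size: int, max_size: int, universe: Optional[frozenset[str]] = None
    ) -> list[str]:
        return [
            t for t in self.term_ids() if min_size <= self.size(t, universe) <= max_size
        ]
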