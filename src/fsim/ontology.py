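"""Ontology DAG loading, level assignment, and level coefficients (LC).

A hierarchical ontology such as the Gene Ontology (GO) is a set of rooted
directed acyclic graphs (one per namespace: biological process, cellular
component, molecular function).  Each term sits at a *level* — here the
length of the longest directed path from its namespace root — and carries a
*level coefficient* in [0, 1]: leaves get LC = 1, roots get LC = 0, and an
internal term averages its children's coefficients scaled by the ratio of
its own level to each child's level,

    LC_i = (1/n) * sum_j  LC_{c_j} * Level(term_i) / Level(c_j)

evaluated from the leaves towards the root.  Because longest-path levels
strictly increase along every parent->child edge, every ratio is < 1 and
the coefficients stay within [0, 1].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

VALID_RELATIONS = frozenset({"is_a", "part_of", "regulates"})

#: namespace labels recognised from OBO files; anything else maps to "custom"
_NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
    "BP": "BP",
    "CC": "CC",
    "MF": "MF",
}


class OntologyError(ValueError):
    """Raised for malformed, cyclic, or disconnected ontology input."""


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str = ""
    namespace: str = "custom"
    is_obsolete: bool = False


@dataclass
class OntologyDAG:
    """Rooted DAG of ontology terms with per-term level and LC.

    ``graph`` holds parent -> child edges (children point *away* from the
    root).  ``level`` and ``lc`` are filled by :func:`assign_levels` and
    :func:`compute_lc`.
    """

    graph: nx.DiGraph
    terms: dict[str, Term]
    level: dict[str, int] = field(default_factory=dict)
    lc: dict[str, float] = field(default_factory=dict)
    # ancestor sets are requested millions of times during benchmarking;
    # cache assumes the graph is not mutated after loading
    _anc_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    # -- structure ---------------------------------------------------------
    @property
    def roots(self) -> list[str]:
        """Terms with no parents, one per namespace in a well-formed DAG."""
        return sorted(t for t in self.graph.nodes if self.graph.in_degree(t) == 0)

    def namespaces(self) -> list[str]:
        return sorted({t.namespace for t in self.terms.values()})

    def children(self, term_id: str) -> set[str]:
        return set(self.graph.successors(term_id))

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.predecessors(term_id))

    def is_leaf(self, term_id: str) -> bool:
        return self.graph.out_degree(term_id) == 0

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive closure over parent edges, excluding the term itself."""
        cached = self._anc_cache.get(term_id)
        if cached is None:
            if term_id not in self.graph:
                raise KeyError(f"unknown term: {term_id}")
            cached = frozenset(nx.ancestors(self.graph, term_id))
            self._anc_cache[term_id] = cached
        return set(cached)

    def descendants(self, term_id: str) -> set[str]:
        if term_id not in self.graph:
            raise KeyError(f"unknown term: {term_id}")
        return set(nx.descendants(self.graph, term_id))

    def terms_in_namespace(self, namespace: str) -> set[str]:
        return {tid for tid, t in self.terms.items() if t.namespace == namespace}

    # -- export ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Table of term_id, namespace, level, lc (sorted by term_id)."""
        rows = [
            {
                "term_id": tid,
                "namespace": term.namespace,
                "level": self.level.get(tid),
                "lc": self.lc.get(tid),
            }
            for tid, term in sorted(self.terms.items())
        ]
        return pd.DataFrame(rows, columns=["term_id", "namespace", "level", "lc"])

    def write_lc_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loading


def _validate_acyclic(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        member = cycle[0][0]
        raise OntologyError(f"ontology graph contains a cycle through {member!r}")


def _finalize(
    graph: nx.DiGraph, terms: dict[str, Term], compute: bool
) -> OntologyDAG:
    _validate_acyclic(graph)
    dag = OntologyDAG(graph=graph, terms=terms)
    if compute:
        assign_levels(dag)
        compute_lc(dag)
    return dag


def load_obo(
    path: str | Path | io.TextIOBase,
    relations: Iterable[str] = VALID_RELATIONS,
    compute: bool = True,
) -> OntologyDAG:
    """Load an OBO 1.2 flat file into an :class:`OntologyDAG`.

    ``relations`` selects which edge types to keep (``is_a`` plus any
    ``relationship:`` tags); all selected relations are merged into a single
    parent -> child edge set and treated identically.  Obsolete terms are
    dropped together with their edges.  With ``compute=True`` levels and LC
    values are assigned immediately.
    """
    relations = set(relations)
    bad = relations - VALID_RELATIONS
    if bad:
        raise OntologyError(f"unsupported relations: {sorted(bad)}")
    try:
        raw = obonet.read_obo(path, ignore_obsolete=True)
    except OSError:
        raise
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise OntologyError(f"malformed OBO file {path}: {exc}") from exc

    graph = nx.DiGraph()
    terms: dict[str, Term] = {}
    for node, data in raw.nodes(data=True):
        ns = _NAMESPACE_ALIASES.get(data.get("namespace", ""), "custom")
        terms[node] = Term(term_id=node, name=data.get("name", ""), namespace=ns)
        graph.add_node(node)
    # obonet edges run child -> parent with the relation as key; flip them.
    for child, parent, rel in raw.edges(keys=True):
        if rel in relations and parent in terms and child in terms:
            graph.add_edge(parent, child)
    return _finalize(graph, terms, compute)


def load_edge_list(
    path: str | Path | io.TextIOBase,
    compute: bool = True,
    namespace: str = "custom",
) -> OntologyDAG:
    """Load a parent_id/child_id/relation TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"parent_id", "child_id"}
    if not required <= set(df.columns):
        raise OntologyError(
            f"edge list must have columns parent_id, child_id; got {list(df.columns)}"
        )
    graph = nx.DiGraph()
    terms: dict[str, Term] = {}
    for _, row in df.iterrows():
        p, c = row["parent_id"], row["child_id"]
        for tid in (p, c):
            if tid not in terms:
                terms[tid] = Term(term_id=tid, namespace=namespace)
                graph.add_node(tid)
        graph.add_edge(p, c)
    return _finalize(graph, terms, compute)


# ---------------------------------------------------------------------------
# levels and level coefficients


def assign_levels(dag: OntologyDAG) -> OntologyDAG:
    """Assign each term the length of the LONGEST path from its root.

    Longest-path depth guarantees level(parent) < level(child) on every
    edge, which keeps every level ratio in the LC recursion below 1.
    Terms unreachable from any root are rejected.
    """
    graph = dag.graph
    roots = dag.roots
    order = list(nx.topological_sort(graph))
    level: dict[str, int] = {r: 0 for r in roots}
    for node in order:
        if node not in level:
            continue
        for child in graph.successors(node):
            level[child] = max(level.get(child, 0), level[node] + 1)
    orphans = sorted(set(graph.nodes) - set(level))
    if orphans:
        raise OntologyError(f"terms unreachable from any root: {orphans}")
    dag.level = level
    return dag


def compute_lc(dag: OntologyDAG) -> OntologyDAG:
    """Compute the level coefficient of every term, leaves to root.

    Processing in reverse topological order guarantees every child's LC
    exists before its parents are evaluated; the result is a pure function
    of the DAG, independent of tie order among same-level terms.
    """
    if not dag.level:
        assign_levels(dag)
    graph, level = dag.graph, dag.level
    lc: dict[str, float] = {}
    for node in reversed(list(nx.topological_sort(graph))):
        kids = list(graph.successors(node))
        if not kids:
            lc[node] = 1.0
        else:
            lc[node] = sum(lc[c] * level[node] / level[c] for c in kids) / len(kids)
    dag.lc = lc
    return dag


def ancestors(dag: OntologyDAG, term_id: str) -> set[str]:
    """Module-level alias for :meth:`OntologyDAG.ancestors`."""
    return dag.ancestors(term_id)


def lc_vector(dag: OntologyDAG, universe: list[str]) -> "pd.Series":
    """LC weights aligned to an ordered term universe."""
    return pd.Series([dag.lc[t] for t in universe], index=universe, dtype=float)
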