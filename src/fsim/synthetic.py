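"""Deterministic generators for toy ontologies and planted-module annotations.

These stand in for the real ontology + pathway databases during testing:
a random rooted DAG per namespace emulates the term hierarchy, genes are
partitioned into functional modules that each own a coherent subtree of
terms, and member genes draw their direct annotations from the module
subtree with a configurable probability of off-module noise.  The planted
module memberships serve as ground-truth "pathways" for the benchmark
harness — with low noise a similarity method should recover members with
AUC well above chance, and at noise 1 the membership is uninformative.

Everything is a pure function of (spec, seed): rerunning a generator with
the same spec yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .annotation import AnnotationSet, make_annotation_set
from .ontology import OntologyDAG, Term, assign_levels, compute_lc


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator knobs; defaults give a small three-namespace benchmark."""

    seed: int = 42
    n_terms_per_namespace: int = 60
    max_depth: int = 6
    branching: tuple[int, int] = (2, 4)
    multiparent_prob: float = 0.1
    n_genes: int = 150
    n_modules: int = 5
    terms_per_module: int = 8
    annotation_noise: float = 0.1
    namespaces: tuple[str, ...] = ("BP", "MF", "CC")
    annotations_per_gene: tuple[int, int] = (3, 6)


# ---------------------------------------------------------------------------
# the canonical hand-checkable fixture: 6 terms R,A,B,C,D,E

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: R
name: root

[Term]
id: A
name: branch a
is_a: R

[Term]
id: B
name: branch b
is_a: R

[Term]
id: C
name: leaf c
is_a: A

[Term]
id: D
name: leaf d
is_a: A

[Term]
id: E
name: leaf e
is_a: A
is_a: B
"""

#: direct annotations of the three hand-checked genes on the toy DAG
TOY_ANNOTATIONS = {
    "g1": {("C", "IDA")},
    "g2": {("C", "IDA"), ("D", "IEA")},
    "g3": {("E", "IDA")},
}


def toy_dag() -> OntologyDAG:
    """The fixed 6-term fixture with levels and LCs computed."""
    graph = nx.DiGraph()
    edges = [("R", "A"), ("R", "B"), ("A", "C"), ("A", "D"), ("A", "E"), ("B", "E")]
    graph.add_edges_from(edges)
    terms = {t: Term(term_id=t, name=t.lower(), namespace="custom") for t in graph}
    dag = OntologyDAG(graph=graph, terms=terms)
    assign_levels(dag)
    compute_lc(dag)
    return dag


def toy_annotation_set() -> AnnotationSet:
    return make_annotation_set(
        {g: set(pairs) for g, pairs in TOY_ANNOTATIONS.items()}, toy_dag()
    )


def write_toy_obo(path: str | Path) -> None:
    Path(path).write_text(TOY_OBO, encoding="utf-8")


# ---------------------------------------------------------------------------
# random DAG generator


def _gen_namespace(
    rng: np.random.Generator, ns: str, spec: SyntheticSpec
) -> tuple[nx.DiGraph, dict[str, Term], dict[str, int]]:
    n = spec.n_terms_per_namespace
    bmin, bmax = spec.branching
    if bmin < 1 or bmax < bmin:
        raise SyntheticError(f"invalid branching range {spec.branching}")
    if bmin > n:
        raise SyntheticError(f"branching min {bmin} exceeds term count {n}")
    if spec.max_depth < 1:
        raise SyntheticError("max_depth must be >= 1")

    def tid(i: int) -> str:
        return f"T{ns}:{i:07d}"

    graph = nx.DiGraph()
    depth = {tid(0): 0}
    graph.add_node(tid(0))
    frontier = [tid(0)]
    next_id = 1
    # breadth-wise growth with per-node child counts in the branching range
    while next_id < n and frontier:
        node = frontier.pop(0)
        if depth[node] >= spec.max_depth:
            continue
        n_children = int(rng.integers(bmin, bmax + 1))
        for _ in range(n_children):
            if next_id >= n:
                break
            child = tid(next_id)
            next_id += 1
            graph.add_edge(node, child)
            depth[child] = depth[node] + 1
            frontier.append(child)
    if next_id < n:
        raise SyntheticError(
            f"cannot place {n} terms within max_depth {spec.max_depth}"
        )
    # second parents: an extra edge from any strictly shallower node keeps
    # the graph acyclic (reachability only ever increases tree depth)
    nodes = sorted(graph.nodes)
    for node in nodes:
        if depth[node] < 2 or rng.random() >= spec.multiparent_prob:
            continue
        candidates = [
            m for m in nodes
            if depth[m] < depth[node] and m not in graph.predecessors(node)
        ]
        if candidates:
            extra = candidates[int(rng.integers(len(candidates)))]
            graph.add_edge(extra, node)
    terms = {
        t: Term(term_id=t, name=f"{ns} term {t}", namespace=ns) for t in graph
    }
    return graph, terms, depth


def gen_ontology(spec: SyntheticSpec) -> OntologyDAG:
    """Random rooted DAG per namespace; levels and LCs computed."""
    rng = np.random.default_rng(spec.seed)
    graph = nx.DiGraph()
    terms: dict[str, Term] = {}
    for ns in spec.namespaces:
        g, t, _ = _gen_namespace(rng, ns, spec)
        graph.update(g)
        terms.update(t)
    dag = OntologyDAG(graph=graph, terms=terms)
    assign_levels(dag)
    compute_lc(dag)
    return dag


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Serialise a DAG as a minimal OBO 1.2 file (sorted, reproducible)."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    ns_obo = {"BP": "biological_process", "CC": "cellular_component",
              "MF": "molecular_function"}
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {term.name}")
        if term.namespace in ns_obo:
            lines.append(f"namespace: {ns_obo[term.namespace]}")
        for parent in sorted(dag.parents(tid)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# planted-module annotations


def _module_subtrees(
    dag: OntologyDAG, spec: SyntheticSpec, rng: np.random.Generator
) -> list[list[str]]:
    """One coherent term subtree per module, cycling through namespaces."""
    subtrees = []
    for m in range(spec.n_modules):
        ns = spec.namespaces[m % len(spec.namespaces)]
        candidates = sorted(
            t for t in dag.terms_in_namespace(ns)
            if dag.level[t] >= 1
            and len(dag.descendants(t)) + 1 >= spec.terms_per_module
        )
        if not candidates:
            raise SyntheticError(
                f"no subtree in namespace {ns} can hold {spec.terms_per_module} terms"
            )
        root = candidates[int(rng.integers(len(candidates)))]
        pool = sorted(dag.descendants(root) | {root})
        pick = rng.choice(len(pool), size=spec.terms_per_module, replace=False)
        subtrees.append([pool[i] for i in sorted(pick)])
    return subtrees


def gen_annotations(
    dag: OntologyDAG, spec: SyntheticSpec
) -> tuple[AnnotationSet, dict[str, set[str]], dict[str, list[str]]]:
    """Annotate genes from planted module subtrees; return the module GMT.

    Returns the annotation set, the module -> member-gene map (the
    ground-truth "pathways"), and the module -> planted-term-subtree map
    (useful for leakage-free scoring of the planted signal).

    Genes are partitioned round-robin across modules.  Each gene draws a
    number of direct annotations from its module's subtree; each draw is
    replaced, with probability ``annotation_noise``, by a uniformly random
    term from the whole ontology.  Evidence codes are mostly experimental
    (IDA) with an occasional electronic (IEA) code so that evidence
    filtering has something to act on.
    """
    rng = np.random.default_rng(spec.seed + 1)
    subtrees = _module_subtrees(dag, spec, rng)
    all_terms = sorted(dag.terms)
    amin, amax = spec.annotations_per_gene
    assignments: dict[str, set[tuple[str, str]]] = {}
    modules: dict[str, set[str]] = {
        f"module_{m:02d}": set() for m in range(spec.n_modules)
    }
    planted = {f"module_{m:02d}": list(subtrees[m]) for m in range(spec.n_modules)}
    for i in range(spec.n_genes):
        gene = f"gene_{i:04d}"
        m = i % spec.n_modules
        modules[f"module_{m:02d}"].add(gene)
        pool = subtrees[m]
        k = int(rng.integers(amin, amax + 1))
        pairs: set[tuple[str, str]] = set()
        for _ in range(k):
            if rng.random() < spec.annotation_noise:
                term = all_terms[int(rng.integers(len(all_terms)))]
            else:
                term = pool[int(rng.integers(len(pool)))]
            evidence = "IEA" if rng.random() < 0.15 else "IDA"
            pairs.add((term, evidence))
        assignments[gene] = pairs
    ann = make_annotation_set(assignments, dag)
    return ann, modules, planted


def write_annotation_tsv(ann: AnnotationSet, path: str | Path) -> None:
    lines = ["gene_id\tterm_id\tevidence_code"]
    for gene in ann.genes:
        for term, ev in sorted(ann.direct[gene]):
            lines.append(f"{gene}\t{term}\t{ev}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
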