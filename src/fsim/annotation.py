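"""Gene annotations and ancestor-closed annotation classes.

A gene's annotation in a hierarchical ontology implicitly includes every
ancestor of its directly annotated terms.  The *annotation class* of a gene
is therefore a binary vector over the full term universe with a 1 for each
direct term and each of its ancestors.  Pairs of such vectors are what the
agreement-table similarity measures compare.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Direct gene -> (term, evidence) assignments over a fixed universe.

    ``universe`` is the lexicographically ordered list of all non-obsolete
    term ids of the loaded namespaces; its order is what aligns annotation
    classes between genes.
    """

    direct: dict[str, set[tuple[str, str]]]
    universe: list[str]
    _index: dict[str, int] = field(init=False, repr=False)
    # per-gene annotation classes are rebuilt constantly while benchmarking;
    # cache assumes `direct` is not mutated after construction
    _class_cache: dict[str, "AnnotationClass"] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.universe)}
        self._class_cache = {}

    @property
    def genes(self) -> list[str]:
        return sorted(self.direct)

    @property
    def n_terms(self) -> int:
        return len(self.universe)

    def direct_terms(self, gene_id: str) -> set[str]:
        if gene_id not in self.direct:
            raise KeyError(f"unknown gene: {gene_id}")
        return {t for t, _ in self.direct[gene_id]}

    def index_of(self, term_id: str) -> int:
        return self._index[term_id]


@dataclass
class AnnotationClass:
    """Ancestor-closed binary vector for one gene (or an ad-hoc term set)."""

    gene_id: str
    bits: np.ndarray  # bool, aligned to AnnotationSet.universe
    universe: list[str]

    @property
    def terms(self) -> set[str]:
        return {self.universe[i] for i in np.flatnonzero(self.bits)}


def _build_universe(dag: OntologyDAG) -> list[str]:
    return sorted(dag.terms)


def make_annotation_set(
    assignments: dict[str, set[tuple[str, str]]], dag: OntologyDAG
) -> AnnotationSet:
    """Assemble an AnnotationSet in memory, dropping unknown-term rows."""
    universe = _build_universe(dag)
    known = set(universe)
    direct: dict[str, set[tuple[str, str]]] = {}
    dropped = 0
    for gene, pairs in assignments.items():
        keep = {(t, e) for t, e in pairs if t in known}
        dropped += len(pairs) - len(keep)
        if keep:
            direct[gene] = keep
    if dropped:
        logger.warning("dropped %d annotation rows with unknown/obsolete terms", dropped)
    return AnnotationSet(direct=direct, universe=universe)


def load_annotations(
    path: str | Path | io.TextIOBase,
    dag: OntologyDAG,
    format: str = "tsv",
) -> AnnotationSet:
    """Load gene -> term annotations from a 3-column TSV or a GAF 2.x file.

    TSV dialect: header row, columns gene_id, term_id, evidence_code.
    GAF dialect: '!'-prefixed comments ignored; DB object id is column 2,
    GO id column 5, evidence column 7 (1-based); rows whose qualifier
    contains NOT are dropped.  Rows referencing unknown or obsolete terms
    are dropped with a logged count.
    """
    if format not in ("tsv", "gaf"):
        raise AnnotationError(f"unknown annotation format: {format!r}")
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "rt", encoding="utf-8")
        close = True
    else:
        handle = path
    assignments: dict[str, set[tuple[str, str]]] = {}
    try:
        if format == "tsv":
            header = handle.readline()
            if not header.strip():
                return make_annotation_set({}, dag)
            for lineno, line in enumerate(handle, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise AnnotationError(
                        f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
                    )
                gene, term, ev = parts[0], parts[1], parts[2]
                assignments.setdefault(gene, set()).add((term, ev))
        else:  # gaf
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 7:
                    raise AnnotationError(
                        f"line {lineno}: GAF row has {len(parts)} columns, need >= 7"
                    )
                qualifier = parts[3]
                if "NOT" in qualifier.split("|"):
                    continue
                gene, term, ev = parts[1], parts[4], parts[6]
                assignments.setdefault(gene, set()).add((term, ev))
    finally:
        if close:
            handle.close()
    return make_annotation_set(assignments, dag)


def filter_evidence(ann: AnnotationSet, exclude: set[str]) -> AnnotationSet:
    """Drop (term, evidence) pairs whose evidence code is excluded.

    Genes left with no annotations are removed entirely — an all-zero
    annotation class has no defined similarity.
    """
    direct = {}
    for gene, pairs in ann.direct.items():
        keep = {(t, e) for t, e in pairs if e not in exclude}
        if keep:
            direct[gene] = keep
    return AnnotationSet(direct=direct, universe=list(ann.universe))


def termset_class(terms: set[str], dag: OntologyDAG, ann: AnnotationSet,
                  label: str = "<termset>") -> AnnotationClass:
    """Ancestor closure of an arbitrary term set as an annotation class."""
    unknown = sorted(t for t in terms if t not in dag.terms)
    if unknown:
        raise KeyError(f"unknown terms: {unknown}")
    closed: set[str] = set()
    for t in terms:
        closed.add(t)
        closed |= dag.ancestors(t)
    bits = np.zeros(ann.n_terms, dtype=bool)
    for t in closed:
        bits[ann.index_of(t)] = True
    return AnnotationClass(gene_id=label, bits=bits, universe=ann.universe)


def annotation_class(
    ann: AnnotationSet, dag: OntologyDAG, gene_id: str
) -> AnnotationClass:
    """Binary vector of a gene's direct terms plus all their ancestors."""
    cached = ann._class_cache.get(gene_id)
    if cached is not None:
        return cached
    if gene_id not in ann.direct:
        raise KeyError(f"unknown gene: {gene_id}")
    terms = ann.direct_terms(gene_id)
    if not terms:
        raise AnnotationError(f"unannotated gene: {gene_id}")
    cls = termset_class(terms, dag, ann, label=gene_id)
    ann._class_cache[gene_id] = cls
    return cls


def load_gmt(path: str | Path | io.TextIOBase) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, then gene ids."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "rt", encoding="utf-8")
        close = True
    else:
        handle = path
    sets: dict[str, set[str]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise AnnotationError(
                    f"line {lineno}: GMT row needs name, description, >=1 gene"
                )
            sets[parts[0]] = set(parts[2:]) - {""}
    finally:
        if close:
            handle.close()
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "wt", encoding="utf-8") as out:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            out.write(f"{name}\t{description}\t{genes}\n")
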