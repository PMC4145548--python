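"""Comparator similarity measures: unweighted kappa and IC-based methods.

The unweighted kappa (the DAVID classification statistic) is Cohen's kappa
on the raw binary annotation-class vectors — equivalently the LC-weighted
table with every weight forced to 1.

The information-content (IC) family scores term pairs by the IC of their
minimum subsumer — the common ancestor with maximal IC, where
IC(t) = -log P(t) and P(t) is the fraction of annotated genes in t's
namespace whose annotation closure includes t:

    Lin(t1, t2)        = 2 IC_ms / (IC(t1) + IC(t2))
    relevance(t1, t2)  = Lin(t1, t2) * (1 - exp(-IC_ms))

Group scores combine the pairwise matrix between two term groups either by
best-match average (funSimMax) or by the max/min Hausdorff-style rule
applied literally to similarities; the "dot" method is the cosine of the
IC-weighted closure vectors (a reconstruction — the original publication
names it without a formula).  Gene-level IC scores are summed across the
three namespaces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .annotation import AnnotationClass, AnnotationSet, annotation_class
from .core import AgreementTable, agreement_table, kappa
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

PairSim = Callable[[str, str], float]


class BaselineError(ValueError):
    pass


@dataclass
class ICTable:
    """Per-term annotation probability and information content.

    Counting is gene-level and descendant-inclusive: a gene counts towards
    P(t) when t appears anywhere in the gene's ancestor closure, and the
    denominator is the number of genes with at least one annotation in t's
    namespace.  Terms no gene reaches have undefined IC and are excluded
    from IC-based scoring.
    """

    p: dict[str, float]
    ic: dict[str, float]
    # memo for pairwise term similarities, keyed by (method, t1, t2)
    pair_cache: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pair_cache is None:
            self.pair_cache = {}

    def defined(self, term_id: str) -> bool:
        return term_id in self.ic


def compute_ic(ann: AnnotationSet, dag: OntologyDAG) -> ICTable:
    # closure term -> genes reaching it, per namespace denominators
    ns_of = {tid: t.namespace for tid, t in dag.terms.items()}
    counts: dict[str, int] = {}
    ns_genes: dict[str, set[str]] = {}
    for gene in ann.direct:
        closure: set[str] = set()
        for t in ann.direct_terms(gene):
            closure.add(t)
            closure |= dag.ancestors(t)
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
        for ns in {ns_of[t] for t in closure}:
            ns_genes.setdefault(ns, set()).add(gene)
    if not ns_genes:
        raise BaselineError("no annotated genes in any namespace")
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t, c in counts.items():
        denom = len(ns_genes[ns_of[t]])
        p[t] = c / denom
        ic[t] = -math.log(p[t])
    return ICTable(p=p, ic=ic)


# ---------------------------------------------------------------------------
# pairwise term similarities


def _ic_ms(t1: str, t2: str, ic: ICTable, dag: OntologyDAG) -> float:
    """IC of the minimum subsumer: max IC over common ancestors.

    Each term counts among its own ancestors here, so a term subsuming the
    other contributes its own IC.
    """
    anc1 = dag.ancestors(t1) | {t1}
    anc2 = dag.ancestors(t2) | {t2}
    common = anc1 & anc2
    values = [ic.ic[t] for t in common if ic.defined(t)]
    return max(values, default=0.0)


def lin_sim(t1: str, t2: str, ic: ICTable, dag: OntologyDAG) -> float:
    """Lin's pairwise similarity; 0 for cross-namespace or zero-IC pairs."""
    for t in (t1, t2):
        if t not in dag.terms:
            raise KeyError(f"unknown term: {t}")
    if dag.terms[t1].namespace != dag.terms[t2].namespace:
        return 0.0
    denom = ic.ic.get(t1, 0.0) + ic.ic.get(t2, 0.0)
    if denom == 0.0:
        return 0.0
    return 2.0 * _ic_ms(t1, t2, ic, dag) / denom


def relevance_sim(t1: str, t2: str, ic: ICTable, dag: OntologyDAG) -> float:
    """Lin similarity damped by (1 - exp(-IC_ms)); always <= Lin."""
    if dag.terms[t1].namespace != dag.terms[t2].namespace:
        return 0.0
    ms = _ic_ms(t1, t2, ic, dag)
    return lin_sim(t1, t2, ic, dag) * (1.0 - math.exp(-ms))


# ---------------------------------------------------------------------------
# group combinations


def funsimmax(group_a: set[str], group_b: set[str], pairsim: PairSim) -> float:
    """Best-match average: mean of row-max average and column-max average."""
    if not group_a or not group_b:
        raise BaselineError("funsimmax requires two non-empty term groups")
    a, b = sorted(group_a), sorted(group_b)
    mat = np.array([[pairsim(x, y) for y in b] for x in a])
    return float((mat.max(axis=1).mean() + mat.max(axis=0).mean()) / 2.0)


def hausdorff_sim(group_a: set[str], group_b: set[str], pairsim: PairSim) -> float:
    """Max-over-one-set of min-over-the-other, outer max of both directions.

    The max/min rule is applied to similarity values exactly as the method
    is defined; note it is a similarity here, not a metric distance.
    """
    if not group_a or not group_b:
        raise BaselineError("hausdorff requires two non-empty term groups")
    a, b = sorted(group_a), sorted(group_b)
    mat = np.array([[pairsim(x, y) for y in b] for x in a])
    d_ab = mat.min(axis=1).max()  # max over a of min over b
    d_ba = mat.min(axis=0).max()  # max over b of min over a
    return float(max(d_ab, d_ba))


def dot_sim(a: AnnotationClass, b: AnnotationClass, ic: ICTable) -> float:
    """Cosine of IC-weighted closure vectors; NaN for a zero vector."""
    if a.universe != b.universe:
        raise BaselineError("annotation classes built over different universes")
    w = np.array([ic.ic.get(t, 0.0) for t in a.universe])
    va = w * a.bits
    vb = w * b.bits
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return math.nan
    return float(va @ vb / (na * nb))


def david_kappa(a: AnnotationClass, b: AnnotationClass) -> float:
    """Cohen's kappa on the raw (unweighted) binary vectors."""
    if a.universe != b.universe:
        raise BaselineError("annotation classes built over different universes")
    av, bv = a.bits, b.bits
    table = AgreementTable(
        p11=float((av & bv).sum()),
        p12=float((av & ~bv).sum()),
        p21=float((~av & bv).sum()),
        p22=float((~av & ~bv).sum()),
    )
    return kappa(table)


# ---------------------------------------------------------------------------
# gene-level IC scores


def _scoreable(terms: set[str], ic: ICTable) -> set[str]:
    keep = {t for t in terms if ic.defined(t)}
    if len(keep) < len(terms):
        logger.warning("dropped %d terms with undefined IC", len(terms) - len(keep))
    return keep


def gene_sim_ic(
    terms_a: set[str],
    terms_b: set[str],
    method: str,
    groupwise: str,
    dag: OntologyDAG,
    ic: ICTable,
) -> float:
    """IC-based similarity between two term groups, summed over namespaces.

    ``method`` is the pairwise term similarity (lin | relevance) and
    ``groupwise`` the combination rule (funsimmax | hausdorff).  Each
    namespace is scored on the direct terms falling in it; namespaces with
    no scoreable terms on either side contribute 0, and the final score is
    the sum across namespaces.  Returns NaN when no namespace is scoreable.
    """
    pair = {"lin": lin_sim, "relevance": relevance_sim}.get(method)
    comb = {"funsimmax": funsimmax, "hausdorff": hausdorff_sim}.get(groupwise)
    if pair is None or comb is None:
        raise BaselineError(f"unknown method spec: {method}/{groupwise}")
    ta = _scoreable(terms_a, ic)
    tb = _scoreable(terms_b, ic)

    def cached_pair(x: str, y: str) -> float:
        key = (method, x, y) if x <= y else (method, y, x)
        val = ic.pair_cache.get(key)
        if val is None:
            val = pair(key[1], key[2], ic, dag)
            ic.pair_cache[key] = val
        return val

    total = 0.0
    scored_any = False
    for ns in dag.namespaces():
        members = dag.terms_in_namespace(ns)
        ga = ta & members
        gb = tb & members
        if not ga or not gb:
            continue
        total += comb(ga, gb, cached_pair)
        scored_any = True
    return total if scored_any else math.nan
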