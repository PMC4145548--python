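"""Functional neighbour search: rank annotated genes against a query.

The query may be a gene, an explicit term list, a list of genes (their
annotations are pooled), or free-text keywords matched case-insensitively
against term names.  Every annotated gene is scored against the query's
annotation class and ranked by descending Z (for the LC-weighted kappa) or
descending raw score otherwise.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, annotation_class, termset_class
from .baselines import compute_ic, david_kappa, dot_sim, gene_sim_ic
from .core import fsim_score
from .ontology import OntologyDAG


class SearchError(ValueError):
    pass


def resolve_keywords(keywords: list[str], dag: OntologyDAG) -> set[str]:
    """Terms whose name contains any keyword (case-insensitive substring)."""
    lowered = [k.lower() for k in keywords]
    hits = {
        tid
        for tid, term in dag.terms.items()
        if any(k in term.name.lower() for k in lowered)
    }
    if not hits:
        raise SearchError(f"no term name matches keywords: {keywords}")
    return hits


def query_terms(
    ann: AnnotationSet,
    dag: OntologyDAG,
    gene: str | None = None,
    genes: list[str] | None = None,
    terms: list[str] | None = None,
    keywords: list[str] | None = None,
) -> set[str]:
    """Resolve any query flavour to a direct term set."""
    if gene is not None:
        return ann.direct_terms(gene)
    if genes is not None:
        missing = [g for g in genes if g not in ann.direct]
        if missing:
            raise SearchError(f"unknown genes in query: {missing}")
        pooled: set[str] = set()
        for g in genes:
            pooled |= ann.direct_terms(g)
        return pooled
    if terms is not None:
        missing = [t for t in terms if t not in dag.terms]
        if missing:
            raise SearchError(f"unknown terms in query: {missing}")
        return set(terms)
    if keywords is not None:
        return resolve_keywords(keywords, dag)
    raise SearchError("empty query")


def search_genes(
    terms: set[str],
    ann: AnnotationSet,
    dag: OntologyDAG,
    method: str = "fsim",
) -> pd.DataFrame:
    """Rank all annotated genes by similarity to a query term set.

    Columns: gene_id, method, score, kappa, se, z, n_shared_terms, where
    ``score`` is the ranking key (Z for fsim variants) and
    ``n_shared_terms`` counts closure terms shared with the query.
    """
    query = termset_class(terms, dag, ann, label="<query>")
    ic = compute_ic(ann, dag) if method in ("dot", "lin_funsimmax",
                                            "relevance_funsimmax", "hausdorff") else None
    rows = []
    for gene in ann.genes:
        cls = annotation_class(ann, dag, gene)
        shared = int(np.sum(query.bits & cls.bits))
        kap = se = z = math.nan
        if method in ("fsim", "fsim_bp", "fsim_mf", "fsim_cc"):
            ns = {"fsim_bp": "BP", "fsim_mf": "MF", "fsim_cc": "CC"}.get(method)
            s = fsim_score(query, cls, dag, namespace=ns)
            kap, se, z, score = s.kappa, s.se, s.z, s.z
        elif method == "david":
            kap = david_kappa(query, cls)
            score = kap
        elif method == "dot":
            score = dot_sim(query, cls, ic)
        elif method in ("lin_funsimmax", "relevance_funsimmax", "hausdorff"):
            pair = "relevance" if method in ("relevance_funsimmax", "hausdorff") else "lin"
            comb = "hausdorff" if method == "hausdorff" else "funsimmax"
            score = gene_sim_ic(ann.direct_terms(gene), terms, pair, comb, dag, ic)
        else:
            raise SearchError(f"unknown method: {method!r}")
        rows.append(
            {
                "gene_id": gene, "method": method, "score": score,
                "kappa": kap, "se": se, "z": z, "n_shared_terms": shared,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                        na_position="last").reset_index(drop=True)
    return df
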