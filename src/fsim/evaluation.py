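"""Benchmark harness: term enrichment, gene scoring, ROC/AUC, and KS tests.

Validation follows the pathway-recovery design: for each gene set
("pathway"), over-represented ontology terms are selected by a one-sided
hypergeometric test against the annotated-gene background, the top k per
namespace are pooled into a representative term group, every annotated
gene is scored against that group with each similarity method, and the
ranking is assessed by the ROC AUC with pathway members as positives.  A
two-sample Kolmogorov-Smirnov test compares the member and non-member
score distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet, annotation_class, termset_class
from .baselines import ICTable, compute_ic, david_kappa, dot_sim, gene_sim_ic
from .core import fsim_score
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

#: the nine method labels of the standard comparison
METHODS = (
    "fsim",
    "fsim_bp",
    "fsim_mf",
    "fsim_cc",
    "david",
    "lin_funsimmax",
    "relevance_funsimmax",
    "dot",
    "hausdorff",
)

_NS_VARIANT = {"fsim_bp": "BP", "fsim_mf": "MF", "fsim_cc": "CC"}


class EvaluationError(ValueError):
    pass


@dataclass
class EnrichedTermGroup:
    pathway_id: str
    terms: pd.DataFrame  # columns term_id, namespace, p_value (all tested terms)
    selected: list[str]  # top-k per namespace, pooled

    @property
    def selected_set(self) -> set[str]:
        return set(self.selected)


@dataclass
class BenchmarkResult:
    pathway_id: str
    method: str
    scores: dict[str, float]
    labels: dict[str, str]  # gene -> "positive" | "negative"
    auc: float
    ks_stat: float = math.nan
    ks_p: float = math.nan

    @property
    def n_pos(self) -> int:
        return sum(1 for v in self.labels.values() if v == "positive")

    @property
    def n_neg(self) -> int:
        return sum(1 for v in self.labels.values() if v == "negative")


def enrich_terms(
    gene_set: set[str],
    ann: AnnotationSet,
    dag: OntologyDAG,
    k: int = 20,
) -> EnrichedTermGroup:
    """Hypergeometric term enrichment; top-k per namespace pooled.

    Term membership is closure-based: a gene hits a term when the term is
    in the gene's ancestor closure.  Ties in p-value break lexicographically
    by term id so the selection is deterministic.
    """
    background = set(ann.direct)
    hits = gene_set & background
    if not hits:
        raise EvaluationError("gene set shares no genes with the annotated background")
    closures = {
        g: annotation_class(ann, dag, g).terms for g in sorted(background)
    }
    term_genes: dict[str, set[str]] = {}
    for g, closure in closures.items():
        for t in closure:
            term_genes.setdefault(t, set()).add(g)
    big_n = len(background)
    draw = len(hits)
    rows = []
    for t, genes in term_genes.items():
        overlap = len(genes & hits)
        if overlap == 0:
            continue
        # P(X >= overlap) drawing `draw` genes from big_n with len(genes) marked
        p = float(stats.hypergeom.sf(overlap - 1, big_n, len(genes), draw))
        rows.append({"term_id": t, "namespace": dag.terms[t].namespace, "p_value": p})
    table = pd.DataFrame(rows, columns=["term_id", "namespace", "p_value"])
    selected: list[str] = []
    for ns, sub in table.groupby("namespace"):
        top = sub.sort_values(["p_value", "term_id"]).head(k)
        selected.extend(top["term_id"].tolist())
    return EnrichedTermGroup(pathway_id="", terms=table, selected=sorted(selected))


def _ensure_ic(ann: AnnotationSet, dag: OntologyDAG, ic: ICTable | None) -> ICTable:
    return ic if ic is not None else compute_ic(ann, dag)


def score_all_genes(
    group: EnrichedTermGroup,
    ann: AnnotationSet,
    dag: OntologyDAG,
    method: str,
    ic: ICTable | None = None,
) -> dict[str, float]:
    """Score every annotated gene against the enriched term group.

    The term group enters as its ancestor closure for the agreement-table
    methods (fsim variants, david, dot) and as the direct term list for the
    IC group-wise methods.  Genes whose score is undefined (NaN) are
    dropped with a logged count.
    """
    if method not in METHODS:
        raise EvaluationError(f"unknown method: {method!r}")
    terms = group.selected_set
    if not terms:
        raise EvaluationError("empty enriched term group")
    scores: dict[str, float] = {}
    if method in ("fsim", "fsim_bp", "fsim_mf", "fsim_cc", "david", "dot"):
        group_class = termset_class(terms, dag, ann, label=group.pathway_id)
        if method in ("dot",):
            ic = _ensure_ic(ann, dag, ic)
        ns = _NS_VARIANT.get(method)
        for gene in ann.genes:
            cls = annotation_class(ann, dag, gene)
            if method == "david":
                scores[gene] = david_kappa(group_class, cls)
            elif method == "dot":
                scores[gene] = dot_sim(group_class, cls, ic)
            else:
                scores[gene] = fsim_score(group_class, cls, dag, namespace=ns).z
    else:
        ic = _ensure_ic(ann, dag, ic)
        pair = "relevance" if method in ("relevance_funsimmax", "hausdorff") else "lin"
        comb = "hausdorff" if method == "hausdorff" else "funsimmax"
        for gene in ann.genes:
            scores[gene] = gene_sim_ic(
                ann.direct_terms(gene), terms, pair, comb, dag, ic
            )
    defined = {g: s for g, s in scores.items() if not math.isnan(s)}
    if len(defined) < len(scores):
        logger.warning(
            "dropped %d genes with undefined %s score", len(scores) - len(defined), method
        )
    return defined


def roc_auc(scores: dict[str, float], labels: dict[str, str]) -> float:
    """AUC via the Mann-Whitney rank statistic with midranks for ties."""
    genes = [g for g in scores if g in labels]
    y = np.array([1 if labels[g] == "positive" else 0 for g in genes])
    s = np.array([scores[g] for g in genes], dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs at least one positive and one negative")
    ranks = stats.rankdata(s)  # midranks for ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_table(scores: dict[str, float], labels: dict[str, str]) -> pd.DataFrame:
    """ROC coordinates (fpr, tpr, threshold) for external plotting."""
    from sklearn.metrics import roc_curve

    genes = [g for g in scores if g in labels]
    y = [1 if labels[g] == "positive" else 0 for g in genes]
    s = [scores[g] for g in genes]
    fpr, tpr, thr = roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def ks_compare(
    scores_pos: list[float],
    scores_neg: list[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    ``alternative='less'`` tests that the positive scores are
    stochastically greater (their ECDF lies below the negatives').
    """
    if not scores_pos or not scores_neg:
        raise EvaluationError("KS comparison requires two non-empty samples")
    res = stats.ks_2samp(scores_pos, scores_neg, alternative=alternative,
                         method="asymp")
    return float(res.statistic), float(res.pvalue)


def run_benchmark(
    pathways: dict[str, set[str]],
    ann: AnnotationSet,
    dag: OntologyDAG,
    methods: tuple[str, ...] = METHODS,
    k: int = 20,
    min_genes: int = 5,
) -> list[BenchmarkResult]:
    """Enrich -> score -> label -> AUC for every pathway x method.

    Pathways with fewer than ``min_genes`` annotated members are skipped.
    Positives are the annotated pathway members; negatives all other
    annotated genes.  The KS comparison is attached to every method's row.
    """
    ic = compute_ic(ann, dag)
    annotated = set(ann.direct)
    results: list[BenchmarkResult] = []
    survivors = 0
    for pid in sorted(pathways):
        members = pathways[pid] & annotated
        if len(members) < min_genes:
            logger.info("pathway %s skipped: %d annotated genes < %d",
                        pid, len(members), min_genes)
            continue
        survivors += 1
        group = enrich_terms(members, ann, dag, k=k)
        group.pathway_id = pid
        for method in methods:
            scores = score_all_genes(group, ann, dag, method, ic=ic)
            labels = {
                g: ("positive" if g in members else "negative") for g in scores
            }
            auc = roc_auc(scores, labels)
            pos = [scores[g] for g in scores if labels[g] == "positive"]
            neg = [scores[g] for g in scores if labels[g] == "negative"]
            ks_stat, ks_p = ks_compare(pos, neg)
            results.append(
                BenchmarkResult(
                    pathway_id=pid, method=method, scores=scores,
                    labels=labels, auc=auc, ks_stat=ks_stat, ks_p=ks_p,
                )
            )
    if survivors == 0:
        raise EvaluationError(f"no pathway passed the >= {min_genes} gene filter")
    return results


def benchmark_table(results: list[BenchmarkResult]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": r.pathway_id,
            "method": r.method,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "auc": r.auc,
            "ks_stat": r.ks_stat,
            "ks_p": r.ks_p,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["pathway_id", "method", "n_pos", "n_neg", "auc", "ks_stat", "ks_p"]
    )
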