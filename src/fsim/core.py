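"""The LC-weighted kappa similarity (the FSim statistic).

Two annotation classes (ancestor-closed binary vectors over the term
universe) are compared through a 2x2 agreement table in which each term
contributes not a count of 1 but its level coefficient:

    p11 = sum of LC over terms set in both classes
    p12 = set in the first only        p21 = set in the second only
    p22 = set in neither               total = sum of LC over the universe

Cohen's kappa on this weighted table is the similarity; its large-sample
standard error follows Fleiss, Cohen & Everitt's non-null variance formula
with the LC mass as the effective sample size, and the headline score is
the standardised Z = kappa / SE.  Larger Z means more significantly similar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annotation import AnnotationClass, AnnotationSet
from .ontology import OntologyDAG


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class AgreementTable:
    """LC-weighted 2x2 agreement table for a pair of annotation classes."""

    p11: float
    p12: float
    p21: float
    p22: float

    @property
    def total(self) -> float:
        return self.p11 + self.p12 + self.p21 + self.p22

    def scaled(self, c: float) -> "AgreementTable":
        return AgreementTable(self.p11 * c, self.p12 * c, self.p21 * c, self.p22 * c)


@dataclass(frozen=True)
class FsimScore:
    kappa: float  # NaN when degenerate
    se: float
    z: float
    per_namespace: dict[str, "FsimScore"] | None = None


def _weights(dag: OntologyDAG, universe: list[str]) -> np.ndarray:
    if not dag.lc:
        raise SimilarityError("level coefficients not computed; call compute_lc first")
    return np.array([dag.lc[t] for t in universe], dtype=float)


def agreement_table(
    a: AnnotationClass,
    b: AnnotationClass,
    dag: OntologyDAG,
    weights: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> AgreementTable:
    """Build the LC-weighted agreement table for two annotation classes.

    ``weights`` overrides the LC vector (e.g. all-ones for the unweighted
    kappa); ``mask`` restricts the table to a subset of the universe
    (used for per-namespace scoring).
    """
    if a.universe != b.universe:
        raise SimilarityError("annotation classes built over different universes")
    w = _weights(dag, a.universe) if weights is None else np.asarray(weights, float)
    if mask is not None:
        w = np.where(mask, w, 0.0)
    av, bv = a.bits, b.bits
    p11 = float(w[av & bv].sum())
    p12 = float(w[av & ~bv].sum())
    p21 = float(w[~av & bv].sum())
    p22 = float(w[~av & ~bv].sum())
    return AgreementTable(p11, p12, p21, p22)


def kappa(table: AgreementTable) -> float:
    """Cohen's kappa on a (possibly weighted) 2x2 table; NaN if degenerate."""
    n = table.total
    if n <= 0:
        raise SimilarityError("agreement table has zero total mass")
    q11, q12, q21, q22 = (x / n for x in (table.p11, table.p12, table.p21, table.p22))
    po = q11 + q22
    pe = (q11 + q12) * (q11 + q21) + (q21 + q22) * (q12 + q22)
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        return math.nan
    return (po - pe) / (1.0 - pe)


def kappa_se(table: AgreementTable, effective_n: float | None = None) -> float:
    """Large-sample (non-null) standard error of kappa.

    Implements the Fleiss-Cohen-Everitt variance for an unweighted kappa
    on a 2x2 proportion table.  ``effective_n`` overrides the sample size
    N; the default uses the table's LC-weight total, treating weighted
    sums as pseudo-counts (pass the universe size instead to use the raw
    term count).
    """
    n = table.total if effective_n is None else float(effective_n)
    if n <= 0:
        raise SimilarityError("agreement table has zero total mass")
    p = np.array([[table.p11, table.p12], [table.p21, table.p22]]) / table.total
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = row @ col
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        return math.nan
    k = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt (1969), large-sample variance of kappa-hat
    a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - k)) ** 2 for i in range(2)
    )
    b = (1.0 - k) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    c = (k - pe * (1.0 - k)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    return math.sqrt(max(var, 0.0))


def score_table(table: AgreementTable, effective_n: float | None = None) -> FsimScore:
    k = kappa(table)
    if math.isnan(k):
        return FsimScore(kappa=math.nan, se=math.nan, z=math.nan)
    se = kappa_se(table, effective_n=effective_n)
    if se > 0:
        z = k / se
    elif k != 0:
        # perfect agreement has zero sampling variance; the Z score diverges
        z = math.copysign(math.inf, k)
    else:
        z = math.nan
    return FsimScore(kappa=k, se=se, z=z)


def namespace_masks(dag: OntologyDAG, universe: list[str]) -> dict[str, np.ndarray]:
    """Boolean mask over the universe for each namespace."""
    masks: dict[str, np.ndarray] = {}
    for ns in dag.namespaces():
        members = dag.terms_in_namespace(ns)
        masks[ns] = np.array([t in members for t in universe], dtype=bool)
    return masks


def fsim_score(
    a: AnnotationClass,
    b: AnnotationClass,
    dag: OntologyDAG,
    combine: str = "all_ontologies",
    namespace: str | None = None,
    effective_n: float | None = None,
) -> FsimScore:
    """LC-weighted kappa similarity between two annotation classes.

    ``combine='all_ontologies'`` (the headline method) builds a single
    agreement table over the union universe of all loaded namespaces;
    ``combine='per_namespace'`` returns one (kappa, SE, Z) triple per
    namespace in :attr:`FsimScore.per_namespace`, with the combined triple
    alongside.  ``namespace`` restricts the single table to one namespace
    (the FSim_BP / FSim_MF / FSim_CC variants).
    """
    if combine not in ("all_ontologies", "per_namespace"):
        raise SimilarityError(f"unknown combine mode: {combine!r}")
    if namespace is not None:
        mask = namespace_masks(dag, a.universe).get(namespace)
        if mask is None:
            raise SimilarityError(f"unknown namespace: {namespace!r}")
        return score_table(agreement_table(a, b, dag, mask=mask), effective_n)
    combined = score_table(agreement_table(a, b, dag), effective_n)
    if combine == "all_ontologies":
        return combined
    per_ns = {
        ns: score_table(agreement_table(a, b, dag, mask=m), effective_n)
        for ns, m in namespace_masks(dag, a.universe).items()
    }
    return FsimScore(
        kappa=combined.kappa, se=combined.se, z=combined.z, per_namespace=per_ns
    )


def pairwise_scores(
    classes: dict[str, AnnotationClass],
    dag: OntologyDAG,
) -> "list[tuple[str, str, float, float, float]]":
    """All-vs-all (gene_a, gene_b, kappa, se, z) rows, a < b lexicographic."""
    genes = sorted(classes)
    w = _weights(dag, classes[genes[0]].universe) if genes else None
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            t = agreement_table(classes[ga], classes[gb], dag, weights=w)
            s = score_table(t)
            rows.append((ga, gb, s.kappa, s.se, s.z))
    return rows


def distance_matrix(
    classes: dict[str, AnnotationClass],
    dag: OntologyDAG,
    metric: str = "one_minus_kappa",
) -> "tuple[list[str], np.ndarray]":
    """Square distance matrix for clustering: 1 - kappa or -Z."""
    if metric not in ("one_minus_kappa", "neg_z"):
        raise SimilarityError(f"unknown distance metric: {metric!r}")
    genes = sorted(classes)
    n = len(genes)
    mat = np.zeros((n, n), dtype=float)
    for i, ga in enumerate(genes):
        for j in range(i + 1, n):
            s = score_table(agreement_table(classes[ga], classes[genes[j]], dag))
            d = 1.0 - s.kappa if metric == "one_minus_kappa" else -s.z
            mat[i, j] = mat[j, i] = d
    return genes, mat
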