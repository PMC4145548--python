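import numpy as np
import pytest

from fsim import annotation_class, toy_annotation_set, toy_dag


@pytest.fixture(scope="session")
def dag():
    return toy_dag()


@pytest.fixture(scope="session")
def ann(dag):
    return toy_annotation_set()


@pytest.fixture(scope="session")
def classes(dag, ann):
    return {g: annotation_class(ann, dag, g) for g in ("g1", "g2", "g3")}


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)


def naive_lc(edges: list[tuple[str, str]]) -> dict[str, float]:
    """Memoized recursive evaluation of the LC definition on an edge list."""
    children: dict[str, list[str]] = {}
    nodes = set()
    for p, c in edges:
        children.setdefault(p, []).append(c)
        nodes.update((p, c))
    parents = {n: [p for p, c in edges if c == n] for n in nodes}
    roots = [n for n in nodes if not parents[n]]

    def longest_depth(n: str) -> int:
        if not parents[n]:
            return 0
        return 1 + max(longest_depth(p) for p in parents[n])

    level = {n: longest_depth(n) for n in nodes}
    memo: dict[str, float] = {}

    def lc(n: str) -> float:
        if n in memo:
            return memo[n]
        kids = children.get(n, [])
        if not kids:
            memo[n] = 1.0
        else:
            memo[n] = sum(lc(c) * level[n] / level[c] for c in kids) / len(kids)
        return memo[n]

    return {n: lc(n) for n in nodes}


def naive_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa computed directly from two binary vectors."""
    a = a.astype(bool)
    b = b.astype(bool)
    n = len(a)
    p11 = (a & b).sum() / n
    p12 = (a & ~b).sum() / n
    p21 = (~a & b).sum() / n
    p22 = (~a & ~b).sum() / n
    po = p11 + p22
    pe = (p11 + p12) * (p11 + p21) + (p21 + p22) * (p12 + p22)
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def naive_auc(scores: dict[str, float], labels: dict[str, str]) -> float:
    """Fraction of (pos, neg) pairs ranked correctly, half credit for ties."""
    pos = [scores[g] for g in scores if labels[g] == "positive"]
    neg = [scores[g] for g in scores if labels[g] == "negative"]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def naive_ks(a: list[float], b: list[float]) -> float:
    """Sup over all sample points of the absolute ECDF difference."""
    points = sorted(set(a) | set(b))
    best = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best
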