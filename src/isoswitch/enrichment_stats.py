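"""Statistical primitives and GO-term enrichment.

Exact hypergeometric upper tails, Benjamini–Hochberg adjustment, a rank-sum
test that is exact (full enumeration) at small sample sizes, hypergeometric
term enrichment over an ontology DAG, and an ancestor/descendant redundancy
filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

#: total-sample-size crossover between exact enumeration and the normal
#: approximation for the rank-sum test
EXACT_RANKSUM_MAX_N = 12


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # set genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # set size
    N: int  # universe size
    p: float
    q: float = float("nan")
    enriched: bool = False


class OntologyDag:
    """Minimal is_a ontology: child->parent edges plus gene annotations.

    Annotations are propagated to all ancestors on construction.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        annotation: Mapping[str, Iterable[str]] | None = None,
        names: Mapping[str, str] | None = None,
    ) -> None:
        self.graph = nx.DiGraph()  # edge child -> parent
        for child, parent in edges:
            self.graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology edges contain a cycle")
        self.names = dict(names or {})
        self.gene_terms: dict[str, frozenset[str]] = {}
        self.term_genes: dict[str, set[str]] = {}
        if annotation:
            for gene, terms in annotation.items():
                closed: set[str] = set()
                for t in terms:
                    closed.add(t)
                    if t in self.graph:
                        closed |= nx.descendants(self.graph, t)  # ancestors (is_a)
                self.gene_terms[gene] = frozenset(closed)
                for t in closed:
                    self.term_genes.setdefault(t, set()).add(gene)

    def terms(self) -> list[str]:
        return sorted(set(self.graph.nodes) | set(self.term_genes))

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            if term not in self.term_genes:
                raise KeyError(f"term {term!r} not in ontology")
            return set()
        return set(nx.descendants(self.graph, term))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed via log-space summation of the point masses for stability.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    lo = max(k, max(0, n - (N - K)))
    log_denom = math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1)
    logs = []
    for x in range(lo, hi + 1):
        log_num = (
            math.lgamma(K + 1) - math.lgamma(x + 1) - math.lgamma(K - x + 1)
            + math.lgamma(N - K + 1) - math.lgamma(n - x + 1)
            - math.lgamma(N - K - (n - x) + 1)
        )
        logs.append(log_num - log_denom)
    m = max(logs)
    total = m + math.log(sum(math.exp(v - m) for v in logs))
    return min(1.0, math.exp(total))


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, original order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out.tolist()


def _midranks(values: Sequence[float]) -> np.ndarray:
    return sps.rankdata(np.asarray(values, dtype=float), method="average")


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = EXACT_RANKSUM_MAX_N,
) -> tuple[float, float]:
    """Wilcoxon–Mann–Whitney rank-sum test.

    Exact permutation p-value (full enumeration over group assignments, valid
    with ties) when ``len(x)+len(y) <= exact_max_n``; otherwise the normal
    approximation with tie and continuity corrections.  The statistic is the
    rank sum of ``x`` under mid-ranks.  ``alternative``: 'two-sided', 'less'
    (x shifted below y) or 'greater'.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx_, ny = len(x), len(y)
    pooled = list(x) + list(y)
    ranks = _midranks(pooled)
    w_obs = float(ranks[:nx_].sum())

    if nx_ + ny <= exact_max_n:
        sums = [sum(ranks[i] for i in comb) for comb in combinations(range(nx_ + ny), nx_)]
        total = len(sums)
        eps = 1e-9
        ge = sum(1 for s in sums if s >= w_obs - eps)
        le = sum(1 for s in sums if s <= w_obs + eps)
        if alternative == "greater":
            p = ge / total
        elif alternative == "less":
            p = le / total
        else:
            p = min(1.0, 2.0 * min(ge, le) / total)
        return w_obs, p

    # normal approximation with tie correction
    n = nx_ + ny
    mu = nx_ * (n + 1) / 2.0
    _unique, counts = np.unique(np.asarray(pooled, dtype=float), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = nx_ * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return w_obs, 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w_obs - mu - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w_obs - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(w_obs - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(z)
    return w_obs, float(min(1.0, p))


def signed_rank_test(deltas: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    All-zero (or empty-after-zero-removal) input returns p = 1.
    """
    arr = np.asarray(deltas, dtype=float)
    arr = arr[arr != 0]
    if arr.size == 0:
        return 1.0
    if arr.size < 5:
        # exact sign-flip enumeration at tiny n
        ranks = sps.rankdata(np.abs(arr), method="average")
        w_obs = float(ranks[arr > 0].sum())
        n = arr.size
        sums = []
        for mask in range(1 << n):
            sums.append(sum(ranks[i] for i in range(n) if mask >> i & 1))
        total = len(sums)
        ge = sum(1 for s in sums if s >= w_obs - 1e-9)
        le = sum(1 for s in sums if s <= w_obs + 1e-9)
        return min(1.0, 2.0 * min(ge, le) / total)
    res = sps.wilcoxon(arr, alternative="two-sided")
    return float(res.pvalue)


def go_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    dag: OntologyDag,
    q_threshold: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every annotated term, BH-adjusted.

    One test per term with at least one annotated universe gene; rows with
    q < ``q_threshold`` are flagged enriched.  Results sorted by p.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    N = len(universe)
    n = len(gene_set)
    results = []
    for term in sorted(dag.term_genes):
        annotated = dag.term_genes[term] & universe
        K = len(annotated)
        if K < 1:
            continue
        k = len(annotated & gene_set)
        p = hypergeom_upper_tail(k, K, n, N)
        results.append(
            EnrichmentResult(term, dag.names.get(term, term), k, K, n, N, p)
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = q
        r.enriched = q < q_threshold
    return sorted(results, key=lambda r: (r.p, r.term_id))


def reduce_redundant(
    results: Sequence[EnrichmentResult], dag: OntologyDag
) -> list[EnrichmentResult]:
    """Drop the weaker member of every enriched ancestor–descendant pair.

    Among related enriched terms the smaller-p term wins; on a p tie the more
    specific (descendant) term is kept.  Non-enriched rows pass through.
    """
    enriched = [r for r in results if r.enriched]
    for r in enriched:
        dag.ancestors(r.term_id)  # raises KeyError for unknown terms
    dropped: set[str] = set()
    for a in enriched:
        for b in enriched:
            if a.term_id == b.term_id:
                continue
            if b.term_id in dag.ancestors(a.term_id):
                # a is the descendant, b the ancestor
                if a.p < b.p or (a.p == b.p):
                    dropped.add(b.term_id)
                else:
                    dropped.add(a.term_id)
    return [
        r
        for r in results
        if not (r.enriched and r.term_id in dropped)
    ]
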