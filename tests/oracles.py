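"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (direct
combinatorics, exhaustive enumeration, naive interval scans) and must stay
independent of the implementation modules it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


# --------------------------------------------------------------------------
# exact statistics


def hypergeom_tail_bruteforce(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by summing binomial coefficients directly."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            acc += comb(K, x) * comb(N - K, n - x)
    return acc / total


def _rank_of(values):
    """Mid-ranks computed by explicit counting (no scipy)."""
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def rank_sum_p_bruteforce(x, y, alternative="two-sided") -> float:
    """Exact rank-sum p by enumerating every assignment of group labels."""
    pooled = list(x) + list(y)
    ranks = _rank_of(pooled)
    nx = len(x)
    w_obs = sum(ranks[:nx])
    sums = [sum(ranks[i] for i in idx) for idx in combinations(range(len(pooled)), nx)]
    eps = 1e-9
    ge = sum(1 for s in sums if s >= w_obs - eps) / len(sums)
    le = sum(1 for s in sums if s <= w_obs + eps) / len(sums)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


def bh_bruteforce(pvals):
    """Step-up BH by literal definition: q_i = min_{j: p_j >= p_i} p_j*m/rank_j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    qs = [None] * m
    raw = {}
    for rank, i in enumerate(order, start=1):
        raw[i] = pvals[i] * m / rank
    for pos, i in enumerate(order):
        qs[i] = min(min(raw[j] for j in order[pos:]), 1.0)
    return qs


# --------------------------------------------------------------------------
# splice-event oracle: naive scans over exon/intron coordinate pairs


def _introns(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def oracle_events(exons_a, exons_b, strand):
    """Set of (event_type, coords) between two exon chains.

    Naive reformulation: every rule is evaluated by scanning all coordinate
    combinations, without the neighbour-index shortcuts the implementation
    uses.
    """
    out = set()
    in_a, in_b = _introns(exons_a), _introns(exons_b)

    def se(ex_incl, in_incl, in_excl):
        found = set()
        for es, ee in ex_incl[1:-1] if len(ex_incl) > 2 else []:
            for x, y in in_excl:
                if (
                    x < es
                    and ee < y
                    and (x, es) in in_incl
                    and (ee, y) in in_incl
                ):
                    found.add(("SE", (es, ee, x, y)))
        return found

    out |= se(exons_a, set(in_a), in_b)
    out |= se(exons_b, set(in_b), in_a)

    def ri(ex_ret, ex_spl, in_spl):
        found = set()
        for es, ee in ex_ret:
            for x, y in in_spl:
                if (es, x) in set(ex_spl) and (y, ee) in set(ex_spl):
                    found.add(("RI", (x, y, es, ee)))
        return found

    out |= ri(exons_a, exons_b, in_b)
    out |= ri(exons_b, exons_a, in_a)

    # MXE: internal exons unique to each chain, disjoint, same flanking introns'
    # outer boundaries
    for e1 in exons_a[1:-1] if len(exons_a) > 2 else []:
        if e1 in exons_b:
            continue
        for e2 in exons_b[1:-1] if len(exons_b) > 2 else []:
            if e2 in exons_a or not (e1[1] <= e2[0] or e2[1] <= e1[0]):
                continue
            flank1 = [(x, y) for (x, y) in in_a if y == e1[0]] + [
                (x, y) for (x, y) in in_a if x == e1[1]
            ]
            flank2 = [(x, y) for (x, y) in in_b if y == e2[0]] + [
                (x, y) for (x, y) in in_b if x == e2[1]
            ]
            if len(flank1) == 2 and len(flank2) == 2:
                if flank1[0][0] == flank2[0][0] and flank1[1][1] == flank2[1][1]:
                    lo, hi = sorted([e1, e2])
                    out.add(("MXE", (*lo, *hi)))

    # alternative splice sites: intron pairs sharing one boundary, where the
    # exon against the differing boundary starts/ends identically
    for x1, y1 in in_a:
        for x2, y2 in in_b:
            if (x1, y1) == (x2, y2):
                continue
            if y1 == y2 and x1 != x2:
                up1 = [e for e in exons_a if e[1] == x1]
                up2 = [e for e in exons_b if e[1] == x2]
                if up1 and up2 and up1[0][0] == up2[0][0]:
                    label = "A5SS" if strand == "+" else "A3SS"
                    out.add((label, (min(x1, x2), max(x1, x2), y1)))
            if x1 == x2 and y1 != y2:
                dn1 = [e for e in exons_a if e[0] == y1]
                dn2 = [e for e in exons_b if e[0] == y2]
                if dn1 and dn2 and dn1[0][1] == dn2[0][1]:
                    label = "A3SS" if strand == "+" else "A5SS"
                    out.add((label, (x1, min(y1, y2), max(y1, y2))))

    # alternative first / last exons (genomic ends; labels strand-resolved)
    if len(exons_a) > 1 and len(exons_b) > 1:
        fa, fb = exons_a[0], exons_b[0]
        if fa != fb and (fa[1] <= fb[0] or fb[1] <= fa[0]):
            if _introns(exons_a)[0][1] == _introns(exons_b)[0][1]:
                lo, hi = sorted([fa, fb])
                label = "AFE" if strand == "+" else "ALE"
                out.add((label, (*lo, *hi, _introns(exons_a)[0][1])))
        la, lb = exons_a[-1], exons_b[-1]
        if la != lb and (la[1] <= lb[0] or lb[1] <= la[0]):
            if _introns(exons_a)[-1][0] == _introns(exons_b)[-1][0]:
                lo, hi = sorted([la, lb])
                label = "ALE" if strand == "+" else "AFE"
                out.add((label, (*lo, *hi, _introns(exons_a)[-1][0])))

    return out
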