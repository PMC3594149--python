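"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (plain Python data
structures, math module only) so that it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque


def bfs_levels(edges: list[tuple[str, str]], root: str) -> dict[str, int]:
    """Breadth-first level map over child->parent edges, walked downward."""
    children: dict[str, list[str]] = {}
    for child, parent in edges:
        children.setdefault(parent, []).append(child)
    levels = {root: 0}
    queue = deque([root])
    while queue:
        node = queue.popleft()
        for ch in children.get(node, []):
            if ch not in levels:
                levels[ch] = levels[node] + 1
                queue.append(ch)
    return levels


def descendants(edges: list[tuple[str, str]], term: str) -> set[str]:
    """All terms below ``term`` by depth-first walk of child->parent edges."""
    children: dict[str, list[str]] = {}
    for child, parent in edges:
        children.setdefault(parent, []).append(child)
    seen: set[str] = set()
    stack = [term]
    while stack:
        node = stack.pop()
        for ch in children.get(node, []):
            if ch not in seen:
                seen.add(ch)
                stack.append(ch)
    return seen


def transitive_closure(
    edges: list[tuple[str, str]],
    terms: list[str],
    direct: dict[str, set[str]],
) -> dict[str, set[str]]:
    """For each term, the union of direct gene sets over itself and all
    its descendants."""
    by_term: dict[str, set[str]] = {t: set() for t in terms}
    for gene, gos in direct.items():
        for go in gos:
            by_term[go].add(gene)
    out = {}
    for t in terms:
        acc = set(by_term[t])
        for d in descendants(edges, t):
            acc |= by_term[d]
        out[t] = acc
    return out


def hypergeom_mean(n: int, K: int, N: int) -> float:
    """Mean of the hypergeometric pmf by explicit enumeration."""
    denom = math.comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    return sum(
        k * math.comb(K, k) * math.comb(N - K, n - k) for k in range(lo, hi + 1)
    ) / denom


def ks_two_sample(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-sample KS: max ECDF gap plus the asymptotic Kolmogorov SF,
    the alternating series 2*sum (-1)^(k-1) exp(-2 k^2 t^2)."""
    points = sorted(set(a) | set(b))
    m, n = len(a), len(b)
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / m
        fb = sum(1 for v in b if v <= x) / n
        d = max(d, abs(fa - fb))
    t = math.sqrt(m * n / (m + n)) * d
    if t == 0:
        return d, 1.0
    s, k, term = 0.0, 1, 1.0
    while abs(term) > 1e-18 or k < 5:
        term = (-1) ** (k - 1) * math.exp(-2.0 * k * k * t * t)
        s += term
        k += 1
        if k > 10000:
            break
    return d, min(1.0, 2.0 * s)


def wilcoxon_rank_sum(a: list[float], b: list[float]) -> tuple[float, float]:
    """Mann–Whitney U of the first sample with midranks and the
    tie-corrected normal approximation (no continuity correction)."""
    m, n = len(a), len(b)
    combined = sorted(a + b)
    # midranks
    ranks: dict[float, float] = {}
    i = 0
    while i < len(combined):
        j = i
        while j < len(combined) and combined[j] == combined[i]:
            j += 1
        ranks[combined[i]] = (i + 1 + j) / 2.0
        i = j
    r1 = sum(ranks[v] for v in a)
    u1 = r1 - m * (m + 1) / 2.0
    mu = m * n / 2.0
    tie_sum = 0.0
    for v in set(combined):
        t = combined.count(v)
        tie_sum += t**3 - t
    var = m * n / 12.0 * ((m + n + 1) - tie_sum / ((m + n) * (m + n - 1)))
    z = (u1 - mu) / math.sqrt(var)
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return u1, min(1.0, p)


def wilcoxon_exact_p(a: list[float], b: list[float]) -> float:
    """Exact two-sided Mann–Whitney p-value for tie-free data.

    Dynamic programming over rank subsets: dp[c][s] counts the ways to
    pick c of the ranks 1..m+n with sum s; the p-value is the symmetric
    tail mass P(|U - mn/2| >= |u_obs - mn/2|).
    """
    m, n = len(a), len(b)
    combined = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in a) - m * (m + 1) / 2.0
    mu = m * n / 2.0

    max_sum = sum(range(n + 1, m + n + 1))
    dp = [[0] * (max_sum + 1) for _ in range(m + 1)]
    dp[0][0] = 1
    for r in range(1, m + n + 1):
        for c in range(min(r, m), 0, -1):
            row_prev, row = dp[c - 1], dp[c]
            for s in range(max_sum - r, -1, -1):
                if row_prev[s]:
                    row[s + r] += row_prev[s]
    total = sum(dp[m])
    extreme = 0
    for s, ways in enumerate(dp[m]):
        if ways:
            u = s - m * (m + 1) / 2.0
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                extreme += ways
    return extreme / total


def wilcoxon(a: list[float], b: list[float]) -> tuple[float, float]:
    """Rank-sum test dispatch: exact null for tie-free vectors of at most
    25 entries each, tie-corrected normal approximation otherwise."""
    combined = a + b
    no_ties = len(set(combined)) == len(combined)
    if no_ties and max(len(a), len(b)) <= 25:
        u, _ = wilcoxon_rank_sum(a, b)
        return u, wilcoxon_exact_p(a, b)
    return wilcoxon_rank_sum(a, b)
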