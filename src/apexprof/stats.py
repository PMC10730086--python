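"""Shared rank statistics and compact letter displays.

Implements the exact Mann-Whitney U test (full null enumeration via the
standard counting recurrence for small, tie-free samples; normal
approximation with tie correction and continuity correction otherwise) and
the compact-letter-display convention used throughout the package: groups
sharing a letter are not significantly different at the chosen alpha.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import networkx as nx
from scipy import stats as sps


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of rank assignments of m-vs-n samples giving each U in 0..m*n.

    Classic recurrence: c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u).
    """
    if m == 0 or n == 0:
        return tuple([1] + [0] * (m * n))
    out = []
    prev1 = _u_counts(m - 1, n)
    prev2 = _u_counts(m, n - 1)
    for u in range(m * n + 1):
        a = prev1[u - n] if 0 <= u - n <= (m - 1) * n else 0
        b = prev2[u] if u <= m * (n - 1) else 0
        out.append(a + b)
    return tuple(out)


def mannwhitney_u(
    x, y, exact_max_n: int = 12
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p, method)`` where U is the statistic of the first sample.
    The exact null distribution is enumerated when the combined sample size
    is at most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction is used.
    Each sample needs at least 2 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("each group needs at least 2 samples")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:m].sum()
    u = r1 - m * (m + 1) / 2.0
    has_ties = len(np.unique(pooled)) < m + n

    if m + n <= exact_max_n and not has_ties:
        counts = np.asarray(_u_counts(m, n), dtype=float)
        total = counts.sum()
        k = int(round(u))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, p, "exact"

    N = m + n
    mu = m * n / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (N * (N - 1.0))
    var = m * n / 12.0 * ((N + 1.0) - tie_term)
    if var <= 0:  # all observations identical
        return u, 1.0, "asymptotic"
    z = max(0.0, abs(u - mu) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return u, p, "asymptotic"


def compact_letters(
    group_names: list[str],
    pairwise_p: dict[tuple[str, str], float],
    group_order_stat: dict[str, float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Assign letters so groups sharing one are not significantly different.

    Builds the "not significantly different" graph (edge when p > alpha, or
    p is NaN) and letters its maximal cliques; each group receives the
    letters of every clique containing it.  Cliques are ordered by the
    smallest group mean they contain so that 'a' labels the lowest groups.
    """
    G = nx.Graph()
    G.add_nodes_from(group_names)
    for (a, b), p in pairwise_p.items():
        if np.isnan(p) or p > alpha:
            G.add_edge(a, b)
    cliques = list(nx.find_cliques(G))
    cliques.sort(key=lambda c: (min(group_order_stat[g] for g in c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in group_names}
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for g in clique:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def dunn_posthoc(
    samples: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z statistics on mean ranks with tie correction; two-sided p-values with
    Bonferroni (default) or Holm adjustment.
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        k = len(samples[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1.0))
    raw = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            var = (N * (N + 1) / 12.0 - tie_term) * (
                1.0 / len(samples[a]) + 1.0 / len(samples[b])
            )
            if var <= 0:
                raw[(a, b)] = 1.0
                continue
            z = abs(mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            raw[(a, b)] = 2.0 * sps.norm.sf(z)
    m = len(raw)
    if adjust == "bonferroni":
        return {k: min(1.0, v * m) for k, v in raw.items()}
    if adjust == "holm":
        items = sorted(raw.items(), key=lambda kv: kv[1])
        adj = {}
        running = 0.0
        for rank, (k, v) in enumerate(items):
            running = max(running, min(1.0, (m - rank) * v))
            adj[k] = running
        return adj
    raise ValueError(f"unknown adjustment {adjust!r}")
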