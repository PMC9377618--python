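"""Independent brute-force reference implementations used by the tests.

These deliberately re-derive each quantity from its definition with plain
Python sets and loops (or a third-party library), never by calling the code
paths under test.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def brute_hwi(n: int, period_groups: list[list[set[int]]]):
    """Half-weight indices by direct enumeration of the definition.

    ``period_groups``: per sampling period, a list of member sets.
    Returns (hwi, x, ya, yb, yab) as dense (n, n) arrays.
    """
    x = np.zeros((n, n), dtype=int)
    ya = np.zeros((n, n), dtype=int)
    yb = np.zeros((n, n), dtype=int)
    yab = np.zeros((n, n), dtype=int)
    for groups in period_groups:
        seen = set().union(*groups) if groups else set()
        for i, j in itertools.permutations(range(n), 2):
            together = any(i in g and j in g for g in groups)
            if together:
                if i < j:
                    pass
                x[i, j] += 1
            elif i in seen and j in seen:
                yab[i, j] += 1
            elif i in seen:
                ya[i, j] += 1
            elif j in seen:
                yb[i, j] += 1
    hwi = np.zeros((n, n))
    for i, j in itertools.permutations(range(n), 2):
        denom = x[i, j] + yab[i, j] + 0.5 * (ya[i, j] + yb[i, j])
        hwi[i, j] = x[i, j] / denom if denom > 0 else 0.0
    return hwi, x, ya, yb, yab


def brute_slar(period_groups: list[list[set[int]]], times, n: int, bin_edges):
    """Standardized lagged association rate by event-level enumeration."""
    assoc = []
    for groups in period_groups:
        s = {i: set() for i in range(n)}
        for g in groups:
            for i in g:
                s[i] |= g - {i}
        assoc.append(s)
    nb = len(bin_edges) - 1
    num = np.zeros(nb)
    den = np.zeros(nb)
    for t, u in itertools.permutations(range(len(period_groups)), 2):
        lag = abs(times[u] - times[t])
        b = None
        for k in range(nb):
            if bin_edges[k] < lag <= bin_edges[k + 1]:
                b = k
        if b is None:
            continue
        for a in range(n):
            if assoc[t][a] and assoc[u][a]:
                num[b] += len(assoc[t][a] & assoc[u][a]) / len(assoc[u][a])
                den[b] += 1
    with np.errstate(invalid="ignore"):
        g = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return g, den


def nx_modularity(hwi: np.ndarray, labels) -> float:
    """Weighted Newman modularity via networkx (independent implementation)."""
    n = hwi.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if hwi[i, j] > 0:
                g.add_edge(i, j, weight=float(hwi[i, j]))
    labels = np.asarray(labels)
    communities = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
    return nx.algorithms.community.modularity(g, communities, weight="weight")


def random_period_groups(rng, n_ind: int, n_periods: int, max_groups: int = 3):
    """Random small group-structured dataset for oracle comparisons."""
    out = []
    for _ in range(n_periods):
        groups = []
        pool = list(rng.permutation(n_ind))
        n_groups = rng.integers(0, max_groups + 1)
        for _ in range(n_groups):
            if not pool:
                break
            size = int(rng.integers(1, max(2, len(pool) + 1)))
            groups.append(set(pool[:size]))
            pool = pool[size:]
        out.append(groups)
    return out
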