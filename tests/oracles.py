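"""Independent brute-force oracles used to validate the vectorized code.

Everything here is written as literal loop-and-count code with Python
sets and ``math`` scalars, deliberately sharing no code path with the
package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import norm


def neighborhood_bf(values, k, box_fraction):
    """Sort cells by (|value - value_k|, index), take the first ceil(a*n)."""
    values = list(values)
    n = len(values)
    q = math.ceil(box_fraction * n)
    order = sorted(range(n), key=lambda c: (abs(values[c] - values[k]), c))
    return set(order[:q])


def overlap_stat_bf(n_x, n_y, n_xy, n):
    den = n_x * n_y * (n - n_x) * (n - n_y) / (n - 1)
    if den <= 0:
        return 0.0
    return (n * n_xy - n_x * n_y) / math.sqrt(den)


def tested_genes_bf(values, min_expressing_cells):
    return [g for g in range(values.shape[0])
            if int((values[g] > 0).sum()) >= min_expressing_cells]


def csn_adjacency_bf(values, k, box_fraction, alpha, min_expressing_cells):
    """Literal CSN construction: all counts over the cells other than k."""
    G, n = values.shape
    z_crit = norm.ppf(1 - alpha)
    tested = tested_genes_bf(values, min_expressing_cells)
    boxes = {g: neighborhood_bf(values[g], k, box_fraction) - {k} for g in range(G)}
    adj = np.zeros((G, G), dtype=bool)
    if len(tested) < 2:
        return adj
    for x, y in combinations(tested, 2):
        stat = overlap_stat_bf(len(boxes[x]), len(boxes[y]),
                               len(boxes[x] & boxes[y]), n - 1)
        if stat > z_crit:
            adj[x, y] = adj[y, x] = True
    return adj


def csn_statistics_bf(values, k, box_fraction):
    """Dense statistic matrix over all gene pairs (no filter, no threshold)."""
    G, n = values.shape
    boxes = {g: neighborhood_bf(values[g], k, box_fraction) - {k} for g in range(G)}
    out = np.zeros((G, G))
    for x in range(G):
        for y in range(G):
            if x != y:
                out[x, y] = overlap_stat_bf(len(boxes[x]), len(boxes[y]),
                                            len(boxes[x] & boxes[y]), n - 1)
    return out


def conditional_genes_bf(adj, m):
    deg = adj.sum(axis=0)
    candidates = [g for g in range(len(deg)) if deg[g] > 0]
    candidates.sort(key=lambda g: (-deg[g], g))
    return candidates[:m]


def ccsn_adjacency_bf(values, k, box_fraction, alpha, m, min_expressing_cells):
    """Literal CCSN: CSN edges pruned by the mean conditional statistic."""
    G, n = values.shape
    z_crit = norm.ppf(1 - alpha)
    csn = csn_adjacency_bf(values, k, box_fraction, alpha, min_expressing_cells)
    if m == 0:
        return csn
    cond = conditional_genes_bf(csn, m)
    if not cond:
        return csn
    boxes = {g: neighborhood_bf(values[g], k, box_fraction) - {k} for g in range(G)}
    adj = np.zeros_like(csn)
    for x in range(G):
        for y in range(x + 1, G):
            if not csn[x, y]:
                continue
            if x in cond or y in cond:
                adj[x, y] = adj[y, x] = True
                continue
            stats = []
            for z in cond:
                universe = boxes[z]
                n_z = len(universe)
                if n_z < 2:
                    stats.append(0.0)
                    continue
                n_xz = len(boxes[x] & universe)
                n_yz = len(boxes[y] & universe)
                n_xyz = len(boxes[x] & boxes[y] & universe)
                stats.append(overlap_stat_bf(n_xz, n_yz, n_xyz, n_z))
            if sum(stats) / len(stats) > z_crit:
                adj[x, y] = adj[y, x] = True
    return adj


def maximal_cliques_bf(adjacency_sets, n_nodes):
    """All maximal cliques by exhaustive subset enumeration (bitmask)."""
    masks = [0] * n_nodes
    for v in range(n_nodes):
        for u in adjacency_sets[v]:
            masks[v] |= 1 << u
    cliques = []
    for s in range(1, 1 << n_nodes):
        members = [v for v in range(n_nodes) if s >> v & 1]
        ok = all((masks[v] | (1 << v)) & s == s for v in members)
        if not ok:
            continue
        # maximal: no outside vertex adjacent to every member
        maximal = True
        for u in range(n_nodes):
            if s >> u & 1:
                continue
            if masks[u] & s == s:
                maximal = False
                break
        if maximal:
            cliques.append(set(members))
    return cliques


def mcc_bf(adjacency_sets, n_nodes):
    """MCC by exhaustive clique enumeration; isolated nodes score 0."""
    scores = {v: 0 for v in range(n_nodes)}
    for clique in maximal_cliques_bf(adjacency_sets, n_nodes):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def bh_bf(pvals):
    """Step-up BH by the textbook recipe."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted


def hypergeom_tail_bf(k, M, K, N):
    """P(X >= k) for X ~ Hypergeom(M population, K successes, N draws)."""
    total = 0
    for i in range(k, min(K, N) + 1):
        total += math.comb(K, i) * math.comb(M - K, N - i)
    return total / math.comb(M, N)


def welch_bf(a, b):
    """Welch t and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def logrank_bf(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square by the O-E / V tabulation."""
    from scipy.stats import chi2
    grid = sorted({t for t, e in zip(list(times_a) + list(times_b),
                                     list(events_a) + list(events_b)) if e == 1})
    O_minus_E = 0.0
    V = 0.0
    for t in grid:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        E_a = d * n_a / n
        O_minus_E += d_a - E_a
        V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    stat = O_minus_E ** 2 / V
    return stat, float(chi2.sf(stat, 1))


def km_bf(times, events):
    """Hand product-limit table: (unique event times, S just after each)."""
    pairs = sorted(zip(times, events))
    grid = sorted({t for t, e in pairs if e == 1})
    S = 1.0
    out = []
    for t in grid:
        at_risk = sum(1 for x, _ in pairs if x >= t)
        d = sum(1 for x, e in pairs if x == t and e == 1)
        S *= 1 - d / at_risk
        out.append((t, S))
    return out
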