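"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from first principles (enumeration,
closed form, or a naive algorithm) without touching the implementation
path it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# --------------------------------------------------- alignment enumeration

def oracle_align_score(mirna: str, window: str,
                       match_wc: float = 5.0, match_wobble: float = 1.0,
                       mismatch: float = -3.0, gap_open: float = -9.0,
                       gap_extend: float = -4.0, seed_scale: float = 2.0,
                       seed_start: int = 2, seed_end: int = 8) -> float:
    """Best local alignment score by exhaustive enumeration of pairings.

    A local alignment is a monotone set of (miRNA position, window
    position) column pairs; unpaired stretches between consecutive columns
    cost gap_open + (g-1)*gap_extend per gap, flanks are free.  The empty
    alignment scores 0.
    """
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "U"), ("U", "G")}
    L, T = len(mirna), len(window)
    rev = mirna[::-1]

    def col_score(k: int, j: int) -> float:
        mb, tb = rev[k], window[j]
        pos5 = L - k
        scale = seed_scale if seed_start <= pos5 <= seed_end else 1.0
        if (mb, tb) in wc:
            return match_wc * scale
        if (mb, tb) in wobble:
            return match_wobble * scale
        return mismatch * scale

    def gap_cost(g: int) -> float:
        return 0.0 if g == 0 else gap_open + (g - 1) * gap_extend

    best = 0.0
    for k in range(1, min(L, T) + 1):
        for mir_pos in combinations(range(L), k):
            for win_pos in combinations(range(T), k):
                s = col_score(mir_pos[0], win_pos[0])
                for a in range(1, k):
                    s += col_score(mir_pos[a], win_pos[a])
                    s += gap_cost(mir_pos[a] - mir_pos[a - 1] - 1)
                    s += gap_cost(win_pos[a] - win_pos[a - 1] - 1)
                if s > best:
                    best = s
    return best


# ------------------------------------------------------- maximal cliques

def oracle_maximal_cliques(nodes: list[str],
                           edges: set[tuple[str, str]]) -> list[set[str]]:
    """All maximal cliques by subset enumeration (n <= ~14)."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def is_clique(sub: tuple[str, ...]) -> bool:
        return all(b in adj[a] for a, b in combinations(sub, 2))

    cliques = []
    n = len(nodes)
    for r in range(1, n + 1):
        for sub in combinations(nodes, r):
            if is_clique(sub):
                cliques.append(set(sub))
    return [c for c in cliques
            if not any(c < other for other in cliques)]


def oracle_mcc(nodes: list[str], edges: set[tuple[str, str]]) -> dict[str, int]:
    import math
    scores = {n: 0 for n in nodes}
    for clique in oracle_maximal_cliques(nodes, edges):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


# ------------------------------------------------------------ classic KS

def oracle_classic_ks(order: list[str], gene_set: set[str]) -> float:
    """Unweighted GSEA ES: signed max deviation of the hit/miss walk."""
    n = len(order)
    n_hit = sum(1 for g in order if g in gene_set)
    running, best = 0.0, 0.0
    for g in order:
        running += 1.0 / n_hit if g in gene_set else -1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


# -------------------------------------------------------------- log-rank

def oracle_logrank(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by direct O-E/V arithmetic."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)] + \
              [(t, e, 1) for t, e in zip(times_b, events_b)]
    event_times = sorted({t for t, e, _ in records if e})
    O = E = V = 0.0
    for t in event_times:
        at_risk_a = sum(1 for tt, _, g in records if tt >= t and g == 0)
        at_risk = sum(1 for tt, _, g in records if tt >= t)
        d = sum(1 for tt, e, _ in records if tt == t and e)
        d_a = sum(1 for tt, e, g in records if tt == t and e and g == 0)
        O += d_a
        E += d * at_risk_a / at_risk
        if at_risk > 1:
            V += d * (at_risk_a / at_risk) * (1 - at_risk_a / at_risk) * \
                 (at_risk - d) / (at_risk - 1)
    return (O - E) ** 2 / V


# ------------------------------------------------------------------- KM

def oracle_km_no_censoring(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """With no censoring the product-limit estimate is 1 - ECDF."""
    ts = np.sort(np.unique(times))
    surv = np.array([(times > t).mean() for t in ts])
    return ts, surv
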