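"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (literal pattern tests, exhaustive
enumeration, all-pairs loops, union-find) and shares no code path with the
package beyond its public data types.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_seed_sites(transcript: str, seed: str, site_types) -> list[tuple]:
    """Literal per-offset pattern tests for the four canonical site types.

    Returns (start, end, type) tuples sorted by start; each 6-nt core
    occurrence is reported once with the highest-priority supported type
    among the requested ones.
    """
    s7 = revcomp(seed)
    s6 = s7[1:]
    wanted = set(site_types)
    out = []
    for j in range(len(transcript) - 5):
        if transcript[j : j + 6] != s6:
            continue
        candidates = []
        if transcript[j - 1 : j + 7] == s7 + "A" and j >= 1:
            candidates.append(("8mer", j - 1, j + 7))
        if transcript[j - 1 : j + 6] == s7 and j >= 1:
            candidates.append(("7mer-m8", j - 1, j + 6))
        if transcript[j : j + 7] == s6 + "A":
            candidates.append(("7mer-A1", j, j + 7))
        candidates.append(("6mer", j, j + 6))
        for t, a, b in candidates:  # already in priority order
            if t in wanted:
                out.append((a, b, t))
                break
    return sorted(out)


def enumerate_pwm(pfm: np.ndarray, background: np.ndarray, pseudocount: float,
                  bin_width: float) -> dict[int, float]:
    """Exhaustive 4^k word enumeration of the discretized PWM score law.

    Scores are per-position log2 odds rounded to integer bins, as in the
    scanner; words with a zero-probability base (pseudocount 0) are dropped.
    Returns {integer score: probability}.
    """
    k = len(pfm)
    totals = pfm.sum(axis=1, keepdims=True)
    probs = (pfm + pseudocount) / (totals + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        lodds = np.log2(probs / background[None, :])
    dist: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=k):
        if any(not np.isfinite(lodds[j, b]) for j, b in enumerate(word)):
            continue
        score = int(sum(int(np.round(lodds[j, b] / bin_width))
                        for j, b in enumerate(word)))
        mass = float(np.prod([background[b] for b in word]))
        dist[score] = dist.get(score, 0.0) + mass
    return dist


def pwm_sf(dist: dict[int, float], score_index: int) -> float:
    return sum(p for s, p in dist.items() if s >= score_index)


def naive_window_scan(codes: np.ndarray, lodds_q: np.ndarray) -> list[int]:
    """Window scores by an explicit O(L*k) double loop."""
    k = len(lodds_q)
    return [
        int(sum(int(lodds_q[j, codes[i + j]]) for j in range(k)))
        for i in range(len(codes) - k + 1)
    ]


def brute_force_cooccurrences(m_intervals, r_intervals, d: int) -> int:
    """All-pairs overlap/adjacency count: g < d or g < 0."""
    n = 0
    for sa, ea in m_intervals:
        for sb, eb in r_intervals:
            g = max(sa, sb) - min(ea, eb)
            if g < d or g < 0:
                n += 1
    return n


def union_find_components(nodes, edges) -> list[frozenset]:
    """Connected components by a plain union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def step_up_bh(pvalues) -> list[float]:
    """Textbook Benjamini-Hochberg step-up, independent implementation."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        q[i] = running
    return q


def pearson_r(x, y) -> tuple[float, float]:
    """Textbook Pearson r and its two-sided t-transform p-value."""
    import math

    from scipy.stats import t as tdist

    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * tdist.sf(abs(tstat), n - 2)
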