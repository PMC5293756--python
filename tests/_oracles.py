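"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (nested loops, direct
summation) and stays independent of the code paths it validates.
"""

from __future__ import annotations

import math


def sw_score_affine(a: str, b: str, sub, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive Smith–Waterman/Gotoh DP, plain Python.

    ``sub(x, y)`` returns the substitution score.  A gap of length k costs
    ``gap_open + (k - 1) * gap_extend``.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def parse_degenerate(pattern: str) -> list[set[str] | None]:
    """Expand a degenerate motif into per-position residue sets (None = any)."""
    out: list[set[str] | None] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            out.append(set(pattern[i + 1 : j]))
            i = j + 1
        elif c == "x":
            j = i + 1
            digits = ""
            while j < len(pattern) and pattern[j].isdigit():
                digits += pattern[j]
                j += 1
            out.extend([None] * (int(digits) if digits else 1))
            i = j
        else:
            out.append({c})
            i += 1
    return out


def brute_motif_positions(seq: str, pattern: str) -> list[int]:
    """All 1-based (overlapping) match starts by direct sliding comparison."""
    slots = parse_degenerate(pattern)
    L = len(slots)
    hits = []
    for start in range(len(seq) - L + 1):
        ok = True
        for off, allowed in enumerate(slots):
            if allowed is not None and seq[start + off] not in allowed:
                ok = False
                break
        if ok:
            hits.append(start + 1)
    return hits


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = 0.0
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x) / denom
    return min(total, 1.0)


def bh_step_up(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg q-values, written the slow direct way."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = indexed[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        q[i] = min(val, 1.0)
        prev = val
    return q


def brute_tandem_arrays(
    seq: str, min_unit: int = 3, max_unit: int = 100,
    min_copies: int = 3, min_identity: float = 0.7,
) -> list[tuple[int, int, int]]:
    """All (start0, unit_len, copies) tandem arrays by full enumeration.

    Checks every (offset, unit length) pair and counts consecutive units
    whose adjacent identity reaches ``min_identity``, rejecting arrays whose
    region is explained by a period below ``min_unit``.
    """
    n = len(seq)
    found = []
    for L in range(min_unit, min(max_unit, n // min_copies) + 1):
        for start in range(n - min_copies * L + 1):
            copies = 1
            while start + (copies + 1) * L <= n:
                u1 = seq[start + (copies - 1) * L : start + copies * L]
                u2 = seq[start + copies * L : start + (copies + 1) * L]
                ident = sum(x == y for x, y in zip(u1, u2)) / L
                if ident >= min_identity - 1e-12:
                    copies += 1
                else:
                    break
            if copies >= min_copies:
                region = seq[start : start + copies * L]
                small_period = False
                for p in range(1, min_unit):
                    if len(region) >= 2 * p:
                        ident = sum(
                            x == y for x, y in zip(region[:-p], region[p:])
                        ) / (len(region) - p)
                        if ident >= min_identity - 1e-12:
                            small_period = True
                            break
                if not small_period:
                    found.append((start, L, copies))
    return found


def connected_components(nodes: list[str], edges: list[tuple[str, str]]) -> list[frozenset]:
    """Plain breadth-first connected components."""
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for v in nodes:
        if v in seen:
            continue
        queue, comp = [v], set()
        while queue:
            u = queue.pop()
            if u in comp:
                continue
            comp.add(u)
            queue.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def two_proportion_z(x1: float, n1: float, x2: float, n2: float) -> float:
    """Unpooled two-proportion z statistic, direct formula."""
    p1, p2 = x1 / n1, x2 / n2
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return (p1 - p2) / se
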