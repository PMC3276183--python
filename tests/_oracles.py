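"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by the most direct method possible
(all-pairs scans, transitive closure, sorted-array quantiles) and share no
code with the implementation paths they check.
"""

from __future__ import annotations

import math

from cnvburden.core import Algorithm, CnvCall


def bf_overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def bf_reciprocal_ok(a, b, min_overlap: float) -> bool:
    if a.interval.chrom != b.interval.chrom:
        return False
    ov = bf_overlap(a.interval.start, a.interval.end, b.interval.start, b.interval.end)
    return (
        ov >= min_overlap * (a.interval.end - a.interval.start)
        and ov >= min_overlap * (b.interval.end - b.interval.start)
    )


def bf_consensus(
    calls: list[CnvCall], min_overlap: float = 0.5
) -> set[tuple]:
    """All-pairs O(n^2) consensus: (sample, chrom, start, end, state, algos)."""
    seeds = [c for c in calls if c.algorithm is Algorithm.IPATTERN]
    support = [
        c for c in calls
        if c.algorithm in (Algorithm.PENNCNV, Algorithm.QUANTISNP)
    ]
    out = set()
    for seed in seeds:
        matched = [
            s for s in support
            if s.sample_id == seed.sample_id
            and s.state is seed.state
            and bf_reciprocal_ok(seed, s, min_overlap)
        ]
        if not matched:
            continue
        start = min([seed.interval.start] + [m.interval.start for m in matched])
        end = max([seed.interval.end] + [m.interval.end for m in matched])
        algos = frozenset(
            {seed.algorithm} | {m.algorithm for m in matched}
        )
        out.add((
            seed.sample_id, seed.interval.chrom, start, end, seed.state, algos,
        ))
    return out


def bf_transitive_clusters(calls, min_overlap: float = 0.5) -> list[frozenset]:
    """Transitive closure of the same-state reciprocal-overlap relation."""
    n = len(calls)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and calls[i].state is calls[j].state and bf_reciprocal_ok(
                calls[i], calls[j], min_overlap
            ):
                adj[i][j] = True
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, group = [i], set()
        while stack:
            k = stack.pop()
            if seen[k]:
                continue
            seen[k] = True
            group.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and not seen[j])
        clusters.append(frozenset(calls[k].call_id for k in group))
    return clusters


def bf_quantile(sorted_vals: list[float], q: float) -> float:
    """Linear-interpolation quantile on a pre-sorted list (textbook form)."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def bf_chi2_2x2(a, b, c, d) -> float:
    """Chi-square from first principles via expected counts."""
    n = a + b + c + d
    exp = [
        (a + b) * (a + c) / n, (a + b) * (b + d) / n,
        (c + d) * (a + c) / n, (c + d) * (b + d) / n,
    ]
    obs = [a, b, c, d]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))
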