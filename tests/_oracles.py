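"""Independent brute-force oracles, written as literal transcriptions of
the method definitions with plain Python loops.  They deliberately share
no code with the package implementation.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations


# ---------------------------------------------------------------------------
# SAM


def _sam_stat_and_s(values, hi_idx, n1, n2, s0):
    hi_set = set(hi_idx)
    hi = [v for i, v in enumerate(values) if i in hi_set]
    lo = [v for i, v in enumerate(values) if i not in hi_set]
    mh = sum(hi) / n1
    ml = sum(lo) / n2
    ss = sum((v - mh) ** 2 for v in hi) + sum((v - ml) ** 2 for v in lo)
    s = math.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)
    return (mh - ml) / (s + s0), s


def brute_sam(X, n1, n2, s0_method="median", s0_value=0.0):
    """Exhaustive-permutation SAM on a gene x sample nested list.

    Samples 0..n1-1 are the observed high group.  Returns per-gene
    (d, dbar, q) lists following the two-class up-side procedure:
    dbar is the mean permuted order statistic at each gene's rank, and q
    is the minimum over admitting margins of median-false/called, made
    monotone along the d ranking.
    """
    G = len(X)
    n = n1 + n2
    obs = tuple(range(n1))
    s_vals = [_sam_stat_and_s(X[g], obs, n1, n2, 0.0)[1] for g in range(G)]
    if s0_method == "median":
        s0 = statistics.median(s_vals)
    elif s0_method == "fixed":
        s0 = s0_value
    else:
        raise ValueError(s0_method)
    d = [_sam_stat_and_s(X[g], obs, n1, n2, s0)[0] for g in range(G)]

    perm_sorted = []
    for hi_idx in combinations(range(n), n1):
        stats = sorted(_sam_stat_and_s(X[g], hi_idx, n1, n2, s0)[0] for g in range(G))
        perm_sorted.append(stats)

    order = sorted(range(G), key=lambda g: d[g])
    dbar_by_rank = [statistics.mean(ps[i] for ps in perm_sorted) for i in range(G)]
    dbar = [0.0] * G
    diff = {}
    for rank, g in enumerate(order):
        dbar[g] = dbar_by_rank[rank]
        diff[g] = d[g] - dbar[g]

    pos_genes = [g for g in range(G) if d[g] > 0]
    q = [1.0] * G
    if pos_genes:
        fdr_at = {}
        for g0 in pos_genes:
            delta = diff[g0]
            called = [g for g in pos_genes if diff[g] >= delta]
            cutoff = min(d[g] for g in called)
            counts = [sum(1 for v in ps if v >= cutoff) for ps in perm_sorted]
            false = statistics.median(counts)
            fdr_at[g0] = min(1.0, false / len(called))
        for g in pos_genes:
            q[g] = min(fdr_at[g0] for g0 in pos_genes if diff[g0] <= diff[g])
        for g in pos_genes:  # monotone along the d ranking
            q[g] = min(q[j] for j in pos_genes if d[j] <= d[g])
    return d, dbar, q


# ---------------------------------------------------------------------------
# ssGSEA


def brute_ssgsea(values, gene_ids, members, alpha):
    """Explicit-ECDF single-sample enrichment score."""
    pairs = sorted(zip(gene_ids, values), key=lambda gv: (-gv[1], gv[0]))
    G = len(pairs)
    rank_value = {g: G - i for i, (g, _) in enumerate(pairs)}
    total_in = sum(rank_value[g] ** alpha for g, _ in pairs if g in members)
    n_out = sum(1 for g, _ in pairs if g not in members)
    p_in, p_out = [], []
    running_in = 0.0
    running_out = 0
    for g, _ in pairs:
        if g in members:
            running_in += rank_value[g] ** alpha
        else:
            running_out += 1
        p_in.append(running_in / total_in)
        p_out.append(running_out / n_out)
    return sum(a - b for a, b in zip(p_in, p_out))


# ---------------------------------------------------------------------------
# two-class GSEA running sum


def brute_gsea_es(metric, gene_ids, members):
    """Maximum-deviation weighted Kolmogorov-Smirnov running sum."""
    pairs = sorted(zip(gene_ids, metric), key=lambda gm: (-gm[1], gm[0]))
    hit_total = sum(abs(m) for g, m in pairs if g in members)
    n_members = sum(1 for g, _ in pairs if g in members)
    n_miss = len(pairs) - n_members
    if hit_total == 0:
        hit_total = float(n_members)
        pairs = [(g, 1.0 if g in members else m) for g, m in pairs]
    running = 0.0
    best = 0.0
    for g, m in pairs:
        if g in members:
            running += abs(m) / hit_total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


# ---------------------------------------------------------------------------
# log-rank


def brute_logrank_2group(t1, e1, t2, e2):
    """Two-group log-rank chi-square by literal risk-set tabulation."""
    event_times = sorted({t for t, e in list(zip(t1, e1)) + list(zip(t2, e2)) if e == 1})
    O1 = E1 = V = 0.0
    for et in event_times:
        n1 = sum(1 for t in t1 if t >= et)
        n2 = sum(1 for t in t2 if t >= et)
        d1 = sum(1 for t, e in zip(t1, e1) if t == et and e == 1)
        d2 = sum(1 for t, e in zip(t2, e2) if t == et and e == 1)
        N = n1 + n2
        D = d1 + d2
        O1 += d1
        E1 += D * n1 / N
        if N > 1:
            V += D * (N - D) / (N - 1) * (n1 / N) * (1 - n1 / N)
    if V == 0:
        return 0.0
    return (O1 - E1) ** 2 / V


def brute_km(times, events, at):
    """Product-limit survival evaluated at time `at`."""
    s = 1.0
    for et in sorted({t for t, e in zip(times, events) if e == 1}):
        if et > at:
            break
        r = sum(1 for t in times if t >= et)
        d = sum(1 for t, e in zip(times, events) if t == et and e == 1)
        s *= 1 - d / r
    return s
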