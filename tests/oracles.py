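"""Independent brute-force oracles used by the test suite.

Each function is a deliberately naive re-derivation (enumeration, explicit
scan, textbook formula) of a quantity the package computes by a different
route; they must stay free of hmcpipe imports.
"""

from __future__ import annotations

from math import comb

import numpy as np


def hypergeom_upper_tail(k: int, n_class: int, n_sel: int, n_uni: int) -> float:
    """P[X >= k] by full enumeration of the hypergeometric pmf."""
    total = comb(n_uni, n_sel)
    lo = max(0, n_sel - (n_uni - n_class))
    hi = min(n_class, n_sel)
    acc = 0
    for x in range(max(k, lo), hi + 1):
        acc += comb(n_class, x) * comb(n_uni - n_class, n_sel - x)
    return acc / total


def hypergeom_lower_tail(k: int, n_class: int, n_sel: int, n_uni: int) -> float:
    total = comb(n_uni, n_sel)
    lo = max(0, n_sel - (n_uni - n_class))
    acc = 0
    for x in range(lo, min(k, min(n_class, n_sel)) + 1):
        acc += comb(n_class, x) * comb(n_uni - n_class, n_sel - x)
    return acc / total


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    current_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, p[i] * m / rank_from_top)
        current_min = min(current_min, val)
        adj[i] = current_min
    return adj


def scan_segments(values, tau: float, gap_bins: int, min_bins_len_bp: int,
                  bin_size: int) -> list[tuple[int, int]]:
    """Single-pass threshold/gap/length scan over one binned track."""
    runs = []
    start = None
    for i, v in enumerate(list(values) + [-(10 ** 9)]):  # sentinel flush
        if v >= tau:
            if start is None:
                start = i
            end = i + 1
        elif start is not None:
            runs.append((start, end))
            start = None
    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) <= gap_bins:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s * bin_size, e * bin_size) for s, e in merged
            if (e - s) * bin_size >= min_bins_len_bp]


def all_pairs_links(enhancers, genes, window: int, concordant_only: bool):
    """Brute-force enhancer-promoter pairing: every pair, plain loops.

    ``enhancers``: list of (id, chrom, start, end, direction);
    ``genes``: list of (id, chrom, tss, direction).
    """
    out = []
    for eid, echrom, es, ee, edir in enhancers:
        mid = (es + ee) // 2
        for gid, gchrom, tss, gdir in genes:
            if echrom != gchrom:
                continue
            dist = tss - mid
            if abs(dist) > window:
                continue
            if concordant_only and edir != gdir:
                continue
            out.append((eid, gid, dist, edir == gdir))
    return out


def pearson_by_formula(x, y) -> float:
    """Textbook Pearson r via explicit sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def gsea_running_sum(scores, is_hit, weight: float = 1.0) -> float:
    """Hand running-sum ES (scores already sorted descending)."""
    w = [abs(s) ** weight for s in scores]
    total_hit = sum(wi for wi, h in zip(w, is_hit) if h)
    n_miss = sum(1 for h in is_hit if not h)
    running, best = 0.0, 0.0
    for wi, h in zip(w, is_hit):
        running += wi / total_hit if h else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Brute-force size factors: per-sample median of count/geomean over
    features positive in every sample."""
    keep = [i for i in range(counts.shape[0]) if (counts[i] > 0).all()]
    factors = []
    for s in range(counts.shape[1]):
        ratios = []
        for i in keep:
            geo = np.exp(np.mean(np.log(counts[i])))
            ratios.append(counts[i, s] / geo)
        factors.append(float(np.median(ratios)))
    return np.array(factors)
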