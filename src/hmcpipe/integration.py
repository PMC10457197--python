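"""Enhancer-promoter pairing, overlap tests, preranked GSEA, retention.

These are the cross-modality analyses: linking differentially transcribed
enhancers to co-regulated promoters within a genomic window, hypergeometric
overlap of gene sets (e.g. repressed genes later rescued by treatment),
a weighted Kolmogorov-Smirnov gene-set enrichment statistic on a preranked
list, and methylation retention of a probe set after treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, ConfigurationError

__all__ = [
    "pair_enhancer_promoter",
    "overlap_test",
    "OverlapTestResult",
    "preranked_gsea",
    "GseaResult",
    "methylation_retention",
    "RetentionSummary",
]

EP_WINDOW_DEFAULT = 500_000


def pair_enhancer_promoter(
    de_ernas: pd.DataFrame,
    de_genes: pd.DataFrame,
    window: int = EP_WINDOW_DEFAULT,
    require_concordant: bool = False,
) -> pd.DataFrame:
    """All (enhancer, gene) pairs with |midpoint - TSS| <= window.

    ``de_ernas`` needs columns id, chrom, start, end, direction and
    ``de_genes`` columns id, chrom, tss, direction — both already filtered
    to significant features. Distance is signed (TSS minus enhancer
    midpoint); concordance means matching up/down direction. One enhancer
    may pair with several genes and vice versa.
    """
    rows = []
    for _, e in de_ernas.iterrows():
        mid = (int(e["start"]) + int(e["end"])) // 2
        near = de_genes[de_genes["chrom"] == e["chrom"]]
        for _, g in near.iterrows():
            dist = int(g["tss"]) - mid
            if abs(dist) > window:
                continue
            concordant = e["direction"] == g["direction"]
            if require_concordant and not concordant:
                continue
            rows.append((e["id"], g["id"], dist, concordant))
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "distance",
                                       "concordant"])


@dataclass
class OverlapTestResult:
    n_a: int
    n_b: int
    overlap: int
    universe: int
    p: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {"n_a": self.n_a, "n_b": self.n_b, "overlap": self.overlap,
                "universe": self.universe, "p": self.p}


def overlap_test(set_a, set_b, universe) -> OverlapTestResult:
    """Upper-tail hypergeometric test of the overlap of two id sets.

    P(X >= k) for X ~ Hypergeom(N, |A|, |B|); k = 0 gives P = 1. The
    universe must contain both sets (it is an explicit parameter: overlap
    significance is meaningless without stating the background).
    """
    uni = pd.Index(universe).unique()
    if len(uni) == 0:
        raise ConfigurationError("overlap_test universe must be non-empty")
    a = pd.Index(set_a).unique()
    b = pd.Index(set_b).unique()
    stray = a.difference(uni).union(b.difference(uni))
    if len(stray):
        raise ConfigurationError(
            f"set members outside universe: {list(stray[:5])}...")
    k = len(a.intersection(b))
    n = len(uni)
    p = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    degenerate = len(a) == n or len(b) == n or k == 0
    return OverlapTestResult(n_a=len(a), n_b=len(b), overlap=k, universe=n,
                             p=min(p, 1.0), degenerate=degenerate)


@dataclass
class GseaResult:
    gene_set: str
    es: float
    nes: float
    p: float
    n_perm: int
    seed: int
    n_hits: int


def _running_es(scores: np.ndarray, is_hit: np.ndarray, weight: float) -> float:
    """Signed enrichment score of one ranking (scores sorted descending)."""
    w = np.abs(scores) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = len(scores) - int(is_hit.sum())
    if total_hit == 0 or n_miss == 0:
        raise ConfigurationError("gene set covers none or all of the ranking")
    steps = hit_w / total_hit - np.where(is_hit, 0.0, 1.0 / n_miss)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranking: pd.Series,
    gene_set,
    set_name: str = "set",
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Weighted-KS enrichment score of ``gene_set`` in a preranked list.

    ``ranking`` maps unique gene ids to scores (any order; sorted descending
    internally). Hits step the running sum up proportionally to
    |score|^weight, misses step down by 1/(N - n_set); ES is the extreme of
    the running sum. Significance comes from gene-label permutations (random
    same-size sets): NES = ES / mean|same-sign permuted ES| and
    p = (1 + #{same-sign |ES_perm| >= |ES|}) / (1 + #same-sign), with +1
    smoothing so p is never zero.
    """
    if ranking.index.has_duplicates:
        raise ConfigurationError("ranking gene ids must be unique")
    members = pd.Index(gene_set).unique()
    hits = ranking.index.isin(members)
    if not hits.any():
        raise ConfigurationError("gene set is disjoint from the ranking")
    order = np.argsort(-ranking.to_numpy(), kind="mergesort")
    scores = ranking.to_numpy()[order]
    is_hit = hits[order]
    es = _running_es(scores, is_hit, weight)

    rng = np.random.Generator(np.random.PCG64(seed))
    n_set = int(is_hit.sum())
    perm_es = np.empty(n_perm)
    n = len(scores)
    for i in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_set, replace=False)] = True
        perm_es[i] = _running_es(scores, mask, weight)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if len(same_sign):
        nes = es / np.mean(np.abs(same_sign))
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
    else:
        nes, p = np.sign(es) * np.inf, 1.0 / (1.0 + n_perm)
    return GseaResult(gene_set=set_name, es=es, nes=float(nes), p=float(p),
                      n_perm=n_perm, seed=seed, n_hits=n_set)


@dataclass
class RetentionSummary:
    probe_set: str
    n_probes: int
    mean_beta_baseline: float
    mean_beta_treated: float
    mean_delta: float
    retained_fraction: float
    per_probe: pd.DataFrame


def methylation_retention(
    baseline: BetaMatrix,
    treated: BetaMatrix,
    probe_set,
    set_name: str = "probes",
    retention_threshold: float = 0.05,
    baseline_condition: str | None = None,
    treated_conditions: list[str] | None = None,
) -> RetentionSummary:
    """Per-probe methylation change of a probe set after treatment.

    Computes group-mean delta-beta (treated minus baseline) per probe over
    the set; a probe is *retained* when |delta| < retention_threshold (the
    same 0.05 delta-beta convention used for differential calling). The two
    matrices may be the same object with different conditions selected.
    Missing probes raise with the offending ids listed.
    """
    probes = pd.Index(probe_set).unique()
    missing = probes.difference(baseline.probes).union(
        probes.difference(treated.probes))
    if len(missing):
        raise ConfigurationError(
            f"probes absent from matrices: {list(missing[:10])}")
    base_vals = baseline.values
    if baseline_condition is not None:
        base_vals = base_vals[baseline.design.samples_for(baseline_condition)]
    treat_vals = treated.values
    if treated_conditions is not None:
        cols = [s for c in treated_conditions
                for s in treated.design.samples_for(c)]
        treat_vals = treat_vals[cols]
    b = base_vals.loc[probes].mean(axis=1)
    t = treat_vals.loc[probes].mean(axis=1)
    delta = t - b
    retained = (delta.abs() < retention_threshold)
    per_probe = pd.DataFrame({"beta_baseline": b, "beta_treated": t,
                              "delta": delta, "retained": retained})
    return RetentionSummary(
        probe_set=set_name, n_probes=len(probes),
        mean_beta_baseline=float(b.mean()), mean_beta_treated=float(t.mean()),
        mean_delta=float(delta.mean()),
        retained_fraction=float(retained.mean()), per_probe=per_probe)
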