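"""Probe genomic-context annotation and Fisher-exact set enrichment.

Probes are assigned exactly one feature class (priority promoter > enhancer
> gene_body > intergenic) and one CpG-context class by distance ``d`` to the
nearest CpG island: island (d = 0), shore (0 < d <= 2000), shelf
(2000 < d <= 4000), open sea (d > 4000); boundary distances fall in the
nearer-island class (inclusive upper bounds).

Enrichment of a selected id set against a universe is a one-sided Fisher
exact test in both directions per class — equivalently the hypergeometric
tail probabilities of the 2x2 table — BH-adjusted across classes within
each direction. The same exact test backs the motif module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeAnnotation, PipelineError
from .diffexpr import bh_adjust

__all__ = [
    "FEATURE_PRIORITY",
    "annotate_probes",
    "fisher_enrichment",
    "hypergeom_tails",
]

FEATURE_PRIORITY = ("promoter", "enhancer", "gene_body", "intergenic")
SHORE_MAX = 2_000
SHELF_MAX = 4_000


class AnnotationError(PipelineError):
    """Raised for probes on chromosomes absent from the annotation."""


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s), np.asarray(out_e)


def _inside(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of positions in merged, sorted half-open intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < ends[idx[ok]]
    return res


def _island_distance(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """bp distance to the nearest island; 0 iff inside an island.

    For a probe left of an island at start s the distance is s - pos; right
    of an island ending at e (half-open) it is pos - (e - 1).
    """
    if len(starts) == 0:
        return np.full(len(pos), np.inf)
    idx = np.searchsorted(starts, pos, side="right") - 1
    dist = np.full(len(pos), np.inf)
    has_prev = idx >= 0
    inside = np.zeros(len(pos), dtype=bool)
    inside[has_prev] = pos[has_prev] < ends[idx[has_prev]]
    dist[inside] = 0
    left = has_prev & ~inside
    dist[left] = pos[left] - (ends[idx[left]] - 1)
    has_next = idx + 1 < len(starts)
    nxt = np.where(has_next, starts[np.minimum(idx + 1, len(starts) - 1)] - pos, np.inf)
    return np.minimum(dist, np.where(~inside, nxt, 0))


def annotate_probes(probes: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Assign feature and CpG-context classes to probes.

    ``probes`` needs columns id, chrom, pos. Returns a frame with
    feature_class, cpg_class and distance_to_island per probe. Probes on
    chromosomes missing from the annotation raise :class:`AnnotationError`.
    """
    known = set(annotation.chromosomes["chrom"])
    unknown = sorted(set(probes["chrom"]) - known)
    if unknown:
        raise AnnotationError(f"probes on unknown chromosomes: {unknown}")

    feature = np.full(len(probes), "intergenic", dtype=object)
    cpg = np.full(len(probes), "open_sea", dtype=object)
    dist_all = np.full(len(probes), np.inf)

    class_intervals = {
        "promoter": annotation.promoters,
        "enhancer": annotation.enhancers,
        "gene_body": annotation.genes,
    }
    for chrom, idx in probes.groupby("chrom", sort=False).groups.items():
        pos = probes.loc[idx, "pos"].to_numpy()
        unassigned = np.ones(len(pos), dtype=bool)
        for cls in FEATURE_PRIORITY[:3]:
            df = class_intervals[cls]
            sub = df[df["chrom"] == chrom]
            s, e = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            hit = _inside(pos, s, e) & unassigned
            feature[np.asarray(idx)[hit]] = cls
            unassigned &= ~hit
        isl = annotation.cpg_islands
        sub = isl[isl["chrom"] == chrom]
        s, e = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        d = _island_distance(pos, s, e)
        dist_all[np.asarray(idx)] = d
        cls = np.where(d == 0, "island",
                       np.where(d <= SHORE_MAX, "shore",
                                np.where(d <= SHELF_MAX, "shelf", "open_sea")))
        cpg[np.asarray(idx)] = cls

    return pd.DataFrame({
        "id": probes["id"].to_numpy(),
        "chrom": probes["chrom"].to_numpy(),
        "pos": probes["pos"].to_numpy(),
        "feature_class": feature,
        "cpg_class": cpg,
        "distance_to_island": dist_all,
    })


def hypergeom_tails(k: int, n_class: int, n_selected: int, n_universe: int
                    ) -> tuple[float, float]:
    """Exact one-sided tail probabilities for a 2x2 table with fixed margins.

    Returns (P[X >= k], P[X <= k]) for X ~ Hypergeom(N=n_universe,
    K=n_class, n=n_selected). Shared by probe-context, gene-set and motif
    enrichment.
    """
    p_greater = float(stats.hypergeom.sf(k - 1, n_universe, n_class, n_selected))
    p_less = float(stats.hypergeom.cdf(k, n_universe, n_class, n_selected))
    return min(p_greater, 1.0), min(p_less, 1.0)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    flagged_empty: bool = False


def fisher_enrichment(
    selected: set[str] | list[str] | pd.Index,
    universe: set[str] | list[str] | pd.Index,
    classifier: pd.Series | dict,
) -> EnrichmentResult:
    """Per-class Fisher exact enrichment of ``selected`` within ``universe``.

    ``classifier`` maps every universe id to a class label (probes to
    feature/CpG classes, or genes to gene-set membership). Reports the 2x2
    counts, sample odds ratio, one-sided p in both directions, and BH
    adjustment across classes within each direction. An empty selection is
    flagged and yields p = 1 everywhere.
    """
    universe = pd.Index(universe).unique()
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    selected = pd.Index(selected).unique()
    stray = selected.difference(universe)
    if len(stray):
        raise ValueError(f"selected ids outside universe: {list(stray[:5])}...")
    labels = pd.Series(classifier).reindex(universe)
    if labels.isna().any():
        missing = list(universe[labels.isna()][:5])
        raise ValueError(f"classifier missing labels for universe ids: {missing}...")

    n_uni = len(universe)
    n_sel = len(selected)
    sel_labels = labels.loc[selected]
    rows = []
    for cls in sorted(labels.unique()):
        n_class = int((labels == cls).sum())
        k = int((sel_labels == cls).sum())
        a, b = k, n_sel - k
        c, d = n_class - k, n_uni - n_class - (n_sel - k)
        if n_sel == 0:
            p_g, p_l = 1.0, 1.0
        else:
            p_g, p_l = hypergeom_tails(k, n_class, n_sel, n_uni)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append((cls, a, b, c, d, odds, p_g, p_l))
    out = pd.DataFrame(rows, columns=[
        "class", "selected_in", "selected_out", "unselected_in",
        "unselected_out", "odds_ratio", "p_greater", "p_less"]).set_index("class")
    out["p_adj_greater"] = bh_adjust(out["p_greater"].to_numpy())
    out["p_adj_less"] = bh_adjust(out["p_less"].to_numpy())
    return EnrichmentResult(table=out, flagged_empty=(n_sel == 0))
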