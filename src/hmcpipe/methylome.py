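"""5mC/5hmC estimation from paired BS/oxBS betas and delta-beta calling.

Bisulfite conversion reads 5mC + 5hmC; oxidative bisulfite reads 5mC only.
Their per-probe difference therefore estimates 5hmC:

    h_raw = beta_BS - beta_oxBS        (may be negative under noise)
    m_hat = beta_oxBS
    h_hat = max(h_raw, 0), jointly rescaled with m_hat if m + h > 1

Delta-beta and correlation analyses use the *unclipped* ``h_raw`` to avoid
censoring bias; the clipped ``h_hat`` is reported as the state estimate only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignmentError, BetaMatrix, ContrastError, ConfigurationError, SampleSheet
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "MethylomeEstimate",
    "DeltaBetaTable",
    "ZScoreMatrix",
    "estimate_5hmc",
    "delta_beta",
    "call_differential",
    "correlate_changes",
    "standardize_profiles",
]


@dataclass
class MethylomeEstimate:
    """Per probe/sample 5mC and 5hmC estimates from a paired BS/oxBS design."""

    m: pd.DataFrame
    h_raw: pd.DataFrame
    h: pd.DataFrame
    design: SampleSheet
    n_rescaled: int = 0

    def mark_values(self, mark: str) -> pd.DataFrame:
        """Values used for contrasts: raw (unclipped) h, plain m."""
        if mark == "h":
            return self.h_raw
        if mark == "m":
            return self.m
        raise KeyError(f"unknown mark {mark!r} (expected 'm' or 'h')")


@dataclass
class DeltaBetaTable:
    """Per-probe group means and delta-beta for one contrast.

    ``table`` columns per mark X: mean_<g1>_X, mean_<g2>_X, delta_X, and
    optionally p_X / p_adj_X / call_X. The contrast is (group1, group2) with
    delta = mean(group2) - mean(group1).
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    marks: tuple[str, ...]
    tested: bool = False

    def calls(self, mark: str) -> pd.Series:
        col = f"call_{mark}"
        if col not in self.table:
            raise ConfigurationError("call_differential has not been run")
        return self.table[col]

    def write(self, path: str | Path, probe_positions: pd.DataFrame | None = None) -> None:
        out = self.table
        if probe_positions is not None:
            pos = probe_positions.set_index("id")[["chrom", "pos"]]
            out = pos.join(out, how="right")
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(path, sep="\t")


@dataclass
class ZScoreMatrix:
    """Row-standardized profiles; constant rows are zeroed and flagged."""

    values: pd.DataFrame
    constant_rows: pd.Index = field(default_factory=lambda: pd.Index([]))


def estimate_5hmc(bs: BetaMatrix, oxbs: BetaMatrix) -> MethylomeEstimate:
    """Estimate per-probe/sample 5mC and 5hmC from paired BS and oxBS betas.

    Raises :class:`AlignmentError` when the two matrices disagree on probes
    or sample design. Missing values in either assay propagate to the
    estimate. Where the clipped estimates violate m + h <= 1 they are
    jointly rescaled by 1/(m + h); the number of rescaled entries is kept.
    """
    if bs.assay == oxbs.assay:
        raise AlignmentError(f"need one BS and one oxBS matrix, got two {bs.assay!r}")
    only_bs = bs.probes.difference(oxbs.probes)
    only_ox = oxbs.probes.difference(bs.probes)
    if len(only_bs) or len(only_ox):
        raise AlignmentError(
            "probe sets differ between assays; "
            f"BS-only {list(only_bs[:5])}..., oxBS-only {list(only_ox[:5])}..."
        )
    if not bs.design.table[["condition", "replicate"]].equals(
            oxbs.design.table[["condition", "replicate"]]):
        raise AlignmentError("sample designs differ between BS and oxBS matrices")
    ox = oxbs.values.reindex(bs.probes)
    h_raw = bs.values - ox
    m = ox.copy()
    h = h_raw.clip(lower=0.0)
    total = m + h
    over = total > 1.0
    n_rescaled = int(over.to_numpy().sum())
    if n_rescaled:
        scale = 1.0 / total.where(over, 1.0)
        m = m * scale
        h = h * scale
        logger.info("rescaled %d probe/sample estimates with m + h > 1", n_rescaled)
    return MethylomeEstimate(m=m, h_raw=h_raw, h=h, design=bs.design,
                             n_rescaled=n_rescaled)


def _group_frames(values: pd.DataFrame, design: SampleSheet,
                  contrast: tuple[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    g1, g2 = contrast
    return (values[design.samples_for(g1)], values[design.samples_for(g2)])


def delta_beta(
    est: MethylomeEstimate | BetaMatrix,
    contrast: tuple[str, str],
    test: str = "none",
) -> DeltaBetaTable:
    """Per-probe group means and delta-beta for ``contrast`` = (g1, g2).

    delta = mean(g2) - mean(g1) per probe and mark. ``test='welch_t'``
    attaches a per-probe two-sided Welch t p-value plus BH adjustment
    (requires >= 2 replicates per group). Probes with no observed value in a
    group get NaN deltas for that contrast.
    """
    if test not in ("none", "welch_t"):
        raise ConfigurationError(f"unknown test {test!r}")
    if isinstance(est, BetaMatrix):
        marks: tuple[str, ...] = ("beta",)
        frames = {"beta": est.values}
        design = est.design
    else:
        marks = ("m", "h")
        frames = {mark: est.mark_values(mark) for mark in marks}
        design = est.design

    cols: dict[str, pd.Series | np.ndarray] = {}
    g1, g2 = contrast
    for mark in marks:
        a, b = _group_frames(frames[mark], design, contrast)
        if test == "welch_t" and (a.shape[1] < 2 or b.shape[1] < 2):
            raise ConfigurationError("welch_t requires >= 2 replicates per group")
        mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
        cols[f"mean_{g1}_{mark}"] = mean1
        cols[f"mean_{g2}_{mark}"] = mean2
        cols[f"delta_{mark}"] = mean2 - mean1
        if test == "welch_t":
            res = stats.ttest_ind(b.to_numpy(), a.to_numpy(), axis=1,
                                  equal_var=False, nan_policy="omit")
            p = np.asarray(res.pvalue, dtype=float)
            cols[f"p_{mark}"] = p
            cols[f"p_adj_{mark}"] = bh_adjust(p)
    table = pd.DataFrame(cols, index=frames[marks[0]].index)
    return DeltaBetaTable(table=table, contrast=contrast, marks=marks,
                          tested=(test == "welch_t"))


def call_differential(
    table: DeltaBetaTable,
    effect_threshold: float = 0.05,
    alpha: float | None = None,
) -> DeltaBetaTable:
    """Call hyper/hypo per mark with a strict |delta| > threshold rule.

    ``hyper`` iff delta > threshold, ``hypo`` iff delta < -threshold
    (delta equal to the threshold is *not* called), additionally requiring
    p_adj < alpha when ``alpha`` is given. Threshold-only mode supports
    duplicate designs without a usable per-probe test.
    """
    if effect_threshold < 0:
        raise ConfigurationError("effect_threshold must be >= 0")
    if alpha is not None and not table.tested:
        raise ConfigurationError("alpha given but no test was run on this table")
    out = table.table.copy()
    for mark in table.marks:
        delta = out[f"delta_{mark}"]
        call = np.where(delta > effect_threshold, "hyper",
                        np.where(delta < -effect_threshold, "hypo", "none"))
        if alpha is not None:
            sig = out[f"p_adj_{mark}"] < alpha
            call = np.where(sig.fillna(False), call, "none")
        call = np.where(delta.isna(), "none", call)
        out[f"call_{mark}"] = call
    return DeltaBetaTable(table=out, contrast=table.contrast,
                          marks=table.marks, tested=table.tested)


def correlate_changes(
    table_x: DeltaBetaTable,
    table_y: DeltaBetaTable,
    selection: pd.Index | list[str],
    mark_x: str = "h",
    mark_y: str = "m",
) -> dict:
    """Pearson correlation between two delta-beta columns over ``selection``.

    Typically correlates delta 5hmC against delta 5mC over differential
    probes (both tables may be the same object). Returns ``{"r", "p", "n"}``.
    """
    sel = pd.Index(selection)
    if len(sel) < 3:
        raise ConfigurationError("selection must contain >= 3 probes")
    missing = sel.difference(table_x.table.index).union(
        sel.difference(table_y.table.index))
    if len(missing):
        raise ConfigurationError(f"selection probes absent from tables: "
                                 f"{list(missing[:5])}...")
    x = table_x.table.loc[sel, f"delta_{mark_x}"].to_numpy(dtype=float)
    y = table_y.table.loc[sel, f"delta_{mark_y}"].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ConfigurationError("fewer than 3 complete pairs in selection")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigurationError("zero variance in one coordinate; "
                                 "correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}


def standardize_profiles(values: pd.DataFrame) -> ZScoreMatrix:
    """Row-wise z-scores (sample s.d., ddof=1); constant rows become zeros.

    Used for condition-profile heatmaps of delta-beta values. Requires at
    least two columns.
    """
    if values.shape[1] < 2:
        raise ConfigurationError("standardize_profiles needs >= 2 conditions")
    arr = values.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, keepdims=True, ddof=1)
    constant = (sd == 0) | np.isnan(sd)
    safe_sd = np.where(constant, 1.0, sd)
    z = (arr - mean) / safe_sd
    z[constant[:, 0], :] = 0.0
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns)
    return ZScoreMatrix(values=zdf, constant_rows=values.index[constant[:, 0]])
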