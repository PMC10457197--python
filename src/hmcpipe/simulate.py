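"""Synthetic genomes, paired BS/oxBS methylomes, and nascent transcription.

The generator plants the effect structure this pipeline is built to detect:

* a hypermethylation-skewed 5mC landscape (hyper >> hypo, ~2.2:1) together
  with 5hmC loss outnumbering gain 3:1 (2156 loss vs 664 gain sites by
  default), anti-correlated by construction (5hmC lost as 5mC gained);
* partial reversal of all planted methylation effects after simulated
  inhibitor treatment (two timepoints), except for an "HLA-like" contiguous
  gene cluster that stays hypermethylated and transcriptionally repressed —
  the non-responder retention phenotype;
* strand-specific nascent-transcription coverage with bidirectionally
  transcribed enhancers (eRNAs), negative-binomial counts carrying planted
  log2 fold changes, and concordant enhancer-promoter pairs within 500 kb.

Every planted choice is recorded in :class:`TruthTables` so downstream
estimates can be scored against ground truth.

Randomness: a single seed expands into named substreams via
``numpy.random.SeedSequence.spawn``. The spawn order is fixed and documented
per operation, so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BetaMatrix,
    ConfigurationError,
    CountMatrix,
    CoverageTracks,
    GenomeAnnotation,
    PlacementError,
    SampleSheet,
)

logger = logging.getLogger(__name__)

CONDITIONS = ("WT", "MUT", "MUT_T4", "MUT_T7")

__all__ = [
    "GenomeSpec",
    "EffectConfig",
    "HlaLikeEffect",
    "TruthTables",
    "build_genome",
    "simulate_methylome",
    "simulate_transcription",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of the synthetic genome (desk-scale array/genome stand-in)."""

    n_chroms: int = 4
    chrom_length: int = 6_000_000
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    n_enhancers: int = 300
    enhancer_length_range: tuple[int, int] = (600, 1_500)
    n_cpg_islands: int = 350
    island_length_range: tuple[int, int] = (500, 2_000)
    probes_per_island_region: int = 12
    probes_per_promoter: int = 2
    probes_per_gene_body: int = 2
    probes_per_enhancer: int = 4
    intergenic_probe_count: int = 10_000
    min_feature_gap: int = 2_000
    promoter_upstream: int = 1_000
    promoter_downstream: int = 500
    hla_cluster_size: int = 12
    hla_probe_count: int = 116
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_chroms": self.n_chroms,
            "chrom_length": self.chrom_length,
            "n_genes": self.n_genes,
            "n_enhancers": self.n_enhancers,
            "n_cpg_islands": self.n_cpg_islands,
            "probes_per_island_region": self.probes_per_island_region,
            "intergenic_probe_count": self.intergenic_probe_count,
            "hla_cluster_size": self.hla_cluster_size,
        }
        bad = [k for k, v in counts.items() if v <= 0]
        if bad:
            raise ConfigurationError(f"GenomeSpec counts must be > 0: {bad}")
        if self.min_feature_gap < 0:
            raise ConfigurationError("min_feature_gap must be >= 0")
        for name, (lo, hi) in (
            ("gene_length_range", self.gene_length_range),
            ("enhancer_length_range", self.enhancer_length_range),
            ("island_length_range", self.island_length_range),
        ):
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < lo <= hi")
            if hi > self.chrom_length:
                raise ConfigurationError(f"{name} exceeds chromosome length")
        if self.hla_cluster_size > self.n_genes:
            raise ConfigurationError("hla_cluster_size exceeds n_genes")


@dataclass(frozen=True)
class HlaLikeEffect:
    """Planted non-responder cluster: repressed and hypermethylated, never
    reversed by treatment."""

    log2fc: float = -1.5
    delta_beta: float = 0.2


@dataclass(frozen=True)
class EffectConfig:
    """Planted condition effects.

    5hmC loss/gain default to 2156/664 sites (3:1 loss skew) and 5mC
    hyper/hypo to 3000/1400 (~2.2:1 hyper skew, scaled to probe count).
    ``delta_effect`` is the central |delta beta| of a planted change; each
    planted probe draws its own effect from U(0.5, 1.5) x delta_effect so the
    planted sites carry a realistic spread of magnitudes.

    ``beta_noise_sd`` is the marginal s.d. of an observed beta around truth.
    A fraction ``beta_noise_shared_frac`` of that variance is shared between
    the BS and oxBS measurement of the same biological replicate (same DNA
    aliquot and array position); only the assay-specific remainder survives
    in the BS - oxBS difference, which is what makes paired designs usable
    for 5hmC at all.
    """

    conditions: tuple[str, ...] = CONDITIONS
    replicates_per_condition: int = 2
    n_hyper_5mc: int = 3000
    n_hypo_5mc: int = 1400
    n_loss_5hmc: int = 2156
    n_gain_5hmc: int = 664
    delta_effect: float = 0.2
    reversal_fraction_t4: float = 0.8
    reversal_fraction_t7: float = 0.9
    n_genes_down: int = 60
    n_genes_up: int = 45
    n_genes_rescued: int = 10
    n_ernas_transcribed: int = 200
    n_ernas_up: int = 30
    n_ernas_down: int = 18
    n_ep_pairs: int = 8
    ep_window: int = 500_000
    hla_like_cluster: HlaLikeEffect = field(default_factory=HlaLikeEffect)
    beta_noise_sd: float = 0.03
    beta_noise_shared_frac: float = 0.85
    nb_dispersion: float = 0.05
    mean_count_range: tuple[float, float] = (50.0, 2000.0)
    erna_mean_range: tuple[float, float] = (40.0, 200.0)
    erna_length_range: tuple[int, int] = (300, 800)
    bg_noise_rate: float = 0.002
    bin_size: int = 10
    sampling_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if list(self.conditions) != list(CONDITIONS):
            raise ConfigurationError(
                f"conditions must be {CONDITIONS} in order, got {self.conditions}"
            )
        if self.replicates_per_condition < 1:
            raise ConfigurationError("replicates_per_condition must be >= 1")
        for name in ("reversal_fraction_t4", "reversal_fraction_t7",
                     "beta_noise_shared_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.delta_effect <= 1.0:
            raise ConfigurationError("delta_effect must be in [0, 1]")
        if self.beta_noise_sd < 0 or self.nb_dispersion < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.n_ep_pairs > min(self.n_ernas_up + self.n_ernas_down,
                                 self.n_genes_up + self.n_genes_down):
            raise ConfigurationError("n_ep_pairs exceeds available DE features")


@dataclass
class TruthTables:
    """Ground truth of one simulation; treat as immutable once generated."""

    # methylome truth
    probe_truth: pd.DataFrame | None = None   # index probe; m_<cond>, h_<cond>
    probe_effects: pd.DataFrame | None = None  # index probe; delta_m, delta_h (MUT-WT)
    # transcription truth
    gene_truth: pd.DataFrame | None = None    # id, base_mean, lfc_mut, rescued
    erna_truth: pd.DataFrame | None = None    # enhancer_id, spans, lfc_mut
    ep_pairs: pd.DataFrame | None = None      # enhancer_id, gene_id, distance, direction
    erna_counts: pd.DataFrame | None = None   # truth-level eRNA counts (both strands)
    sets: dict[str, list[str]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("probe_truth", "probe_effects", "gene_truth",
                     "erna_truth", "ep_pairs", "erna_counts"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"{name}.tsv", sep="\t")
        rows = [(n, m) for n, ids in sorted(self.sets.items()) for m in ids]
        pd.DataFrame(rows, columns=["set", "id"]).to_csv(
            outdir / "truth_sets.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

class _IntervalBook:
    """Sorted non-overlapping interval registry for rejection placement."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def clashes(self, start: int, end: int, margin: int) -> bool:
        i = bisect_left(self.starts, end + margin)
        if i > 0 and self.ends[i - 1] + margin > start:
            return True
        if i < len(self.starts) and self.starts[i] < end + margin:
            return True
        return False

    def add(self, start: int, end: int) -> None:
        i = bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _place_intervals(rng: np.random.Generator, n: int, chrom_len: int,
                     length_range: tuple[int, int], margin: int,
                     avoid: list[_IntervalBook], label: str,
                     max_tries: int = 400) -> list[tuple[int, int]]:
    """Place ``n`` intervals avoiding every book in ``avoid`` by ``margin``."""
    own = avoid[0]
    placed: list[tuple[int, int]] = []
    for _ in range(n):
        for _try in range(max_tries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            if length >= chrom_len:
                continue
            start = int(rng.integers(0, chrom_len - length))
            end = start + length
            if any(book.clashes(start, end, margin) for book in avoid):
                continue
            own.add(start, end)
            placed.append((start, end))
            break
        else:
            raise PlacementError(
                f"could not place {label} after {max_tries} tries "
                f"({len(placed)}/{n} placed on a {chrom_len} bp chromosome; "
                f"reduce counts or min_feature_gap)"
            )
    return placed


def _split_counts(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def build_genome(spec: GenomeSpec) -> GenomeAnnotation:
    """Build a deterministic synthetic genome annotation.

    Gene bodies never overlap and keep ``min_feature_gap`` clearance;
    enhancers keep that clearance from genes and each other; CpG islands are
    placed independently (they only avoid each other). Probes are laid down
    inside islands, at graded shore/shelf/open-sea distances, in promoters,
    gene bodies, enhancers and intergenic space, plus a dense block over a
    contiguous "HLA_like" gene cluster.

    Substream order (``SeedSequence(spec.seed).spawn``):
    genes, enhancers, islands, probes.
    """
    spec.validate()
    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(spec.seed).spawn(4)]
    rng_gene, rng_enh, rng_isl, rng_probe = rngs

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_df = pd.DataFrame({"chrom": chroms, "length": spec.chrom_length})

    genes_rows, enh_rows, isl_rows = [], [], []
    per_chrom_genes = _split_counts(spec.n_genes, spec.n_chroms)
    per_chrom_enh = _split_counts(spec.n_enhancers, spec.n_chroms)
    per_chrom_isl = _split_counts(spec.n_cpg_islands, spec.n_chroms)

    for ci, chrom in enumerate(chroms):
        gene_book = _IntervalBook()
        gene_iv = _place_intervals(
            rng_gene, per_chrom_genes[ci], spec.chrom_length,
            spec.gene_length_range, spec.min_feature_gap, [gene_book], "genes")
        strands = rng_gene.choice(["+", "-"], size=len(gene_iv))
        for (s, e), st in zip(sorted(gene_iv), strands):
            genes_rows.append((chrom, s, e, st))

        enh_book = _IntervalBook()
        enh_iv = _place_intervals(
            rng_enh, per_chrom_enh[ci], spec.chrom_length,
            spec.enhancer_length_range, spec.min_feature_gap,
            [enh_book, gene_book], "enhancers")
        for s, e in sorted(enh_iv):
            enh_rows.append((chrom, s, e))

        isl_book = _IntervalBook()
        isl_iv = _place_intervals(
            rng_isl, per_chrom_isl[ci], spec.chrom_length,
            spec.island_length_range, 0, [isl_book], "cpg_islands")
        for s, e in sorted(isl_iv):
            isl_rows.append((chrom, s, e))

    genes = pd.DataFrame(genes_rows, columns=["chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    genes.insert(0, "id", [f"g{i:04d}" for i in range(len(genes))])
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end"])
    enhancers = enhancers.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    enhancers.insert(0, "id", [f"e{i:04d}" for i in range(len(enhancers))])
    islands = pd.DataFrame(isl_rows, columns=["chrom", "start", "end"])
    islands = islands.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    islands.insert(0, "id", [f"cgi{i:04d}" for i in range(len(islands))])

    # promoters: strand-aware TSS -upstream / +downstream, half-open, clipped
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    p_start = np.where(genes["strand"] == "+",
                       tss - spec.promoter_upstream, tss - spec.promoter_downstream + 1)
    p_end = np.where(genes["strand"] == "+",
                     tss + spec.promoter_downstream, tss + spec.promoter_upstream + 1)
    promoters = pd.DataFrame({
        "gene_id": genes["id"],
        "chrom": genes["chrom"],
        "start": np.clip(p_start, 0, spec.chrom_length),
        "end": np.clip(p_end, 0, spec.chrom_length),
        "strand": genes["strand"],
    })

    # HLA-like cluster: contiguous run of genes in the middle of chr1
    chr1_genes = genes[genes["chrom"] == chroms[0]].reset_index(drop=True)
    if len(chr1_genes) < spec.hla_cluster_size:
        raise PlacementError("not enough chr1 genes for the HLA-like cluster")
    first = (len(chr1_genes) - spec.hla_cluster_size) // 2
    cluster = chr1_genes.iloc[first:first + spec.hla_cluster_size]
    gene_sets = {"HLA_like": list(cluster["id"])}

    probes = _place_probes(spec, rng_probe, chroms, genes, promoters,
                           enhancers, islands, cluster)
    probe_sets = {"HLA_like": list(probes.loc[probes["tag"] == "hla", "id"])}
    probes = probes.drop(columns="tag")

    return GenomeAnnotation(
        chromosomes=chrom_df, genes=genes, promoters=promoters,
        enhancers=enhancers, cpg_islands=islands, probes=probes,
        gene_sets=gene_sets, probe_sets=probe_sets,
    )


def _place_probes(spec, rng, chroms, genes, promoters, enhancers, islands,
                  cluster) -> pd.DataFrame:
    rows: list[tuple[str, int, str]] = []

    def uniform_in(df: pd.DataFrame, per: int, tag: str) -> None:
        for _, r in df.iterrows():
            if r["end"] - r["start"] < 1:
                continue
            pos = rng.integers(r["start"], r["end"], size=per)
            rows.extend((r["chrom"], int(p), tag) for p in pos)

    # island-anchored probes at graded distances; split of the per-island
    # budget: 1/3 inside, then shore/shelf/open-sea bands
    n_in = max(1, spec.probes_per_island_region // 3)
    n_shore = max(1, (spec.probes_per_island_region - n_in) // 3)
    n_shelf = max(1, (spec.probes_per_island_region - n_in - n_shore) // 2)
    n_sea = max(0, spec.probes_per_island_region - n_in - n_shore - n_shelf)
    for _, r in islands.iterrows():
        chrom, s, e = r["chrom"], int(r["start"]), int(r["end"])
        pos = list(rng.integers(s, e, size=n_in))
        for n_band, lo, hi in ((n_shore, 1, 2000), (n_shelf, 2001, 4000),
                               (n_sea, 4001, 12000)):
            for j in range(n_band):
                d = int(rng.integers(lo, hi + 1))
                side = 1 if (j + int(rng.integers(0, 2))) % 2 == 0 else -1
                p = e - 1 + d if side > 0 else s - d
                pos.append(p)
        rows.extend((chrom, int(np.clip(p, 0, spec.chrom_length - 1)), "island_region")
                    for p in pos)

    uniform_in(promoters, spec.probes_per_promoter, "promoter")
    uniform_in(genes, spec.probes_per_gene_body, "gene_body")
    uniform_in(enhancers, spec.probes_per_enhancer, "enhancer")

    for chrom, n in zip(chroms, _split_counts(spec.intergenic_probe_count,
                                              len(chroms))):
        pos = rng.integers(0, spec.chrom_length, size=n)
        rows.extend((chrom, int(p), "intergenic") for p in pos)

    # dense probe block over the HLA-like cluster (promoters + bodies)
    spans = []
    for _, g in cluster.iterrows():
        pstart = g["start"] - spec.promoter_upstream if g["strand"] == "+" else g["start"]
        pend = g["end"] if g["strand"] == "+" else g["end"] + spec.promoter_upstream
        spans.append((g["chrom"], max(0, int(pstart)), min(spec.chrom_length, int(pend))))
    for i in range(spec.hla_probe_count):
        chrom, s, e = spans[i % len(spans)]
        rows.append((chrom, int(rng.integers(s, e)), "hla"))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "tag"])
    # resolve position collisions deterministically by nudging +1
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    for chrom, idx in df.groupby("chrom", sort=False).groups.items():
        pos = df.loc[idx, "pos"].to_numpy().copy()
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        df.loc[idx, "pos"] = np.minimum(pos, spec.chrom_length - 1)
    df = df.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "id", [f"cg{i:06d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def _sample_sheet(eff: EffectConfig) -> SampleSheet:
    rows = [(f"{c}_r{r + 1}", c, r + 1)
            for c in eff.conditions
            for r in range(eff.replicates_per_condition)]
    df = pd.DataFrame(rows, columns=["sample", "condition", "replicate"])
    return SampleSheet(df.set_index("sample"))


def simulate_methylome(
    annotation: GenomeAnnotation, effects: EffectConfig
) -> tuple[BetaMatrix, BetaMatrix, TruthTables]:
    """Simulate paired BS/oxBS beta matrices with planted 5mC/5hmC effects.

    Per probe and condition the truth is a pair (m, h) with m, h >= 0 and
    m + h <= 1; the true BS signal is m + h and the true oxBS signal is m.
    Planted 5hmC-loss sites trade h for m (and vice versa for gain), so the
    construction is anti-correlated by design. Treatment conditions move
    every planted effect back toward WT by the configured reversal fraction
    — except HLA-like cluster probes, which retain their hypermethylation.

    Substream order (``SeedSequence(effects.seed).spawn``):
    baseline, assignment, effect sizes, observation noise.
    """
    effects.validate()
    probes = annotation.probes.reset_index(drop=True)
    n = len(probes)
    total_planted = (effects.n_loss_5hmc + effects.n_gain_5hmc
                     + effects.n_hyper_5mc + effects.n_hypo_5mc)
    hla_ids = set(annotation.probe_sets.get("HLA_like", []))
    if total_planted + len(hla_ids) > n:
        raise ConfigurationError(
            f"planted effect counts ({total_planted} + {len(hla_ids)} cluster) "
            f"exceed available probes ({n})"
        )
    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(effects.seed).spawn(4)]
    rng_base, rng_assign, rng_eff, rng_noise = rngs

    # --- baseline truth -----------------------------------------------------
    bimodal = rng_base.random(n) < 0.45
    m0 = np.where(bimodal, rng_base.beta(5.0, 1.5, size=n),
                  rng_base.beta(0.6, 3.0, size=n))
    h0 = rng_base.beta(2.0, 28.0, size=n)
    m0 = np.minimum(m0, 1.0 - h0)

    # --- planted set assignment --------------------------------------------
    from .enrichment import annotate_probes  # local import avoids cycle at import time

    ctx = annotate_probes(probes, annotation)
    feat_w = {"enhancer": 3.0, "gene_body": 1.5, "promoter": 0.25, "intergenic": 1.0}
    cpg_w = {"open_sea": 2.0, "shelf": 1.0, "shore": 0.5, "island": 0.3}
    weights = (ctx["feature_class"].map(feat_w).to_numpy()
               * ctx["cpg_class"].map(cpg_w).to_numpy())
    is_hla = probes["id"].isin(hla_ids).to_numpy()
    weights[is_hla] = 0.0
    p = weights / weights.sum()
    n_hmc = effects.n_loss_5hmc + effects.n_gain_5hmc
    hmc_idx = rng_assign.choice(n, size=n_hmc, replace=False, p=p)
    loss_idx = hmc_idx[: effects.n_loss_5hmc]
    gain_idx = hmc_idx[effects.n_loss_5hmc:]

    taken = np.zeros(n, dtype=bool)
    taken[hmc_idx] = True
    taken[is_hla] = True
    free = np.flatnonzero(~taken)
    mc_idx = rng_assign.choice(free, size=effects.n_hyper_5mc + effects.n_hypo_5mc,
                               replace=False)
    hyper_idx = mc_idx[: effects.n_hyper_5mc]
    hypo_idx = mc_idx[effects.n_hyper_5mc:]
    hla_idx = np.flatnonzero(is_hla)

    # --- per-probe effect sizes and feasible baselines ----------------------
    def sized(k: int) -> np.ndarray:
        return effects.delta_effect * rng_eff.uniform(0.5, 1.5, size=k)

    d_loss, d_gain = sized(len(loss_idx)), sized(len(gain_idx))
    d_hyper, d_hypo = sized(len(hyper_idx)), sized(len(hypo_idx))
    d_hla = effects.hla_like_cluster.delta_beta * rng_eff.uniform(
        0.75, 1.25, size=len(hla_idx))

    # keep planted probes clear of the [0, 1] boundaries (headroom beyond
    # the effect size), otherwise the noise truncation piles observations
    # at the clip edge and biases the observed deltas
    head = 0.08
    h0[loss_idx] = d_loss + rng_eff.uniform(0.02, 0.08, size=len(loss_idx))
    # 5hmC is oxidized 5mC, so h-carrying sites keep some 5mC: flooring m
    # also keeps oxBS observations off the zero boundary
    m0[loss_idx] = np.clip(m0[loss_idx], head, 1.0 - h0[loss_idx] - head)
    m0[gain_idx] = np.clip(m0[gain_idx], d_gain + head, None)
    m0[gain_idx] = np.minimum(m0[gain_idx], 1.0 - h0[gain_idx] - d_gain - head)
    m0[hyper_idx] = np.minimum(m0[hyper_idx], 1.0 - h0[hyper_idx] - d_hyper - head)
    m0[hypo_idx] = np.clip(m0[hypo_idx], d_hypo + head, None)
    m0[hla_idx] = np.minimum(m0[hla_idx], 1.0 - h0[hla_idx] - d_hla - head)

    # --- condition truth ----------------------------------------------------
    m = {c: m0.copy() for c in effects.conditions}
    h = {c: h0.copy() for c in effects.conditions}
    for cond in ("MUT", "MUT_T4", "MUT_T7"):
        m[cond][loss_idx] += d_loss
        h[cond][loss_idx] -= d_loss
        m[cond][gain_idx] -= d_gain
        h[cond][gain_idx] += d_gain
        m[cond][hyper_idx] += d_hyper
        m[cond][hypo_idx] -= d_hypo
        m[cond][hla_idx] += d_hla
    for cond, rev in (("MUT_T4", effects.reversal_fraction_t4),
                      ("MUT_T7", effects.reversal_fraction_t7)):
        moved = np.concatenate([loss_idx, gain_idx, hyper_idx, hypo_idx])
        m[cond][moved] += rev * (m0[moved] - m[cond][moved])
        h[cond][moved] += rev * (h0[moved] - h[cond][moved])
        # HLA-like probes deliberately NOT reversed (non-responder retention)

    clamped = 0
    for cond in effects.conditions:
        bad = (m[cond] < 0) | (h[cond] < 0) | (m[cond] + h[cond] > 1)
        clamped += int(bad.sum())
        m[cond] = np.clip(m[cond], 0.0, 1.0)
        h[cond] = np.clip(h[cond], 0.0, 1.0)
        excess = m[cond] + h[cond] - 1.0
        over = excess > 0
        m[cond][over] -= excess[over]
    if clamped:
        logger.warning("methylome truth clamped at %d probe/condition pairs", clamped)

    # --- observation --------------------------------------------------------
    design = _sample_sheet(effects)
    sd = effects.beta_noise_sd
    sd_shared = sd * np.sqrt(effects.beta_noise_shared_frac)
    sd_assay = sd * np.sqrt(1.0 - effects.beta_noise_shared_frac)
    bs_cols, ox_cols = {}, {}
    for cond in effects.conditions:
        for rep in range(effects.replicates_per_condition):
            name = f"{cond}_r{rep + 1}"
            if sd == 0:
                bs_cols[name] = m[cond] + h[cond]
                ox_cols[name] = m[cond].copy()
            else:
                shared = rng_noise.normal(0.0, sd_shared, size=n)
                bs_cols[name] = np.clip(
                    m[cond] + h[cond] + shared
                    + rng_noise.normal(0.0, sd_assay, size=n), 0.0, 1.0)
                ox_cols[name] = np.clip(
                    m[cond] + shared
                    + rng_noise.normal(0.0, sd_assay, size=n), 0.0, 1.0)

    index = pd.Index(probes["id"], name="probe")
    bs = BetaMatrix(pd.DataFrame(bs_cols, index=index), design, assay="BS")
    oxbs = BetaMatrix(pd.DataFrame(ox_cols, index=index), design, assay="oxBS")

    truth_cols = {}
    for cond in effects.conditions:
        truth_cols[f"m_{cond}"] = m[cond]
        truth_cols[f"h_{cond}"] = h[cond]
    probe_truth = pd.DataFrame(truth_cols, index=index)
    delta_m = np.zeros(n)
    delta_h = np.zeros(n)
    delta_m[loss_idx] += d_loss
    delta_h[loss_idx] -= d_loss
    delta_m[gain_idx] -= d_gain
    delta_h[gain_idx] += d_gain
    delta_m[hyper_idx] += d_hyper
    delta_m[hypo_idx] -= d_hypo
    delta_m[hla_idx] += d_hla
    probe_effects = pd.DataFrame({"delta_m": delta_m, "delta_h": delta_h},
                                 index=index)
    ids = probes["id"].to_numpy()
    truth = TruthTables(
        probe_truth=probe_truth,
        probe_effects=probe_effects,
        sets={
            "loss_5hmc": list(ids[loss_idx]),
            "gain_5hmc": list(ids[gain_idx]),
            "hyper_5mc": list(ids[hyper_idx]),
            "hypo_5mc": list(ids[hypo_idx]),
            "hla_probes": list(ids[hla_idx]),
        },
    )
    return bs, oxbs, truth


# ---------------------------------------------------------------------------
# Nascent transcription simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float,
             sampling_noise: bool) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if not sampling_noise:
        return np.rint(mean).astype(np.int64)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def simulate_transcription(
    annotation: GenomeAnnotation, effects: EffectConfig
) -> tuple[CoverageTracks, CountMatrix, TruthTables]:
    """Simulate strand-specific nascent coverage and count matrices.

    Every gene contributes a rectangular coverage block on its own strand;
    a subset of enhancers is transcribed bidirectionally (divergent blocks
    around the enhancer midpoint). Per-unit counts are negative-binomial
    with condition means implementing the planted log2 fold changes, and
    reads are scattered multinomially over the unit's bins, plus sparse
    Poisson background noise. Planted enhancer-promoter pairs put a
    de-regulated enhancer within ``ep_window`` of a concordantly de-regulated
    gene; HLA-like genes are down-regulated in MUT and never rescued.

    Returns the coverage tracks, the gene-level count matrix (the RNA-seq
    analogue), and truth tables (which also carry truth-level eRNA counts).

    Substream order (``SeedSequence(effects.seed + 1).spawn``):
    expression levels, DE assignment, counts, read placement, background.
    """
    effects.validate()
    if effects.n_ernas_transcribed > len(annotation.enhancers):
        raise ConfigurationError("n_ernas_transcribed exceeds enhancer count")
    if effects.n_ernas_up + effects.n_ernas_down > effects.n_ernas_transcribed:
        raise ConfigurationError("DE eRNA counts exceed transcribed enhancers")
    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(effects.seed + 1).spawn(5)]
    rng_expr, rng_de, rng_counts, rng_reads, rng_bg = rngs

    genes = annotation.genes.reset_index(drop=True)
    zero_len = genes["end"] <= genes["start"]
    if zero_len.any():
        raise ConfigurationError("zero-length gene units rejected")
    n_genes = len(genes)
    cluster_genes = annotation.gene_sets.get("HLA_like", [])
    lo, hi = effects.mean_count_range
    base_mean = np.exp(rng_expr.uniform(np.log(lo), np.log(hi), size=n_genes))
    in_cluster = genes["id"].isin(cluster_genes).to_numpy()
    base_mean[in_cluster] = np.exp(rng_expr.uniform(np.log(200.0), np.log(800.0),
                                                    size=in_cluster.sum()))

    # --- gene DE assignment -------------------------------------------------
    lfc = np.zeros(n_genes)
    cluster_idx = np.flatnonzero(in_cluster)
    lfc[cluster_idx] = effects.hla_like_cluster.log2fc
    n_down_extra = max(0, effects.n_genes_down - len(cluster_idx))
    free = np.flatnonzero(~in_cluster)
    de_extra = rng_de.choice(free, size=n_down_extra + effects.n_genes_up,
                             replace=False)
    down_extra = de_extra[:n_down_extra]
    up_idx = de_extra[n_down_extra:]
    lfc[down_extra] = -rng_de.uniform(1.0, 2.5, size=len(down_extra))
    lfc[up_idx] = rng_de.uniform(1.0, 2.5, size=len(up_idx))
    down_idx = np.concatenate([cluster_idx, down_extra])
    rescued = rng_de.choice(down_extra, size=min(effects.n_genes_rescued,
                                                 len(down_extra)), replace=False)
    rescued_mask = np.zeros(n_genes, dtype=bool)
    rescued_mask[rescued] = True

    gene_cond_mean = {
        "WT": base_mean,
        "MUT": base_mean * 2.0 ** lfc,
        "MUT_T4": base_mean * 2.0 ** lfc,
        "MUT_T7": np.where(rescued_mask, base_mean, base_mean * 2.0 ** lfc),
    }

    # --- eRNA geometry and DE ----------------------------------------------
    enh = annotation.enhancers.reset_index(drop=True)
    tx_pos = rng_expr.choice(len(enh), size=effects.n_ernas_transcribed,
                             replace=False)
    tx_pos.sort()
    tx = enh.iloc[tx_pos].reset_index(drop=True)
    mid = ((tx["start"] + tx["end"]) // 2).to_numpy()
    llo, lhi = effects.erna_length_range
    len_minus = rng_expr.integers(llo, lhi + 1, size=len(tx))
    len_plus = rng_expr.integers(llo, lhi + 1, size=len(tx))
    gap = rng_expr.integers(0, 200, size=len(tx))
    minus_end = mid - gap // 2
    minus_start = np.clip(minus_end - len_minus, 0, None)
    plus_start = mid + (gap - gap // 2)
    plus_end = plus_start + len_plus
    elo, ehi = effects.erna_mean_range
    e_mean_minus = np.exp(rng_expr.uniform(np.log(elo), np.log(ehi), size=len(tx)))
    e_mean_plus = np.exp(rng_expr.uniform(np.log(elo), np.log(ehi), size=len(tx)))

    e_lfc = np.zeros(len(tx))
    gene_tss = annotation.tss().set_index("id")
    pair_rows = []
    paired_enh: set[int] = set()
    de_gene_pool = list(np.concatenate([down_idx, up_idx]))
    rng_de.shuffle(de_gene_pool)
    for gi in de_gene_pool:
        if len(pair_rows) >= effects.n_ep_pairs:
            break
        g = genes.iloc[gi]
        tssg = int(gene_tss.loc[g["id"], "tss"])
        cands = np.flatnonzero(
            (tx["chrom"] == g["chrom"]).to_numpy()
            & (np.abs((minus_start + plus_end) // 2 - tssg) <= effects.ep_window)
        )
        cands = [c for c in cands if c not in paired_enh and e_lfc[c] == 0.0]
        if not cands:
            continue
        dists = np.abs((minus_start[cands] + plus_end[cands]) // 2 - tssg)
        c = cands[int(np.argmin(dists))]
        direction = 1.0 if lfc[gi] > 0 else -1.0
        e_lfc[c] = direction * rng_de.uniform(1.0, 2.5)
        paired_enh.add(c)
        pair_rows.append((tx["id"].iloc[c], g["id"], int(dists.min()),
                          "up" if direction > 0 else "down"))

    n_up_have = int((e_lfc > 0).sum())
    n_down_have = int((e_lfc < 0).sum())
    free_e = np.flatnonzero(e_lfc == 0.0)
    need = (effects.n_ernas_up - n_up_have) + (effects.n_ernas_down - n_down_have)
    extra = rng_de.choice(free_e, size=need, replace=False)
    up_extra = extra[: effects.n_ernas_up - n_up_have]
    down_extra_e = extra[effects.n_ernas_up - n_up_have:]
    e_lfc[up_extra] = rng_de.uniform(1.0, 2.5, size=len(up_extra))
    e_lfc[down_extra_e] = -rng_de.uniform(1.0, 2.5, size=len(down_extra_e))
    erna_cond_scale = {c: 2.0 ** e_lfc if c != "WT" else np.ones(len(tx))
                       for c in effects.conditions}

    # --- counts and coverage -----------------------------------------------
    design = _sample_sheet(effects)
    bin_size = effects.bin_size
    chrom_lengths = dict(zip(annotation.chromosomes["chrom"],
                             annotation.chromosomes["length"]))
    data: dict[tuple[str, str, str], np.ndarray] = {}
    for sample in design.samples:
        for chrom, length in chrom_lengths.items():
            nb = -(-length // bin_size)
            data[(sample, chrom, "+")] = np.zeros(nb, dtype=np.int32)
            data[(sample, chrom, "-")] = np.zeros(nb, dtype=np.int32)

    def scatter(arr: np.ndarray, start: int, end: int, k: int) -> None:
        b0, b1 = start // bin_size, -(-end // bin_size)
        nbin = max(1, b1 - b0)
        if k <= 0:
            return
        if effects.sampling_noise:
            arr[b0:b0 + nbin] += rng_reads.multinomial(
                k, np.full(nbin, 1.0 / nbin)).astype(np.int32)
        else:
            base, extra_r = divmod(k, nbin)
            arr[b0:b0 + nbin] += base
            arr[b0:b0 + extra_r] += 1

    gene_counts = {}
    erna_counts = {}
    alpha = effects.nb_dispersion
    for sample in design.samples:
        cond = design.table.loc[sample, "condition"]
        gk = _nb_draw(rng_counts, gene_cond_mean[cond], alpha,
                      effects.sampling_noise)
        gene_counts[sample] = gk
        ek_minus = _nb_draw(rng_counts, e_mean_minus * erna_cond_scale[cond],
                            alpha, effects.sampling_noise)
        ek_plus = _nb_draw(rng_counts, e_mean_plus * erna_cond_scale[cond],
                           alpha, effects.sampling_noise)
        erna_counts[sample] = ek_minus + ek_plus
        for i in range(n_genes):
            g = genes.iloc[i]
            scatter(data[(sample, g["chrom"], g["strand"])],
                    int(g["start"]), int(g["end"]), int(gk[i]))
        for i in range(len(tx)):
            chrom = tx["chrom"].iloc[i]
            scatter(data[(sample, chrom, "-")], int(minus_start[i]),
                    int(minus_end[i]), int(ek_minus[i]))
            scatter(data[(sample, chrom, "+")], int(plus_start[i]),
                    int(plus_end[i]), int(ek_plus[i]))
        if effects.sampling_noise and effects.bg_noise_rate > 0:
            for chrom, length in chrom_lengths.items():
                nbins = -(-length // bin_size)
                for strand in "+-":
                    k = int(rng_bg.poisson(effects.bg_noise_rate * nbins))
                    idx = rng_bg.integers(0, nbins, size=k)
                    np.add.at(data[(sample, chrom, strand)], idx, 1)

    tracks = CoverageTracks(bin_size=bin_size, chrom_lengths=chrom_lengths,
                            data=data)
    gene_cm = CountMatrix(
        pd.DataFrame(gene_counts, index=pd.Index(genes["id"], name="feature")),
        design, feature_kind="gene")
    erna_cm = pd.DataFrame(erna_counts, index=pd.Index(tx["id"], name="feature"))

    gene_truth = pd.DataFrame({
        "id": genes["id"], "chrom": genes["chrom"], "start": genes["start"],
        "end": genes["end"], "strand": genes["strand"],
        "base_mean": base_mean, "lfc_mut": lfc, "rescued": rescued_mask,
    }).set_index("id")
    erna_truth = pd.DataFrame({
        "enhancer_id": tx["id"], "chrom": tx["chrom"],
        "minus_start": minus_start, "minus_end": minus_end,
        "plus_start": plus_start, "plus_end": plus_end,
        "span_start": np.minimum(minus_start, plus_start),
        "span_end": np.maximum(minus_end, plus_end),
        "lfc_mut": e_lfc,
    }).set_index("enhancer_id")
    ep_pairs = pd.DataFrame(pair_rows, columns=["enhancer_id", "gene_id",
                                                "distance", "direction"])
    ids = genes["id"].to_numpy()
    truth = TruthTables(
        gene_truth=gene_truth, erna_truth=erna_truth, ep_pairs=ep_pairs,
        erna_counts=erna_cm,
        sets={
            "de_genes_up": list(ids[up_idx]),
            "de_genes_down": list(ids[down_idx]),
            "rescued_genes": list(ids[rescued]),
            "de_ernas_up": list(tx["id"].to_numpy()[e_lfc > 0]),
            "de_ernas_down": list(tx["id"].to_numpy()[e_lfc < 0]),
            "transcribed_enhancers": list(tx["id"]),
        },
    )
    return tracks, gene_cm, truth


def merge_truth(methylome: TruthTables, transcription: TruthTables) -> TruthTables:
    """Combine the methylome and transcription truth of one simulation."""
    merged = replace(methylome)
    merged.gene_truth = transcription.gene_truth
    merged.erna_truth = transcription.erna_truth
    merged.ep_pairs = transcription.ep_pairs
    merged.erna_counts = transcription.erna_counts
    merged.sets = {**methylome.sets, **transcription.sets}
    return merged
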