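"""End-to-end orchestration: simulate -> methylome -> enrichment -> eRNAs ->
DE -> integration -> motifs, with config validation and a run manifest.

The full run reproduces, on synthetic truth-tracked data, the study design
this package implements: steady-state 5mC/5hmC differences between an
IDH-mutant-like and a wild-type condition, their partial reversal under two
treatment timepoints, context enrichment of the changed sites, eRNA
annotation and differential activity, enhancer-promoter pairing,
rescue-overlap and gene-set statistics, motif enrichment, and
methylation retention of the repressed HLA-like cluster.

All outputs are plain TSV/BED/JSON; rerunning with the same config and seed
produces byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ConfigurationError, CountMatrix, GenomeAnnotation
from .diffexpr import estimate_dispersion, nb_wald, size_factors
from .enrichment import annotate_probes, fisher_enrichment
from .integration import (methylation_retention, overlap_test,
                          pair_enhancer_promoter, preranked_gsea)
from .methylome import (call_differential, correlate_changes, delta_beta,
                        estimate_5hmc, standardize_profiles)
from .motifs import Pwm, motif_enrichment, plant_motif, random_sequences
from .nascent import SegmentationParams, annotate_ernas, units_to_bed
from .simulate import (EffectConfig, GenomeSpec, HlaLikeEffect, TruthTables,
                       build_genome, merge_truth, simulate_methylome,
                       simulate_transcription)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_full", "PipelineResult"]


@dataclass(frozen=True)
class AnalysisParams:
    """Stage thresholds; defaults follow the conventional values used for
    the analyses this pipeline mirrors."""

    delta_threshold: float = 0.05
    gene_alpha: float = 0.05
    erna_alpha: float = 0.1
    ep_window: int = 500_000
    require_concordant: bool = True
    retention_threshold: float = 0.05
    gsea_permutations: int = 1000
    motif_score_fraction: float = 0.8
    motif_targets: int = 100
    motif_background: int = 1000
    motif_decoys: int = 10
    motif_target_rate: float = 0.9
    motif_background_rate: float = 0.05

    def validate(self) -> list[str]:
        errors = []
        for name, lo, hi in (
            ("delta_threshold", 0.0, 1.0), ("gene_alpha", 0.0, 1.0),
            ("erna_alpha", 0.0, 1.0), ("retention_threshold", 0.0, 1.0),
            ("motif_score_fraction", 0.0, 1.0),
            ("motif_target_rate", 0.0, 1.0),
            ("motif_background_rate", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                errors.append(f"analysis.{name} must be in [{lo}, {hi}], got {v}")
        for name in ("ep_window", "gsea_permutations", "motif_targets",
                     "motif_background", "motif_decoys"):
            if getattr(self, name) < 0:
                errors.append(f"analysis.{name} must be >= 0")
        return errors


@dataclass(frozen=True)
class PipelineConfig:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    effects: EffectConfig = field(default_factory=EffectConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    write_coverage: bool = False

    def to_yaml(self) -> str:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        doc = {
            "seed": self.seed,
            "write_coverage": self.write_coverage,
            "genome": plain(self.genome),
            "effects": plain(self.effects),
            "segmentation": plain(self.segmentation),
            "analysis": plain(self.analysis),
        }
        return yaml.safe_dump(doc, sort_keys=True)


_SECTIONS = {
    "genome": GenomeSpec,
    "effects": EffectConfig,
    "segmentation": SegmentationParams,
    "analysis": AnalysisParams,
}
_TOP_KEYS = set(_SECTIONS) | {"seed", "write_coverage", "simulate"}


def _build_section(cls, raw: dict, section: str, errors: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"unknown key {section}.{key}")
            continue
        f = known[key]
        if f.type in ("tuple[int, int]", "tuple[float, float]") and \
                isinstance(value, list):
            value = tuple(value)
        if key == "conditions" and isinstance(value, list):
            value = tuple(value)
        if key == "hla_like_cluster" and isinstance(value, dict):
            try:
                value = HlaLikeEffect(**value)
            except TypeError as exc:
                errors.append(f"{section}.{key}: {exc}")
                continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errors.append(f"{section}: {exc}")
        return cls()


def validate_config(raw_text: str | None = None) -> PipelineConfig:
    """Parse and validate a YAML pipeline config.

    Empty input (or ``simulate: default``) yields the full default config.
    Unknown keys and out-of-range values are all reported together in one
    :class:`ConfigurationError`. The config echo is idempotent:
    ``validate_config(cfg.to_yaml()) == cfg``.
    """
    doc = yaml.safe_load(raw_text) if raw_text else None
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config must be a YAML mapping")
    errors: list[str] = []
    unknown = set(doc) - _TOP_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown key {key}")
    simulate = doc.get("simulate", "default")
    if simulate not in ("default", None):
        errors.append("simulate: only 'default' is supported "
                      "(override genome/effects sections instead)")
    sections = {}
    for name, cls in _SECTIONS.items():
        raw = doc.get(name, {})
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            errors.append(f"section {name} must be a mapping")
            raw = {}
        sections[name] = _build_section(cls, raw, name, errors)
    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0
    write_coverage = bool(doc.get("write_coverage", False))
    errors.extend(sections["analysis"].validate())
    for name in ("genome", "effects"):
        try:
            sections[name].validate()
        except ConfigurationError as exc:
            errors.append(f"{name}: {exc}")
    try:
        SegmentationParams(**dataclasses.asdict(sections["segmentation"]))
    except ValueError as exc:
        errors.append(f"segmentation: {exc}")
    if errors:
        raise ConfigurationError("invalid config:\n  " + "\n  ".join(errors))
    # propagate the top-level seed into stage seeds unless explicitly set
    genome = sections["genome"]
    effects = sections["effects"]
    if "seed" not in (doc.get("genome") or {}):
        genome = dataclasses.replace(genome, seed=seed)
    if "seed" not in (doc.get("effects") or {}):
        effects = dataclasses.replace(effects, seed=seed)
    return PipelineConfig(genome=genome, effects=effects,
                          segmentation=sections["segmentation"],
                          analysis=sections["analysis"], seed=seed,
                          write_coverage=write_coverage)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    annotation: GenomeAnnotation
    truth: TruthTables
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _match_ernas(units, truth_erna: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Overlap-match detected eRNA units to planted enhancer transcripts.

    Returns (unit -> enhancer_id map, precision, recall)."""
    ernas = [u for u in units if u.unit_class == "eRNA"]
    mapping = {}
    matched_truth = set()
    by_chrom = {c: g.sort_values("span_start")
                for c, g in truth_erna.groupby("chrom")}
    for u in ernas:
        sub = by_chrom.get(u.chrom)
        if sub is None:
            continue
        hit = sub[(sub["span_start"] < u.end) & (sub["span_end"] > u.start)]
        if len(hit):
            eid = hit.index[0]
            mapping[u.id] = eid
            matched_truth.add(eid)
    precision = len(mapping) / len(ernas) if ernas else float("nan")
    recall = len(matched_truth) / len(truth_erna) if len(truth_erna) else float("nan")
    return pd.Series(mapping, name="enhancer_id"), precision, recall


def run_full(config: PipelineConfig | None = None,
             outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage on a simulated dataset and collect the report.

    When ``outdir`` is given, all stage tables, the summary and the run
    manifest are written there as plain text. Stage failures abort with the
    stage name; outputs written before the failure are preserved.
    """
    cfg = config or PipelineConfig()
    ana = cfg.analysis
    result = PipelineResult(config=cfg, annotation=None, truth=None)
    tables = result.tables
    summary = result.summary

    # --- simulate ----------------------------------------------------------
    sim = _stage("simulate")(lambda: (
        build_genome(cfg.genome),))
    ann = sim()[0]
    bs, oxbs, truth_m = _stage("simulate_methylome")(
        simulate_methylome)(ann, cfg.effects)
    tracks, gene_cm, truth_t = _stage("simulate_transcription")(
        simulate_transcription)(ann, cfg.effects)
    truth = merge_truth(truth_m, truth_t)
    result.annotation, result.truth = ann, truth
    tables["bs"] = bs
    tables["oxbs"] = oxbs
    tables["gene_counts"] = gene_cm
    tables["tracks"] = tracks

    # --- methylome ---------------------------------------------------------
    @_stage("methylome")
    def _methylome():
        est = estimate_5hmc(bs, oxbs)
        out = {"estimate": est}
        for tag, contrast in (("mut", ("WT", "MUT")),
                              ("t4", ("MUT", "MUT_T4")),
                              ("t7", ("MUT", "MUT_T7"))):
            dt = call_differential(delta_beta(est, contrast),
                                   ana.delta_threshold)
            out[f"delta_{tag}"] = dt
        return out

    meth = _methylome()
    tables.update(meth)
    dt_mut = meth["delta_mut"]
    calls_h = dt_mut.calls("h")
    calls_m = dt_mut.calls("m")
    changed_h = dt_mut.table.index[calls_h != "none"]
    loss_true = set(truth.sets["loss_5hmc"])
    gain_true = set(truth.sets["gain_5hmc"])
    called_loss = set(dt_mut.table.index[calls_h == "hypo"])
    called_gain = set(dt_mut.table.index[calls_h == "hyper"])
    true_changed = loss_true | gain_true
    called_changed = called_loss | called_gain
    correct = (called_loss & loss_true) | (called_gain & gain_true)
    summary["n_5hmc_loss_called"] = len(called_loss)
    summary["n_5hmc_gain_called"] = len(called_gain)
    summary["hmc_call_sensitivity"] = len(correct) / len(true_changed)
    summary["hmc_call_fdr"] = (len(called_changed - correct)
                               / max(len(called_changed), 1))
    summary["n_5mc_hyper_called"] = int((calls_m == "hyper").sum())
    summary["n_5mc_hypo_called"] = int((calls_m == "hypo").sum())

    summary["r_steady"] = correlate_changes(dt_mut, dt_mut, changed_h)["r"]
    for tag in ("t4", "t7"):
        dt = meth[f"delta_{tag}"]
        sel = dt.table.index[dt.calls("h") != "none"]
        summary[f"r_{tag}"] = correlate_changes(dt, dt, sel)["r"]

    # z-score profile of delta 5hmC (vs WT) across conditions, loss set
    est = meth["estimate"]
    prof = pd.DataFrame({
        cond: delta_beta(est, ("WT", cond)).table["delta_h"]
        for cond in ("MUT", "MUT_T4", "MUT_T7")})
    z = standardize_profiles(prof.loc[sorted(called_loss & loss_true)])
    tables["z_profile"] = z

    # --- enrichment --------------------------------------------------------
    @_stage("enrichment")
    def _enrich():
        ctx = annotate_probes(ann.probes, ann)
        by_id = ctx.set_index("id")
        feat = fisher_enrichment(changed_h, by_id.index, by_id["feature_class"])
        cpg = fisher_enrichment(changed_h, by_id.index, by_id["cpg_class"])
        return ctx, feat, cpg

    ctx, feat_enr, cpg_enr = _enrich()
    tables["probe_context"] = ctx
    tables["enrichment_feature"] = feat_enr
    tables["enrichment_cpg"] = cpg_enr
    summary["enhancer_p_greater"] = float(
        feat_enr.table.loc["enhancer", "p_greater"])
    summary["promoter_p_less"] = float(feat_enr.table.loc["promoter", "p_less"])
    summary["open_sea_p_greater"] = float(
        cpg_enr.table.loc["open_sea", "p_greater"])
    summary["island_p_less"] = float(cpg_enr.table.loc["island", "p_less"])

    # --- eRNA annotation ---------------------------------------------------
    units, unit_counts = _stage("ernas")(annotate_ernas)(
        tracks, ann, cfg.segmentation)
    tables["units"] = units
    erna_units = [u for u in units if u.unit_class == "eRNA"]
    mapping, precision, recall = _match_ernas(units, truth.erna_truth)
    summary["n_ernas_detected"] = len(erna_units)
    summary["erna_precision"] = precision
    summary["erna_recall"] = recall
    erna_counts = CountMatrix(
        unit_counts.loc[[u.id for u in erna_units], bs.design.samples],
        bs.design, feature_kind="eRNA")
    tables["erna_counts"] = erna_counts

    # --- differential expression -------------------------------------------
    @_stage("diffexpr")
    def _de():
        sf_g = size_factors(gene_cm)
        disp_g = estimate_dispersion(gene_cm, sf_g)
        de_genes = nb_wald(gene_cm, sf_g, disp_g, ("WT", "MUT"),
                           alpha=ana.gene_alpha)
        de_genes_t7 = nb_wald(gene_cm, sf_g, disp_g, ("MUT", "MUT_T7"),
                              alpha=ana.gene_alpha)
        sf_e = size_factors(erna_counts)
        disp_e = estimate_dispersion(erna_counts, sf_e)
        de_ernas = nb_wald(erna_counts, sf_e, disp_e, ("WT", "MUT"),
                           alpha=ana.erna_alpha)
        return de_genes, de_genes_t7, de_ernas

    de_genes, de_genes_t7, de_ernas = _de()
    tables["de_genes"] = de_genes
    tables["de_genes_t7"] = de_genes_t7
    tables["de_ernas"] = de_ernas
    summary["n_genes_up"] = len(de_genes.significant("up"))
    summary["n_genes_down"] = len(de_genes.significant("down"))
    summary["n_ernas_up"] = len(de_ernas.significant("up"))
    summary["n_ernas_down"] = len(de_ernas.significant("down"))

    # --- integration -------------------------------------------------------
    @_stage("integration")
    def _integrate():
        sig_e = de_ernas.table[de_ernas.table["direction"] != "none"]
        unit_by_id = {u.id: u for u in erna_units}
        e_df = pd.DataFrame({
            "id": sig_e.index,
            "chrom": [unit_by_id[i].chrom for i in sig_e.index],
            "start": [unit_by_id[i].start for i in sig_e.index],
            "end": [unit_by_id[i].end for i in sig_e.index],
            "direction": sig_e["direction"].to_numpy(),
        })
        sig_g = de_genes.table[de_genes.table["direction"] != "none"]
        tss = ann.tss().set_index("id")
        g_df = pd.DataFrame({
            "id": sig_g.index,
            "chrom": tss.loc[sig_g.index, "chrom"].to_numpy(),
            "tss": tss.loc[sig_g.index, "tss"].to_numpy(),
            "direction": sig_g["direction"].to_numpy(),
        })
        links = pair_enhancer_promoter(e_df, g_df, ana.ep_window,
                                       require_concordant=ana.require_concordant)
        down_mut = set(de_genes.significant("down"))
        up_t7 = set(de_genes_t7.significant("up"))
        rescue = overlap_test(down_mut, up_t7, de_genes.table.index)
        ranking = pd.Series(de_genes.table["stat"].to_numpy(),
                            index=de_genes.table.index)
        gsea = preranked_gsea(ranking, ann.gene_sets["HLA_like"],
                              set_name="HLA_like",
                              n_perm=ana.gsea_permutations, seed=cfg.seed)
        cluster_down = fisher_enrichment(
            down_mut, de_genes.table.index,
            pd.Series(np.where(de_genes.table.index.isin(
                ann.gene_sets["HLA_like"]), "HLA_like", "other"),
                index=de_genes.table.index))
        # retention mirrors a BS-only patient analysis: the "global" set is
        # what a total-methylation (BS) contrast calls hypermethylated —
        # 5hmC<->5mC trades cancel in BS and rightly stay out of this set
        hla_probes = ann.probe_sets["HLA_like"]
        dt_total = call_differential(delta_beta(bs, ("WT", "MUT")),
                                     ana.delta_threshold)
        tables["delta_total"] = dt_total
        calls_total = dt_total.calls("beta")
        global_hyper = [p for p in dt_total.table.index[calls_total == "hyper"]
                        if p not in set(hla_probes)]
        ret_kw = dict(retention_threshold=ana.retention_threshold,
                      baseline_condition="MUT",
                      treated_conditions=["MUT_T4", "MUT_T7"])
        ret_cluster = methylation_retention(bs, bs, hla_probes,
                                            set_name="HLA_like", **ret_kw)
        ret_global = methylation_retention(bs, bs, global_hyper,
                                           set_name="global_hyper", **ret_kw)
        return links, rescue, gsea, cluster_down, ret_cluster, ret_global

    links, rescue, gsea, cluster_down, ret_cluster, ret_global = _integrate()
    tables["ep_links"] = links
    tables["rescue_overlap"] = rescue
    tables["gsea"] = gsea
    tables["cluster_down_enrichment"] = cluster_down
    tables["retention_cluster"] = ret_cluster
    tables["retention_global"] = ret_global

    planted = truth.ep_pairs
    recovered = 0
    if len(links) and len(planted):
        link_pairs = {(mapping.get(e), g)
                      for e, g in zip(links["enhancer_id"], links["gene_id"])}
        recovered = sum((e, g) in link_pairs
                        for e, g in zip(planted["enhancer_id"],
                                        planted["gene_id"]))
    summary["n_ep_links"] = len(links)
    summary["n_ep_planted_recovered"] = recovered
    summary["n_ep_planted"] = len(planted)
    summary["rescue_overlap_k"] = rescue.overlap
    summary["rescue_overlap_p"] = rescue.p
    summary["gsea_hla_nes"] = gsea.nes
    summary["gsea_hla_p"] = gsea.p
    summary["cluster_down_p"] = float(
        cluster_down.table.loc["HLA_like", "p_greater"])
    cluster_calls = calls_m.loc[ann.probe_sets["HLA_like"]]
    summary["cluster_hyper_count"] = int((cluster_calls == "hyper").sum())
    summary["cluster_hypo_count"] = int((cluster_calls == "hypo").sum())
    summary["cluster_retained_fraction"] = ret_cluster.retained_fraction
    summary["global_retained_fraction"] = ret_global.retained_fraction
    calls_total = tables["delta_total"].calls("beta")
    summary["n_total_hyper_called"] = int((calls_total == "hyper").sum())
    summary["n_total_hypo_called"] = int((calls_total == "hypo").sum())

    # --- motifs ------------------------------------------------------------
    @_stage("motifs")
    def _motifs():
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([cfg.seed, 7]).generate_state(1)))
        planted_pwm = Pwm.from_consensus("planted_TGACTCAG", "TGACTCAG")
        decoys = []
        for i in range(ana.motif_decoys):
            cons = "".join("ACGT"[c] for c in rng.integers(0, 4, size=8))
            decoys.append(Pwm.from_consensus(f"decoy_{i:02d}_{cons}", cons))
        targets = random_sequences(ana.motif_targets, 500, rng, prefix="tgt")
        background = random_sequences(ana.motif_background, 500, rng,
                                      prefix="bg")
        targets = plant_motif(targets, planted_pwm, ana.motif_target_rate, rng)
        background = plant_motif(background, planted_pwm,
                                 ana.motif_background_rate, rng)
        table = motif_enrichment(targets, background, [planted_pwm] + decoys,
                                 ana.motif_score_fraction)
        return table

    motif_table = _motifs()
    tables["motif_enrichment"] = motif_table
    summary["top_motif"] = str(motif_table.iloc[0]["motif"])
    summary["top_motif_pct_targets"] = float(
        motif_table.iloc[0]["pct_targets_with_motif"])

    result.manifest = {
        "package_version": __version__,
        "config": yaml.safe_load(cfg.to_yaml()),
        "seed": cfg.seed,
        "stage_rows": {
            "probes": len(ann.probes), "genes": len(ann.genes),
            "enhancers": len(ann.enhancers),
            "delta_table": len(dt_mut.table),
            "units": len(units), "erna_units": len(erna_units),
            "de_genes": len(de_genes.table), "de_ernas": len(de_ernas.table),
            "ep_links": len(links), "motifs": len(motif_table),
        },
    }
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ann, t = result.annotation, result.tables
    ann.write_bed(outdir / "annotation")
    result.truth.write(outdir / "truth")
    t["bs"].design.table.to_csv(outdir / "sample_sheet.tsv", sep="\t")
    t["bs"].write(outdir / "betas_bs.tsv")
    t["oxbs"].write(outdir / "betas_oxbs.tsv")
    t["gene_counts"].write(outdir / "gene_counts.tsv")
    for tag in ("mut", "t4", "t7", "total"):
        t[f"delta_{tag}"].write(outdir / f"delta_beta_{tag}.tsv", ann.probes)
    t["z_profile"].values.to_csv(outdir / "z_profile_loss.tsv", sep="\t")
    t["probe_context"].to_csv(outdir / "probe_context.tsv", sep="\t",
                              index=False)
    t["enrichment_feature"].table.to_csv(outdir / "enrichment_feature.tsv",
                                         sep="\t")
    t["enrichment_cpg"].table.to_csv(outdir / "enrichment_cpg.tsv", sep="\t")
    units_to_bed(t["units"]).to_csv(outdir / "transcribed_units.bed",
                                    sep="\t", header=False, index=False)
    t["erna_counts"].write(outdir / "erna_counts.tsv")
    t["de_genes"].write(outdir / "de_genes_mut.tsv")
    t["de_genes_t7"].write(outdir / "de_genes_t7.tsv")
    t["de_ernas"].write(outdir / "de_ernas_mut.tsv")
    t["de_genes"].volcano_table().to_csv(outdir / "volcano_genes.tsv", sep="\t")
    t["de_ernas"].volcano_table().to_csv(outdir / "volcano_ernas.tsv", sep="\t")
    t["ep_links"].to_csv(outdir / "ep_links.tsv", sep="\t", index=False)
    t["retention_cluster"].per_probe.to_csv(outdir / "retention_cluster.tsv",
                                            sep="\t")
    t["retention_global"].per_probe.to_csv(outdir / "retention_global.tsv",
                                           sep="\t")
    t["motif_enrichment"].to_csv(outdir / "motif_enrichment.tsv", sep="\t",
                                 index=False)
    t["cluster_down_enrichment"].table.to_csv(
        outdir / "cluster_down_enrichment.tsv", sep="\t")
    gsea = t["gsea"]
    pd.DataFrame([dataclasses.asdict(gsea)]).to_csv(
        outdir / "gsea_hla.tsv", sep="\t", index=False)
    if result.config.write_coverage:
        t["tracks"].write_bedgraph(outdir / "coverage")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
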