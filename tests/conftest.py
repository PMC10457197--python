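"""Shared fixtures: default-scale simulations are session-scoped because
several modules (and the acceptance checks) score against the same planted
truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hmcpipe.core import CountMatrix, SampleSheet
from hmcpipe.pipeline import AnalysisParams, PipelineConfig, run_full
from hmcpipe.simulate import (EffectConfig, GenomeSpec, HlaLikeEffect,
                              build_genome, simulate_methylome,
                              simulate_transcription)


@pytest.fixture(scope="session")
def annotation():
    return build_genome(GenomeSpec(seed=0))


@pytest.fixture(scope="session")
def default_methylome(annotation):
    """Paired BS/oxBS matrices + truth at the default study conditions."""
    return simulate_methylome(annotation, EffectConfig(seed=0))


@pytest.fixture(scope="session")
def default_transcription(annotation):
    return simulate_transcription(annotation, EffectConfig(seed=0))


@pytest.fixture(scope="session")
def full_result():
    """One complete default pipeline run shared by end-to-end checks."""
    return run_full(PipelineConfig())


def tiny_genome_spec(seed: int = 0) -> GenomeSpec:
    return GenomeSpec(
        n_chroms=2, chrom_length=1_500_000, n_genes=120,
        gene_length_range=(1_500, 5_000), n_enhancers=60,
        n_cpg_islands=60, intergenic_probe_count=1_500,
        hla_cluster_size=6, hla_probe_count=40, seed=seed)


def tiny_effects(seed: int = 0, **overrides) -> EffectConfig:
    base = dict(
        n_hyper_5mc=300, n_hypo_5mc=140, n_loss_5hmc=220, n_gain_5hmc=70,
        n_genes_down=18, n_genes_up=12, n_genes_rescued=4,
        n_ernas_transcribed=40, n_ernas_up=8, n_ernas_down=5, n_ep_pairs=3,
        seed=seed)
    base.update(overrides)
    return EffectConfig(**base)


def tiny_pipeline_config(seed: int = 0, **analysis_overrides) -> PipelineConfig:
    ana = AnalysisParams(gsea_permutations=200, motif_targets=40,
                         motif_background=200, **analysis_overrides)
    return PipelineConfig(genome=tiny_genome_spec(seed),
                          effects=tiny_effects(seed), analysis=ana, seed=seed)


def make_count_matrix(counts: np.ndarray, reps_a: int, reps_b: int,
                      kind: str = "gene") -> CountMatrix:
    samples = [f"A_r{i+1}" for i in range(reps_a)] + \
              [f"B_r{i+1}" for i in range(reps_b)]
    design = SampleSheet(pd.DataFrame(
        {"condition": ["A"] * reps_a + ["B"] * reps_b,
         "replicate": list(range(1, reps_a + 1)) + list(range(1, reps_b + 1))},
        index=pd.Index(samples, name="sample")))
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"f{i}" for i in range(len(counts))])
    return CountMatrix(df, design, feature_kind=kind)


def nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float,
              size: int) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    return rng.poisson(rng.gamma(1.0 / alpha, alpha * mean, size=size))
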