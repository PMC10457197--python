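"""Generator tests: geometry, determinism, truth bookkeeping, noise model."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_effects, tiny_genome_spec
from hmcpipe.core import ConfigurationError, PlacementError
from hmcpipe.simulate import (EffectConfig, GenomeSpec, build_genome,
                              simulate_methylome, simulate_transcription)


class TestBuildGenome:
    def test_features_respect_chromosome_bounds(self, annotation):
        length = int(annotation.chromosomes["length"].iloc[0])
        for df in (annotation.genes, annotation.enhancers,
                   annotation.cpg_islands):
            assert (df["start"] >= 0).all()
            assert (df["end"] <= length).all()
            assert (df["start"] < df["end"]).all()
        assert annotation.probes["pos"].between(0, length - 1).all()

    def test_gene_bodies_disjoint_with_gap(self, annotation):
        spec = GenomeSpec()
        for _, sub in annotation.genes.groupby("chrom"):
            s = sub.sort_values("start")
            gaps = s["start"].to_numpy()[1:] - s["end"].to_numpy()[:-1]
            assert (gaps >= spec.min_feature_gap).all()

    def test_enhancers_keep_distance_from_genes(self, annotation):
        spec = GenomeSpec()
        for chrom, enh in annotation.enhancers.groupby("chrom"):
            genes = annotation.genes[annotation.genes["chrom"] == chrom]
            for _, e in enh.iterrows():
                closest = np.minimum(
                    np.abs(genes["start"] - e["end"]),
                    np.abs(e["start"] - genes["end"]))
                overlap = (genes["start"] < e["end"]) & (genes["end"] > e["start"])
                assert not overlap.any()
                assert (closest >= spec.min_feature_gap).all()

    def test_same_seed_is_byte_identical(self):
        spec = tiny_genome_spec(seed=11)
        a, b = build_genome(spec), build_genome(spec)
        for name in ("genes", "enhancers", "cpg_islands", "probes",
                     "promoters"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        assert a.gene_sets == b.gene_sets
        assert a.probe_sets == b.probe_sets

    def test_infeasible_enhancer_density_raises_placement_error(self):
        # pigeonhole: 200 enhancers with 10 kb clearance cannot fit in 1 Mb
        spec = GenomeSpec(n_chroms=1, chrom_length=1_000_000, n_genes=4,
                          n_enhancers=200, min_feature_gap=10_000,
                          n_cpg_islands=5, intergenic_probe_count=10,
                          hla_cluster_size=2, hla_probe_count=4, seed=0)
        with pytest.raises(PlacementError, match="enhancer"):
            build_genome(spec)

    def test_hla_cluster_is_contiguous_run_of_genes(self, annotation):
        ids = annotation.gene_sets["HLA_like"]
        chr1 = annotation.genes[annotation.genes["chrom"] == "chr1"]
        idx = chr1.index[chr1["id"].isin(ids)]
        assert list(idx) == list(range(idx.min(), idx.max() + 1))
        assert len(annotation.probe_sets["HLA_like"]) == GenomeSpec().hla_probe_count

    def test_promoters_are_strand_aware(self, annotation):
        g = annotation.genes.set_index("id")
        p = annotation.promoters.set_index("gene_id")
        plus = g[g["strand"] == "+"].index[0]
        assert p.loc[plus, "start"] == g.loc[plus, "start"] - 1000
        minus = g[g["strand"] == "-"].index[0]
        assert p.loc[minus, "end"] == g.loc[minus, "end"] + 1000


class TestSimulateMethylome:
    def test_zero_noise_recovers_truth_exactly(self, annotation):
        eff = tiny_effects(beta_noise_sd=0.0)
        ann = build_genome(tiny_genome_spec())
        bs, oxbs, truth = simulate_methylome(ann, eff)
        for cond in eff.conditions:
            m = truth.probe_truth[f"m_{cond}"]
            h = truth.probe_truth[f"h_{cond}"]
            for rep in range(eff.replicates_per_condition):
                col = f"{cond}_r{rep + 1}"
                assert np.allclose(oxbs.values[col], m)
                assert np.allclose(bs.values[col], m + h)

    def test_truth_lists_match_configured_counts(self, default_methylome):
        _, _, truth = default_methylome
        eff = EffectConfig()
        assert len(truth.sets["loss_5hmc"]) == eff.n_loss_5hmc == 2156
        assert len(truth.sets["gain_5hmc"]) == eff.n_gain_5hmc == 664
        assert len(truth.sets["hyper_5mc"]) == eff.n_hyper_5mc
        assert len(truth.sets["hypo_5mc"]) == eff.n_hypo_5mc
        all_sets = [s for name in ("loss_5hmc", "gain_5hmc", "hyper_5mc",
                                   "hypo_5mc", "hla_probes")
                    for s in truth.sets[name]]
        assert len(all_sets) == len(set(all_sets)), "planted sets overlap"

    def test_truth_conserves_mass(self, default_methylome):
        _, _, truth = default_methylome
        t = truth.probe_truth
        for cond in EffectConfig().conditions:
            m, h = t[f"m_{cond}"], t[f"h_{cond}"]
            assert (m >= 0).all() and (h >= 0).all()
            assert (m + h <= 1 + 1e-12).all()

    def test_anticorrelated_construction(self, default_methylome):
        # 5hmC loss is compensated by 5mC gain probe-by-probe
        _, _, truth = default_methylome
        eff = truth.probe_effects.loc[truth.sets["loss_5hmc"]]
        assert np.allclose(eff["delta_m"], -eff["delta_h"])
        assert (eff["delta_h"] < 0).all()

    def test_hla_probes_not_reversed_by_treatment(self, default_methylome):
        _, _, truth = default_methylome
        t = truth.probe_truth.loc[truth.sets["hla_probes"]]
        assert np.allclose(t["m_MUT"], t["m_MUT_T7"])
        reversed_ = truth.probe_truth.loc[truth.sets["hyper_5mc"]]
        assert (reversed_["m_MUT_T7"] < reversed_["m_MUT"]).all()

    def test_observed_delta_tracks_truth_within_clt_bound(self, annotation,
                                                          default_methylome):
        bs, oxbs, truth = default_methylome
        eff = EffectConfig()
        loss = truth.sets["loss_5hmc"]
        h_obs = bs.values - oxbs.values
        d_obs = (h_obs[["MUT_r1", "MUT_r2"]].mean(axis=1)
                 - h_obs[["WT_r1", "WT_r2"]].mean(axis=1)).loc[loss]
        d_true = truth.probe_effects.loc[loss, "delta_h"]
        sd_assay = eff.beta_noise_sd * np.sqrt(1 - eff.beta_noise_shared_frac)
        sd_delta = sd_assay * np.sqrt(2) * np.sqrt(2 / eff.replicates_per_condition)
        err = d_obs - d_true
        assert abs(err.mean()) < 3 * sd_delta / np.sqrt(len(loss))
        assert (np.abs(err) < 4 * sd_delta).mean() > 0.995

    def test_effect_counts_beyond_probes_rejected(self):
        ann = build_genome(tiny_genome_spec())
        with pytest.raises(ConfigurationError, match="exceed"):
            simulate_methylome(ann, tiny_effects(n_hyper_5mc=10 ** 6))


class TestSimulateTranscription:
    def test_noise_off_counts_equal_rounded_means(self):
        ann = build_genome(tiny_genome_spec())
        eff = tiny_effects(sampling_noise=False)
        _, gene_cm, truth = simulate_transcription(ann, eff)
        gt = truth.gene_truth
        wt = gene_cm.counts["WT_r1"]
        assert np.array_equal(wt.to_numpy(),
                              np.rint(gt["base_mean"]).astype(int))
        mut = gene_cm.counts["MUT_r1"]
        expected = np.rint(gt["base_mean"] * 2.0 ** gt["lfc_mut"]).astype(int)
        assert np.array_equal(mut.to_numpy(), expected)

    def test_planted_ep_pairs_within_window(self, annotation,
                                            default_transcription):
        _, _, truth = default_transcription
        eff = EffectConfig()
        assert len(truth.ep_pairs) == eff.n_ep_pairs
        tss = annotation.tss().set_index("id")
        et = truth.erna_truth
        for _, row in truth.ep_pairs.iterrows():
            e = et.loc[row["enhancer_id"]]
            mid = (e["span_start"] + e["span_end"]) // 2
            d = abs(int(tss.loc[row["gene_id"], "tss"]) - mid)
            assert d <= eff.ep_window
            # concordant by construction
            gdir = truth.gene_truth.loc[row["gene_id"], "lfc_mut"]
            edir = e["lfc_mut"]
            assert np.sign(gdir) == np.sign(edir) != 0

    def test_nb_sampling_mean(self):
        # 1000 NB draws at mean 100, alpha 0.05: sample mean within +-5
        rng = np.random.Generator(np.random.PCG64(0))
        draws = rng.poisson(rng.gamma(1 / 0.05, 0.05 * 100, size=1000))
        assert abs(draws.mean() - 100) < 5

    def test_coverage_supports_truth_counts(self, default_transcription):
        tracks, gene_cm, truth = default_transcription
        # reads scattered for one gene sum back to its drawn count
        gt = truth.gene_truth.iloc[0]
        b0, b1 = gt["start"] // tracks.bin_size, -(-gt["end"] // tracks.bin_size)
        arr = tracks.data[("WT_r1", gt["chrom"], gt["strand"])]
        total = int(arr[b0:b1].sum())
        k = int(gene_cm.counts.loc[gt.name, "WT_r1"])
        # background noise may add a few extra reads inside the span
        assert k <= total <= k + 50

    def test_same_seed_reproduces_counts(self):
        ann = build_genome(tiny_genome_spec())
        eff = tiny_effects(seed=5)
        _, cm1, t1 = simulate_transcription(ann, eff)
        _, cm2, t2 = simulate_transcription(ann, eff)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1.erna_counts, t2.erna_counts)

    def test_de_erna_counts_match_config(self, default_transcription):
        _, _, truth = default_transcription
        eff = EffectConfig()
        assert len(truth.sets["de_ernas_up"]) == eff.n_ernas_up
        assert len(truth.sets["de_ernas_down"]) == eff.n_ernas_down
        assert len(truth.sets["transcribed_enhancers"]) == eff.n_ernas_transcribed
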