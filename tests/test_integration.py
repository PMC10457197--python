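"""E-P pairing, overlap test, preranked GSEA, methylation retention."""

import numpy as np
import pandas as pd
import pytest

from oracles import (all_pairs_links, gsea_running_sum, hypergeom_upper_tail)
from test_methylome import beta_pair
from hmcpipe.core import ConfigurationError
from hmcpipe.integration import (methylation_retention, overlap_test,
                                 pair_enhancer_promoter, preranked_gsea)


def erna_frame(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end",
                                       "direction"])


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "tss", "direction"])


class TestPairEnhancerPromoter:
    def test_out_of_window_excluded(self):
        e = erna_frame([("e1", "chr1", 0, 1000, "up")])
        g = gene_frame([("g1", "chr1", 600_500, "up")])
        assert len(pair_enhancer_promoter(e, g, 500_000)) == 0

    def test_in_window_signed_distance(self):
        e = erna_frame([("e1", "chr1", 999_000, 1_001_000, "up")])
        g = gene_frame([("g1", "chr1", 1_300_000, "up")])
        links = pair_enhancer_promoter(e, g, 500_000)
        assert len(links) == 1
        assert links["distance"].iloc[0] == 300_000

    def test_matches_all_pairs_oracle(self):
        rng = np.random.Generator(np.random.PCG64(0))
        for _ in range(20):
            ne, ng = rng.integers(1, 8, size=2)
            e_rows = [(f"e{i}", f"chr{rng.integers(1, 3)}",
                       int(rng.integers(0, 3_000_000)), 0,
                       rng.choice(["up", "down"])) for i in range(ne)]
            e_rows = [(i, c, s, s + 1000, d) for i, c, s, _, d in e_rows]
            g_rows = [(f"g{i}", f"chr{rng.integers(1, 3)}",
                       int(rng.integers(0, 3_000_000)),
                       rng.choice(["up", "down"])) for i in range(ng)]
            for conc in (False, True):
                links = pair_enhancer_promoter(erna_frame(e_rows),
                                               gene_frame(g_rows),
                                               500_000, conc)
                expected = all_pairs_links(e_rows, g_rows, 500_000, conc)
                got = sorted(map(tuple, links.to_numpy()))
                assert got == sorted(expected)

    def test_discordant_rejected_when_required(self):
        e = erna_frame([("e1", "chr1", 0, 1000, "up")])
        g = gene_frame([("g1", "chr1", 10_000, "down")])
        assert len(pair_enhancer_promoter(e, g, 500_000, True)) == 0
        links = pair_enhancer_promoter(e, g, 500_000, False)
        assert len(links) == 1 and not links["concordant"].iloc[0]

    def test_planted_pairs_recovered_in_pipeline(self, full_result):
        s = full_result.summary
        assert s["n_ep_planted_recovered"] == s["n_ep_planted"]


class TestOverlapTest:
    def test_worked_example(self):
        uni = [f"x{i}" for i in range(20)]
        res = overlap_test(uni[:5], uni[2:6], uni)
        assert res.overlap == 3
        assert res.p == pytest.approx(155 / 4845, abs=1e-12)  # ~0.0320
        assert res.p == pytest.approx(hypergeom_upper_tail(3, 5, 4, 20),
                                      abs=1e-12)

    def test_zero_overlap_gives_unit_p(self):
        uni = [f"x{i}" for i in range(10)]
        res = overlap_test(uni[:3], uni[5:8], uni)
        assert res.overlap == 0 and res.p == 1.0

    def test_degenerate_full_sets_flagged(self):
        uni = [f"x{i}" for i in range(6)]
        res = overlap_test(uni, uni, uni)
        assert res.p == pytest.approx(1.0)
        assert res.degenerate

    def test_enumeration_agreement_small_universes(self):
        rng = np.random.Generator(np.random.PCG64(1))
        for _ in range(50):
            n = int(rng.integers(4, 60))
            uni = [f"x{i}" for i in range(n)]
            a = list(rng.choice(uni, size=int(rng.integers(1, n)),
                                replace=False))
            b = list(rng.choice(uni, size=int(rng.integers(1, n)),
                                replace=False))
            res = overlap_test(a, b, uni)
            expected = hypergeom_upper_tail(res.overlap, len(a), len(b), n)
            assert res.p == pytest.approx(expected, abs=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigurationError, match="universe"):
            overlap_test([], [], [])


class TestPrerankedGsea:
    def ranking(self):
        return pd.Series(np.arange(10, 0, -1, dtype=float),
                         index=[f"g{i}" for i in range(1, 11)])

    def test_hand_computed_es(self):
        res = preranked_gsea(self.ranking(), ["g1", "g3"], n_perm=10, seed=0)
        scores = np.arange(10, 0, -1, dtype=float)
        is_hit = np.array([True, False, True] + [False] * 7)
        assert res.es == pytest.approx(
            gsea_running_sum(scores, is_hit), abs=1e-12)
        assert res.es == pytest.approx(0.875, abs=1e-12)

    def test_top_set_is_extremal(self):
        r = self.ranking()
        top = preranked_gsea(r, ["g1", "g2"], n_perm=50, seed=0)
        for pair in (["g3", "g7"], ["g5", "g9"], ["g9", "g10"]):
            other = preranked_gsea(r, pair, n_perm=50, seed=0)
            assert top.es >= other.es
        assert top.es > 0

    def test_sign_flips_on_reversed_ranking(self):
        r = self.ranking()
        fwd = preranked_gsea(r, ["g1", "g2", "g3"], n_perm=50, seed=0)
        rev = preranked_gsea(-r, ["g1", "g2", "g3"], n_perm=50, seed=0)
        assert np.sign(fwd.es) == -np.sign(rev.es)
        assert np.sign(fwd.nes) == np.sign(fwd.es)

    def test_classical_ks_symmetry_at_zero_weight(self):
        r = self.ranking()
        fwd = preranked_gsea(r, ["g2", "g4"], n_perm=10, seed=0, weight=0.0)
        rev = preranked_gsea(-r, ["g2", "g4"], n_perm=10, seed=0, weight=0.0)
        assert fwd.es == pytest.approx(-rev.es, abs=1e-12)

    def test_planted_set_significant(self, full_result):
        # pipeline GSEA of the repressed cluster in the DE ranking
        assert full_result.summary["gsea_hla_p"] <= 0.01
        assert full_result.summary["gsea_hla_nes"] < 0

    def test_disjoint_set_rejected(self):
        with pytest.raises(ConfigurationError, match="disjoint"):
            preranked_gsea(self.ranking(), ["nope"], n_perm=10, seed=0)

    def test_es_bounded_by_one(self):
        rng = np.random.Generator(np.random.PCG64(0))
        r = pd.Series(rng.normal(size=200),
                      index=[f"g{i}" for i in range(200)])
        res = preranked_gsea(r, [f"g{i}" for i in range(0, 200, 10)],
                             n_perm=100, seed=1)
        assert abs(res.es) <= 1.0


class TestMethylationRetention:
    def test_no_change_fully_retained(self):
        bs, _ = beta_pair(np.full((6, 4), 0.7), np.zeros((6, 4)))
        res = methylation_retention(bs, bs, bs.probes,
                                    baseline_condition="A",
                                    treated_conditions=["B"])
        assert res.retained_fraction == 1.0
        assert res.mean_delta == 0.0

    def test_half_shifted_half_retained(self):
        vals = np.full((10, 4), 0.7)
        vals[:5, 2:] -= 0.2  # five probes lose 0.2 in condition B
        bs, _ = beta_pair(vals, np.zeros((10, 4)))
        res = methylation_retention(bs, bs, bs.probes,
                                    baseline_condition="A",
                                    treated_conditions=["B"])
        assert res.retained_fraction == pytest.approx(0.5)

    def test_missing_probes_listed(self):
        bs, _ = beta_pair(np.full((3, 4), 0.5), np.zeros((3, 4)))
        with pytest.raises(ConfigurationError, match="cgX"):
            methylation_retention(bs, bs, ["cg0", "cgX"])

    def test_cluster_retained_globally_reversed(self, full_result):
        s = full_result.summary
        assert s["cluster_retained_fraction"] >= 0.9
        assert s["global_retained_fraction"] < 0.5
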