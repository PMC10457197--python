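"""Methylome estimation, delta-beta, calling, correlation, z-scores."""

import numpy as np
import pandas as pd
import pytest

from oracles import pearson_by_formula
from hmcpipe.core import (AlignmentError, BetaMatrix, ConfigurationError,
                          ContrastError, SampleSheet)
from hmcpipe.methylome import (call_differential, correlate_changes,
                               delta_beta, estimate_5hmc,
                               standardize_profiles)


def beta_pair(bs_vals, ox_vals, conditions=("A", "A", "B", "B")):
    samples = [f"{c}_r{i}" for i, c in enumerate(conditions)]
    design = SampleSheet(pd.DataFrame(
        {"condition": conditions,
         "replicate": list(range(1, len(conditions) + 1))},
        index=pd.Index(samples, name="sample")))
    probes = pd.Index([f"cg{i}" for i in range(len(bs_vals))], name="probe")
    bs = BetaMatrix(pd.DataFrame(np.asarray(bs_vals, dtype=float),
                                 index=probes, columns=samples), design, "BS")
    ox = BetaMatrix(pd.DataFrame(np.asarray(ox_vals, dtype=float),
                                 index=probes, columns=samples), design, "oxBS")
    return bs, ox


class TestEstimate5hmc:
    @pytest.mark.parametrize("bs,ox,h_raw,h,m", [
        (0.6, 0.6, 0.0, 0.0, 0.6),     # identical assays: no 5hmC
        (0.80, 0.65, 0.15, 0.15, 0.65),
        (0.50, 0.60, -0.10, 0.0, 0.60),  # negative difference clipped
    ])
    def test_arithmetic(self, bs, ox, h_raw, h, m):
        mat_bs, mat_ox = beta_pair([[bs] * 4], [[ox] * 4])
        est = estimate_5hmc(mat_bs, mat_ox)
        assert est.h_raw.iloc[0, 0] == pytest.approx(h_raw)
        assert est.h.iloc[0, 0] == pytest.approx(h)
        assert est.m.iloc[0, 0] == pytest.approx(m)

    def test_state_estimates_stay_in_unit_simplex(self):
        # m + h = max(BS, oxBS) <= 1 for valid betas, so the joint rescale
        # guard never fires on in-range input; the invariant still holds
        rng = np.random.Generator(np.random.PCG64(0))
        mat_bs, mat_ox = beta_pair(rng.random((50, 4)), rng.random((50, 4)))
        est = estimate_5hmc(mat_bs, mat_ox)
        assert est.n_rescaled == 0
        assert ((est.m + est.h).to_numpy() <= 1 + 1e-12).all()
        # raw difference preserved unmodified, including negatives
        assert np.allclose(est.h_raw, mat_bs.values - mat_ox.values)

    def test_misaligned_probes_raise(self):
        mat_bs, mat_ox = beta_pair([[0.5] * 4], [[0.5] * 4])
        mat_ox.values.index = pd.Index(["other"], name="probe")
        with pytest.raises(AlignmentError, match="other"):
            estimate_5hmc(mat_bs, mat_ox)

    def test_missing_values_propagate(self):
        mat_bs, mat_ox = beta_pair([[0.5, np.nan, 0.5, 0.5]],
                                   [[0.4, 0.4, 0.4, 0.4]])
        est = estimate_5hmc(mat_bs, mat_ox)
        assert np.isnan(est.h_raw.iloc[0, 1])
        assert est.h_raw.iloc[0, 0] == pytest.approx(0.1)


class TestDeltaBeta:
    def test_identical_groups_zero_delta(self):
        bs, ox = beta_pair(np.full((5, 4), 0.7), np.full((5, 4), 0.5))
        table = delta_beta(estimate_5hmc(bs, ox), ("A", "B"))
        assert np.allclose(table.table["delta_h"], 0.0)
        assert np.allclose(table.table["delta_m"], 0.0)

    def test_forced_arithmetic(self):
        ox = [[0.30, 0.30, 0.42, 0.42]]
        bs, oxm = beta_pair([[0.5] * 4], ox)
        table = delta_beta(estimate_5hmc(bs, oxm), ("A", "B"))
        assert table.table["delta_m"].iloc[0] == pytest.approx(0.12)

    def test_unknown_condition_raises(self):
        bs, ox = beta_pair(np.full((2, 4), 0.5), np.full((2, 4), 0.5))
        with pytest.raises(ContrastError, match="nope"):
            delta_beta(estimate_5hmc(bs, ox), ("A", "nope"))

    def test_welch_requires_replicates(self):
        bs, ox = beta_pair(np.full((2, 2), 0.5), np.full((2, 2), 0.4),
                           conditions=("A", "B"))
        with pytest.raises(ConfigurationError, match="replicates"):
            delta_beta(estimate_5hmc(bs, ox), ("A", "B"), test="welch_t")

    def test_welch_null_calibration(self):
        # synthetic null, 4 vs 4: p uniform, rejection rate in binomial CI
        rng = np.random.Generator(np.random.PCG64(0))
        n = 5000
        vals = rng.normal(0.5, 0.05, size=(n, 8)).clip(0, 1)
        conditions = ("A",) * 4 + ("B",) * 4
        bs, ox = beta_pair(vals, np.zeros((n, 8)), conditions=conditions)
        table = delta_beta(bs, ("A", "B"), test="welch_t")
        frac = float((table.table["p_beta"] < 0.05).mean())
        ci = 3 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < ci


class TestCallDifferential:
    def test_threshold_is_strict(self):
        # dyadic values so that delta == threshold holds exactly in floats
        bs, ox = beta_pair([[0.5, 0.5, 0.5625, 0.5625],
                            [0.5, 0.5, 0.375, 0.375]],
                           np.zeros((2, 4)))
        table = call_differential(delta_beta(bs, ("A", "B")), 0.0625)
        calls = table.calls("beta")
        assert calls.iloc[0] == "none"   # delta exactly at threshold
        assert calls.iloc[1] == "hypo"   # delta -0.125

    def test_alpha_without_test_is_an_error(self):
        bs, ox = beta_pair(np.full((2, 4), 0.5), np.zeros((2, 4)))
        table = delta_beta(bs, ("A", "B"))
        with pytest.raises(ConfigurationError, match="test"):
            call_differential(table, 0.05, alpha=0.05)

    def test_recovers_planted_5hmc_sites(self, default_methylome):
        bs, ox, truth = default_methylome
        table = call_differential(delta_beta(estimate_5hmc(bs, ox),
                                             ("WT", "MUT")), 0.05)
        calls = table.calls("h")
        loss, gain = set(truth.sets["loss_5hmc"]), set(truth.sets["gain_5hmc"])
        called_hypo = set(table.table.index[calls == "hypo"])
        called_hyper = set(table.table.index[calls == "hyper"])
        correct = (called_hypo & loss) | (called_hyper & gain)
        called = called_hypo | called_hyper
        assert len(correct) / len(loss | gain) >= 0.90
        assert len(called - correct) / len(called) <= 0.10


class TestCorrelateChanges:
    def test_perfect_anticorrelation(self):
        probes = [f"cg{i}" for i in range(10)]
        d = pd.Series(np.linspace(-0.3, 0.3, 10), index=probes)
        t = pd.DataFrame({"delta_h": d, "delta_m": -d})
        from hmcpipe.methylome import DeltaBetaTable
        table = DeltaBetaTable(t, ("A", "B"), ("m", "h"))
        assert correlate_changes(table, table, probes)["r"] == pytest.approx(-1.0)

    def test_matches_hand_pearson_formula(self):
        x = [0.1, 0.2, 0.3, 0.0, 0.4]
        y = [-0.1, -0.1, -0.3, 0.0, -0.2]
        t = pd.DataFrame({"delta_h": x, "delta_m": y},
                         index=[f"cg{i}" for i in range(5)])
        from hmcpipe.methylome import DeltaBetaTable
        table = DeltaBetaTable(t, ("A", "B"), ("m", "h"))
        res = correlate_changes(table, table, t.index)
        assert res["r"] == pytest.approx(pearson_by_formula(x, y), abs=1e-12)
        assert res["n"] == 5

    def test_symmetric_under_mark_swap(self):
        rng = np.random.Generator(np.random.PCG64(1))
        t = pd.DataFrame({"delta_h": rng.normal(size=50),
                          "delta_m": rng.normal(size=50)},
                         index=[f"cg{i}" for i in range(50)])
        from hmcpipe.methylome import DeltaBetaTable
        table = DeltaBetaTable(t, ("A", "B"), ("m", "h"))
        r1 = correlate_changes(table, table, t.index, "h", "m")["r"]
        r2 = correlate_changes(table, table, t.index, "m", "h")["r"]
        assert r1 == pytest.approx(r2, abs=1e-14)

    def test_zero_variance_is_an_error(self):
        t = pd.DataFrame({"delta_h": [0.1] * 5,
                          "delta_m": [0.0, 0.1, 0.2, 0.3, 0.4]},
                         index=[f"cg{i}" for i in range(5)])
        from hmcpipe.methylome import DeltaBetaTable
        table = DeltaBetaTable(t, ("A", "B"), ("m", "h"))
        with pytest.raises(ConfigurationError, match="variance"):
            correlate_changes(table, table, t.index)


class TestStandardizeProfiles:
    def test_linear_row(self):
        z = standardize_profiles(pd.DataFrame([[1.0, 2.0, 3.0]]))
        expected = np.array([-1.0, 0.0, 1.0]) / np.std([1, 2, 3], ddof=1)
        assert np.allclose(z.values.iloc[0], expected)
        # rows standardized with the sample (n-1) convention: unit variance
        assert np.std(z.values.iloc[0], ddof=1) == pytest.approx(1.0)

    def test_constant_row_zeroed_and_flagged(self):
        df = pd.DataFrame([[0.5, 0.5, 0.5], [1.0, 2.0, 4.0]],
                          index=["flat", "varying"])
        z = standardize_profiles(df)
        assert np.allclose(z.values.loc["flat"], 0.0)
        assert list(z.constant_rows) == ["flat"]

    def test_duplicated_columns_get_identical_z(self):
        df = pd.DataFrame([[0.1, 0.4, 0.4], [0.9, 0.2, 0.2]],
                          columns=["a", "b", "b2"])
        z = standardize_profiles(df)
        assert np.allclose(z.values["b"], z.values["b2"])
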