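"""Error metrics, ranking coefficients, bootstrap intervals, significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import kendall_pair_oracle

from rbfenet.stats import (
    StatisticError,
    bootstrap_ci,
    determinant_correlations,
    metric_with_ci,
    mue,
    outlier_ratio,
    rank_metrics,
    rmse,
    significance_matrix,
    weighted_tau_overall,
)


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "dev,exp_rmse,exp_mue",
        [([1.0, -1.0], 1.0, 1.0), ([0.0, 2.0], np.sqrt(2.0), 1.0), ([0.0, 0.0], 0.0, 0.0)],
    )
    def test_textbook_values(self, dev, exp_rmse, exp_mue):
        dev = np.array(dev)
        assert rmse(dev, np.zeros_like(dev)) == pytest.approx(exp_rmse)
        assert mue(dev, np.zeros_like(dev)) == pytest.approx(exp_mue)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatisticError):
            rmse(np.ones(3), np.ones(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40))
    def test_rmse_dominates_mue(self, devs):
        dev = np.array(devs)
        ref = np.zeros_like(dev)
        assert rmse(dev, ref) >= mue(dev, ref) - 1e-12


class TestRanking:
    def test_concordant_and_reversed(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert rank_metrics(x, x) == (1.0, 1.0)
        tau, rho = rank_metrics(x, -x)
        assert (tau, rho) == (-1.0, -1.0)

    def test_adjacent_swap_matches_pair_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        tau, _ = rank_metrics(x, y)
        assert tau == pytest.approx(2.0 / 3.0)
        assert tau == pytest.approx(kendall_pair_oracle(x, y))

    @pytest.mark.parametrize("seed", range(10))
    def test_tau_b_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 12).astype(float)  # rounding creates ties
        y = x + rng.integers(-2, 3, 12)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            pytest.skip("degenerate draw")
        tau, _ = rank_metrics(x, y)
        assert tau == pytest.approx(kendall_pair_oracle(x, y), abs=1e-12)

    def test_constant_vector_flagged_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            tau, rho = rank_metrics(np.ones(5), np.arange(5.0))
        assert np.isnan(tau) and np.isnan(rho)


class TestWeightedTau:
    def test_single_target_identity(self):
        assert weighted_tau_overall([(12, 0.42)]) == pytest.approx(0.42)

    def test_two_target_weighting(self):
        assert weighted_tau_overall([(10, 0.5), (30, 0.9)]) == pytest.approx(0.8)

    def test_constant_tau_independent_of_weights(self):
        assert weighted_tau_overall([(3, 0.37), (17, 0.37), (100, 0.37)]) == pytest.approx(0.37)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_stays_in_range(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 12)
        ns = rng.integers(3, 40, k)
        taus = rng.uniform(-1, 1, k)
        got = weighted_tau_overall(list(zip(ns, taus)))
        brute = sum(n * t for n, t in zip(ns, taus)) / sum(ns)
        assert got == pytest.approx(brute, abs=1e-12)
        assert taus.min() - 1e-12 <= got <= taus.max() + 1e-12

    def test_undefined_targets_excluded_with_renormalization(self, caplog):
        with caplog.at_level("WARNING"):
            got = weighted_tau_overall([(10, 0.5), (30, np.nan)])
        assert got == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(StatisticError):
            weighted_tau_overall([])


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        val, lo, hi = bootstrap_ci(lambda d: float(np.mean(d)), np.full(10, 2.5), seed=0)
        assert val == lo == hi == 2.5

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal(50)
        a = bootstrap_ci(lambda d: float(np.std(d)), data, n_boot=200, seed=42)
        b = bootstrap_ci(lambda d: float(np.std(d)), data, n_boot=200, seed=42)
        assert a == b

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal(40)
        a = bootstrap_ci(lambda d: float(np.mean(d)), data, n_boot=200, seed=7)
        b = bootstrap_ci(lambda d: float(np.mean(d)), data[::-1].copy(), n_boot=200, seed=7)
        assert a == b

    def test_interval_brackets_value(self):
        rng = np.random.default_rng(2)
        data = np.column_stack([rng.standard_normal(80), np.zeros(80)])
        r = metric_with_ci("rmse", data[:, 0], data[:, 1], n_boot=300, seed=0)
        assert r.ci_low <= r.value <= r.ci_high

    def test_mostly_undefined_statistic_rejected(self):
        def bad(d):
            return np.nan

        with pytest.raises(StatisticError, match="undefined"):
            bootstrap_ci(bad, np.arange(10.0), n_boot=50, seed=0)


class TestSignificance:
    def _pivot(self, devs_by_ff):
        return pd.DataFrame(devs_by_ff)

    def test_identical_force_fields_tie(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(100)
        sm = significance_matrix(self._pivot({"F1": d, "F2": d.copy()}), seed=0)
        assert not sm.significant.loc["F1", "F2"]
        assert sm.winner.loc["F1", "F1"] == "tie"

    def test_tripled_deviations_significant_with_winner(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal(500)
        sm = significance_matrix(self._pivot({"F1": d, "F2": 3 * d}), seed=0)
        assert sm.significant.loc["F1", "F2"]
        assert sm.winner.loc["F1", "F2"] == "left"  # F1 has the lower RMSE
        assert sm.winner.loc["F2", "F1"] == "down"

    def test_structure_symmetric_in_significance(self):
        rng = np.random.default_rng(2)
        sm = significance_matrix(
            self._pivot({f"F{i}": rng.standard_normal(60) * (1 + 0.3 * i) for i in range(4)}),
            seed=3,
        )
        assert (sm.significant.to_numpy() == sm.significant.to_numpy().T).all()
        assert (np.diag(sm.significant.to_numpy()) == False).all()  # noqa: E712

    def test_requires_two_force_fields(self):
        with pytest.raises(ValueError):
            significance_matrix(self._pivot({"F1": np.arange(5.0)}))


class TestOutlierRatio:
    def test_threshold_counts(self):
        ratios, _ = outlier_ratio(
            pd.DataFrame({"target": "T1", "deviation": [0.5, 1.5]}), thresholds=(1.0, 2.0)
        )
        by_t = ratios.set_index("threshold")["ratio"]
        assert by_t[1.0] == 0.5
        assert by_t[2.0] == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        dev = pd.DataFrame(
            {"target": np.repeat([f"T{i}" for i in range(6)], 30),
             "deviation": rng.normal(0, 1.5, 180)}
        )
        ratios, _ = outlier_ratio(dev)
        for _, grp in ratios.groupby("target"):
            r = grp.sort_values("threshold")["ratio"].to_numpy()
            assert (np.diff(r) >= 0).all()

    def test_box_summary_matches_reference_quartiles(self):
        rng = np.random.default_rng(3)
        dev = pd.DataFrame(
            {"target": np.repeat([f"T{i:02d}" for i in range(22)], 40),
             "deviation": rng.normal(0, 1.7, 880)}
        )
        ratios, summary = outlier_ratio(dev, thresholds=(1.0,))
        r = np.sort(ratios["ratio"].to_numpy())
        # linear-interpolation quantile, computed directly
        def quantile(v, q):
            pos = q * (len(v) - 1)
            lo = int(np.floor(pos))
            return v[lo] + (pos - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

        row = summary.iloc[0]
        assert row["q1"] == pytest.approx(quantile(r, 0.25))
        assert row["median"] == pytest.approx(quantile(r, 0.5))
        assert row["q3"] == pytest.approx(quantile(r, 0.75))


class TestDeterminantCorrelations:
    def _table(self, n, rng):
        return pd.DataFrame(
            {"heavy_atom_change": rng.integers(1, 15, n).astype(float),
             "abs_deviation": rng.exponential(1.0, n),
             "ddg_pred": rng.normal(0, 2, n),
             "alpha_mean": rng.uniform(-1, 1, n)}
        )

    def test_planted_linear_dependence_recovered(self):
        rng = np.random.default_rng(0)
        df = self._table(1000, rng)
        df["abs_deviation"] = 0.1 * df["heavy_atom_change"] + rng.normal(0, 0.4, 1000)
        corr, bins = determinant_correlations(df)
        row = corr.set_index(["x", "y"]).loc[("heavy_atom_change", "abs_deviation")]
        expected = 0.1 * df["heavy_atom_change"].std() / df["abs_deviation"].std()
        assert row["pearson_r"] == pytest.approx(expected, abs=0.08)
        assert row["stars"] == "***"
        assert (bins.groupby(["x", "y"]).size() == 20).all()

    def test_independent_features_mostly_uncorrelated(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            corr, _ = determinant_correlations(self._table(1000, rng))
            r = corr.set_index(["x", "y"]).loc[("ddg_pred", "alpha_mean"), "pearson_r"]
            hits += abs(r) >= 0.08
        assert hits <= 2  # |r| < 0.08 should hold in ~99% of null draws

    def test_constant_feature_flagged(self):
        rng = np.random.default_rng(1)
        df = self._table(100, rng)
        df["alpha_mean"] = 0.5
        corr, _ = determinant_correlations(df)
        row = corr.set_index(["x", "y"]).loc[("ddg_pred", "alpha_mean")]
        assert bool(row["undefined"]) and np.isnan(row["pearson_r"])
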