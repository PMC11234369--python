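"""Parameter perturbation sets, MCC co-usage, clustering, and ΔRMSE."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, matthews_corrcoef

from rbfenet.params import (
    cluster_parameters,
    delta_rmse,
    mcc,
    mcc_matrix,
    perturbed_parameters,
    rmse_per_parameter,
    usage_matrix,
)


class TestPerturbedParameters:
    def test_identical_assignments_empty(self):
        a = Counter({"b20": 2, "t107": 1})
        assert perturbed_parameters(a, Counter(a)) == set()

    def test_count_change_detected(self):
        a = Counter({"b20": 2, "t107": 1})
        b = Counter({"b20": 1, "t107": 1})
        assert perturbed_parameters(a, b) == {"b20"}

    def test_annihilation_and_creation(self):
        assert perturbed_parameters(Counter({"a15": 1}), Counter({"t106": 1})) == {"a15", "t106"}

    def test_symmetric(self):
        a, b = Counter({"x": 1, "y": 2}), Counter({"y": 1, "z": 3})
        assert perturbed_parameters(a, b) == perturbed_parameters(b, a)


def _usages(perturbed_sets):
    return pd.DataFrame(
        [{"target": "T1", "ligand_a": f"A{i}", "ligand_b": f"B{i}",
          "perturbed": frozenset(s)} for i, s in enumerate(perturbed_sets)]
    )


class TestUsageMatrix:
    def test_binary_entries_lexicographic_columns(self):
        mat = usage_matrix(_usages([{"p1"}, {"p1", "p2"}]))
        assert list(mat.columns) == ["p1", "p2"]
        assert mat.to_numpy().tolist() == [[1, 0], [1, 1]]

    def test_unused_parameter_absent(self):
        mat = usage_matrix(_usages([{"p1"}, {"p1"}]))
        assert list(mat.columns) == ["p1"]

    def test_all_empty_warns(self, caplog):
        with caplog.at_level("WARNING"):
            mat = usage_matrix(_usages([set(), set()]))
        assert mat.shape == (2, 0)


class TestMCC:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
            ([1, 1, 0, 0], [0, 0, 1, 1], -1.0),
            ([1, 0, 1, 0], [1, 1, 0, 0], 0.0),
        ],
    )
    def test_canonical_values(self, u, v, expected):
        assert mcc(np.array(u), np.array(v)) == pytest.approx(expected)

    def test_zero_marginal_returns_zero(self):
        assert mcc(np.array([1, 1, 1, 1]), np.array([1, 0, 1, 0])) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_sklearn_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.integers(0, 2, 60)
        v = rng.integers(0, 2, 60)
        if len(set(u)) < 2 or len(set(v)) < 2:
            pytest.skip("degenerate draw")
        assert mcc(u, v) == pytest.approx(matthews_corrcoef(u, v), abs=1e-12)

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(5)
        u, v = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert mcc(u, v) == pytest.approx(mcc(1 - u, 1 - v), abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        u, v = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert mcc(u, v) == mcc(v, u)


class TestClustering:
    def _block_usage(self, rng, blocks, n_edges=200, noise=0.0):
        cols = [p for block in blocks for p in block]
        rows = np.zeros((n_edges, len(cols)), dtype=int)
        for e in range(n_edges):
            k = rng.integers(0, len(blocks))
            start = sum(len(b) for b in blocks[:k])
            rows[e, start:start + len(blocks[k])] = 1
            flip = rng.random(len(cols)) < noise
            rows[e, flip] = 1 - rows[e, flip]
        return pd.DataFrame(rows, columns=cols)

    def test_two_perfect_blocks_recovered(self):
        rng = np.random.default_rng(0)
        usage = self._block_usage(rng, [["p1", "p2", "p3"], ["q1", "q2", "q3"]])
        labels = cluster_parameters(mcc_matrix(usage), n_clusters=2, seed=0)
        assert labels["p1"] == labels["p2"] == labels["p3"]
        assert labels["q1"] == labels["q2"] == labels["q3"]
        assert labels["p1"] != labels["q1"]

    def test_noisy_planted_blocks_high_agreement(self):
        blocks = [[f"b{k}{i}" for i in range(4)] for k in range(3)]
        truth = [k for k, b in enumerate(blocks) for _ in b]
        good = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            usage = self._block_usage(rng, blocks, noise=0.10)
            labels = cluster_parameters(mcc_matrix(usage), n_clusters=3, seed=0)
            if adjusted_rand_score(truth, labels.to_numpy()) > 0.9:
                good += 1
        assert good >= 18

    def test_labels_are_valid_partition_under_identity_affinity(self):
        corr = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        labels = cluster_parameters(corr, n_clusters="auto", seed=0)
        assert set(labels.index) == set("abcde")
        assert labels.notna().all()

    def test_invariant_to_column_permutation(self):
        rng = np.random.default_rng(1)
        usage = self._block_usage(rng, [["p1", "p2"], ["q1", "q2"]], noise=0.05)
        labels = cluster_parameters(mcc_matrix(usage), n_clusters=2, seed=0)
        perm = usage[["q2", "p1", "q1", "p2"]]
        labels_p = cluster_parameters(mcc_matrix(perm), n_clusters=2, seed=0)
        same = labels.loc[["p1", "p2", "q1", "q2"]].to_numpy()
        permuted = labels_p.loc[["p1", "p2", "q1", "q2"]].to_numpy()
        assert adjusted_rand_score(same, permuted) == 1.0


class TestRMSEPerParameter:
    def test_subset_rmse(self):
        usage = usage_matrix(_usages([{"p"}, {"p"}, {"q"}]))
        out = rmse_per_parameter(np.array([1.0, -1.0, 2.0]), usage).set_index("parameter")
        assert out.loc["p", "rmse"] == pytest.approx(1.0)
        assert out.loc["q", "rmse"] == pytest.approx(2.0)
        assert bool(out.loc["q", "low_support"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_subset_recompute(self, seed):
        rng = np.random.default_rng(seed)
        params = [f"p{i}" for i in range(8)]
        sets = [set(rng.choice(params, rng.integers(1, 4), replace=False)) for _ in range(60)]
        usage = usage_matrix(_usages(sets))
        dev = rng.normal(0, 1, 60)
        out = rmse_per_parameter(dev, usage).set_index("parameter")
        for p in usage.columns:
            rows = [i for i, s in enumerate(sets) if p in s]
            if rows:
                brute = np.sqrt(np.mean(dev[rows] ** 2))
                assert out.loc[p, "rmse"] == pytest.approx(brute, abs=1e-12)


class TestDeltaRMSE:
    def test_identical_force_fields_null(self):
        rng = np.random.default_rng(0)
        sets = [{"p"}, {"p", "q"}, {"q"}] * 20
        usage = usage_matrix(_usages(sets))
        dev = rng.normal(0, 0.5, len(sets))
        out = delta_rmse(dev, dev.copy(), usage, n_boot=300, seed=0)
        assert np.allclose(out["delta_rmse"], 0.0)
        assert not out["significant"].any()

    def test_planted_bias_detected_on_target_parameter(self):
        rng = np.random.default_rng(1)
        params = [f"p{i}" for i in range(10)]
        sets = [set(rng.choice(params, 2, replace=False)) for _ in range(200)]
        usage = usage_matrix(_usages(sets))
        star = usage["p0"].to_numpy(dtype=bool)
        d2 = rng.normal(0, 0.3, 200)
        d1 = d2 + 1.0 * star
        out = delta_rmse(d1, d2, usage, n_boot=500, seed=0).set_index("parameter")
        assert out.loc["p0", "delta_rmse"] > 0.5
        assert bool(out.loc["p0", "significant"])

    def test_mismatched_edge_sets_rejected(self):
        usage = usage_matrix(_usages([{"p"}, {"q"}]))
        with pytest.raises(ValueError):
            delta_rmse(np.zeros(2), np.zeros(3), usage)
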