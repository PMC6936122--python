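import numpy as np
import pandas as pd
import pytest

from rbpcons.relieff import (
    RbpFeatureTable,
    regress_response_on_feature,
    rrelieff,
    shuffle_robustness,
)


def table_from(columns: dict, response="response") -> RbpFeatureTable:
    return RbpFeatureTable(pd.DataFrame(columns), response=response)


def reference_rrelieff(frame, response, k, sigma):
    """Independent step-by-step evaluation of the weight accumulation,
    written as plain loops over instances and neighbors."""
    predictors = [c for c in frame.columns if c != response]
    x = frame[predictors].to_numpy(dtype=float)
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    x = (x - lo) / span
    y = frame[response].to_numpy(dtype=float)
    y_range = y.max() - y.min()
    n = len(y)
    rank_w = np.exp(-((np.arange(1, k + 1) / sigma) ** 2))
    rank_w = rank_w / rank_w.sum()
    n_dc = 0.0
    n_df = np.zeros(len(predictors))
    n_dcdf = np.zeros(len(predictors))
    for r in range(n):
        dists = []
        for i in range(n):
            if i == r:
                continue
            dists.append((sum(abs(x[i, f] - x[r, f]) for f in range(x.shape[1])), i))
        dists.sort(key=lambda t: (t[0], t[1]))
        for rank, (_, i) in enumerate(dists[:k]):
            w = rank_w[rank]
            d_y = abs(y[i] - y[r]) / y_range
            n_dc += d_y * w
            for f in range(len(predictors)):
                d_f = abs(x[i, f] - x[r, f])
                n_df[f] += d_f * w
                n_dcdf[f] += d_y * d_f * w
    weights = {}
    for f, name in enumerate(predictors):
        if n_df[f] == 0:
            weights[name] = 0.0
        else:
            weights[name] = n_dcdf[f] / n_dc - (n_df[f] - n_dcdf[f]) / (n - n_dc)
    return weights


class TestRrelieff:
    def test_constant_predictor_weight_exactly_zero(self, rng):
        t = table_from(
            {
                "const": np.full(20, 7.0),
                "noise": rng.normal(size=20),
                "response": rng.normal(50, 10, size=20),
            }
        )
        fw = rrelieff(t, k=5, m="all")
        assert fw.weights["const"] == 0.0

    def test_matches_hand_trace_on_four_instances(self):
        """k=1, m=all, n=4: the implementation reproduces an explicit
        manual evaluation of the accumulation."""
        frame = pd.DataFrame(
            {
                "x1": [0.0, 1.0, 2.0, 3.0],
                "x2": [5.0, 1.0, 4.0, 2.0],
                "response": [10.0, 20.0, 15.0, 40.0],
            }
        )
        fw = rrelieff(RbpFeatureTable(frame), k=1, m="all", sigma=20.0)
        expected = reference_rrelieff(frame, "response", k=1, sigma=20.0)
        for name in expected:
            assert fw.weights[name] == pytest.approx(expected[name], abs=1e-12)

    def test_matches_hand_trace_on_random_table(self, rng):
        frame = pd.DataFrame(
            {
                "a": rng.normal(size=12),
                "b": rng.uniform(0, 5, size=12),
                "c": rng.normal(10, 3, size=12),
                "response": rng.normal(50, 10, size=12),
            }
        )
        fw = rrelieff(RbpFeatureTable(frame), k=4, m="all", sigma=10.0)
        expected = reference_rrelieff(frame, "response", k=4, sigma=10.0)
        for name in expected:
            assert fw.weights[name] == pytest.approx(expected[name], abs=1e-10)

    def test_informative_beats_noise_feature(self, rng):
        wins = 0
        reps = 20
        for _ in range(reps):
            x1 = rng.uniform(0, 1, size=60)
            t = table_from(
                {
                    "x1": x1,
                    "x2": rng.uniform(0, 1, size=60),
                    "response": x1 * 100,
                }
            )
            fw = rrelieff(t, k=10, m="all")
            if fw.weights["x1"] > fw.weights["x2"]:
                wins += 1
        assert wins >= 19

    def test_duplicated_predictor_gets_equal_weight(self, rng):
        x = rng.normal(size=30)
        t = table_from(
            {"x": x, "x_copy": x.copy(), "response": x * 10 + rng.normal(size=30)}
        )
        fw = rrelieff(t, k=5, m="all")
        assert fw.weights["x"] == pytest.approx(fw.weights["x_copy"], abs=1e-12)

    def test_positive_scaling_invariance(self, rng):
        x = rng.normal(size=30)
        y = x * 10 + rng.normal(size=30)
        fw1 = rrelieff(table_from({"x": x, "response": y}), k=5, m="all")
        fw2 = rrelieff(table_from({"x": 1000 * x, "response": y}), k=5, m="all")
        assert fw1.weights["x"] == pytest.approx(fw2.weights["x"], abs=1e-12)

    def test_full_sweep_is_deterministic(self, rng):
        t = table_from(
            {"a": rng.normal(size=25), "response": rng.normal(50, 5, size=25)}
        )
        assert rrelieff(t, k=5, m="all").weights == rrelieff(t, k=5, m="all").weights

    def test_subsampled_is_seed_deterministic(self, rng):
        t = table_from(
            {"a": rng.normal(size=25), "response": rng.normal(50, 5, size=25)}
        )
        assert (
            rrelieff(t, k=5, m=10, seed=3).weights
            == rrelieff(t, k=5, m=10, seed=3).weights
        )

    def test_argument_errors(self, rng):
        t = table_from({"a": rng.normal(size=10), "response": rng.normal(size=10)})
        with pytest.raises(ValueError, match="k"):
            rrelieff(t, k=10, m="all")
        flat = table_from({"a": rng.normal(size=10), "response": np.full(10, 5.0)})
        with pytest.raises(ValueError, match="zero variance"):
            rrelieff(flat, k=3, m="all")


class TestShuffleRobustness:
    @pytest.fixture
    def planted(self, rng):
        # a top feature plus two others that also carry signal: only
        # then does shuffling the top one leave it the sole noise column
        x1 = rng.uniform(0, 1, size=60)
        x2 = rng.uniform(0, 1, size=60)
        x3 = rng.uniform(0, 1, size=60)
        return table_from(
            {
                "informative": x1,
                "weak1": x2,
                "weak2": x3,
                "response": 60 * x1 + 45 * x2 + 40 * x3 + rng.normal(0, 2, size=60),
            }
        )

    def test_informative_feature_drops_to_bottom(self, planted):
        report = shuffle_robustness(planted, k=10, m="all", n_shuffles=20, seed=1)
        row = report.set_index("feature").loc["informative"]
        assert row["original_rank"] == 1
        assert row["median_shuffled_rank"] == 3  # last of 3 features
        assert bool(row["rank_critical"])

    def test_least_informative_feature_barely_moves(self, planted):
        report = shuffle_robustness(planted, k=10, m="all", n_shuffles=20, seed=1)
        row = report.set_index("feature").loc["weak2"]
        assert abs(row["rank_shift"]) <= 1

    def test_zero_shuffles_rejected(self, planted):
        with pytest.raises(ValueError):
            shuffle_robustness(planted, n_shuffles=0, k=10)


class TestRegression:
    def test_exact_linear_data(self):
        x = np.arange(10, dtype=float)
        t = table_from({"x": x, "response": 2 * x + 1})
        slope, intercept, p = regress_response_on_feature(t, "x")
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert p < 1e-10

    def test_null_slope_not_significant_on_average(self, rng):
        pvals = [
            regress_response_on_feature(
                table_from(
                    {"x": rng.normal(size=200), "response": rng.normal(size=200)}
                ),
                "x",
            )[2]
            for _ in range(50)
        ]
        # under the null p is uniform: mean near 0.5, few small values
        assert 0.3 < float(np.mean(pvals)) < 0.7

    def test_planted_negative_slope_recovered(self, rng):
        x = rng.uniform(0, 10, size=100)
        y = -1.4 * x + rng.normal(0, 1, size=100)
        t = table_from({"x": x, "response": y})
        slope, _, _ = regress_response_on_feature(t, "x")
        # sd of the slope estimate is ~0.035 here; 4 sd margin
        assert slope == pytest.approx(-1.4, abs=0.15)

    def test_zero_variance_feature(self):
        t = table_from({"x": np.full(5, 3.0), "response": np.arange(5.0)})
        with pytest.raises(ValueError):
            regress_response_on_feature(t, "x")

    def test_unknown_feature(self):
        t = table_from({"x": np.arange(5.0), "response": np.arange(5.0)})
        with pytest.raises(ValueError):
            regress_response_on_feature(t, "nope")


class TestTableValidation:
    def test_missing_values_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan], "response": [1.0, 2.0]})
        with pytest.raises(ValueError, match="complete"):
            RbpFeatureTable(frame)

    def test_tsv_roundtrip(self, tmp_path, rng):
        frame = pd.DataFrame(
            {"a": rng.normal(size=5), "response": rng.normal(size=5)},
            index=[f"R{i}" for i in range(5)],
        )
        t = RbpFeatureTable(frame)
        path = tmp_path / "t.tsv"
        t.to_tsv(path)
        again = RbpFeatureTable.from_tsv(path)
        assert again.predictors == ["a"]
        assert np.allclose(again.y, t.y)
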