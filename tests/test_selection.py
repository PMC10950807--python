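import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circuitrx import (
    apply_selection,
    bootstrap_evaluate,
    generate_synthetic_dataset,
    nogueira_stability,
    r2_per_output,
    select_kdts,
)
from circuitrx.errors import AlignmentError, ConfigurationError
from circuitrx.explain import RelevanceMatrix
from circuitrx.morf import MorfHyperparams
from circuitrx.selection import MAP_AVERAGE_LABEL


def relevance_from(magnitude, sign=None):
    mag = pd.DataFrame(magnitude)
    mag.index = [f"g{i}" for i in range(mag.shape[0])]
    mag.columns = [f"c{k}" for k in range(mag.shape[1])]
    if sign is None:
        sgn = pd.DataFrame(1, index=mag.index, columns=mag.columns, dtype=float)
    else:
        sgn = pd.DataFrame(sign)
        sgn.index, sgn.columns = mag.index, mag.columns
    return RelevanceMatrix(magnitude=mag, sign=sgn)


class TestR2:
    def test_mean_predictor_scores_zero(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        pred = pd.DataFrame(
            np.tile(Y.mean(axis=0).to_numpy(), (30, 1)), columns=list("abc")
        )
        assert np.allclose(r2_per_output(Y, pred), 0.0)

    def test_perfect_predictor_scores_one(self):
        rng = np.random.default_rng(1)
        Y = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        assert np.allclose(r2_per_output(Y, Y.copy()), 1.0)

    def test_hand_computed_value(self):
        Y = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        pred = pd.DataFrame({"a": [1.0, 2.0, 2.0]})
        assert r2_per_output(Y, pred)["a"] == pytest.approx(0.5)

    def test_zero_variance_truth_flagged(self):
        Y = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 1.0]})
        pred = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 1.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            r2 = r2_per_output(Y, pred)
        assert math.isnan(r2["a"]) and r2["b"] == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(AlignmentError):
            r2_per_output(pd.DataFrame({"a": [1.0, 2.0]}), pd.DataFrame({"a": [1.0]}))


class TestSelection:
    def test_quantile_with_interpolation(self):
        rel = relevance_from([[1.0], [2.0], [3.0], [4.0]])
        r2 = pd.Series({"c0": 0.8})
        Z = select_kdts(rel, r2, q_th=0.75, r2_th=0.5)
        # linear-interpolation 0.75-quantile of (1,2,3,4) is 3.25
        assert Z["c0"].tolist() == [0, 0, 0, 1]

    def test_r2_gate_empties_column(self):
        rel = relevance_from([[1.0], [2.0]])
        Z = select_kdts(rel, pd.Series({"c0": 0.3}), q_th=0.5, r2_th=0.5)
        assert (Z["c0"] == 0).all()

    def test_all_equal_magnitudes_all_selected(self):
        rel = relevance_from([[0.7], [0.7], [0.7]])
        Z = select_kdts(rel, pd.Series({"c0": 0.9}))
        assert (Z["c0"] == 1).all()

    def test_default_thresholds_cap_selection(self):
        rng = np.random.default_rng(0)
        mags = rng.permutation(np.linspace(0.01, 1.0, 100)).reshape(100, 1)
        rel = relevance_from(mags)
        Z = select_kdts(rel, pd.Series({"c0": 0.9}), q_th=0.95, r2_th=0.5)
        assert Z["c0"].sum() <= 6

    @given(st.integers(1, 40), st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_selection_count_bound(self, d, q_th):
        mags = np.linspace(1.0, d, d).reshape(d, 1)  # distinct magnitudes
        rel = relevance_from(mags)
        Z = select_kdts(rel, pd.Series({"c0": 1.0}), q_th=q_th, r2_th=0.0)
        assert 1 <= Z["c0"].sum() <= math.ceil((1 - q_th) * d) + 1

    def test_apply_selection_masks(self):
        rel = relevance_from([[0.3], [0.5]], sign=[[-1.0], [1.0]])
        Z = pd.DataFrame([[1], [0]], index=rel.magnitude.index, columns=rel.magnitude.columns)
        sprime = apply_selection(rel, Z)
        assert sprime.iloc[0, 0] == pytest.approx(-0.3)
        assert sprime.iloc[1, 0] == 0.0

    def test_apply_selection_identity_and_zero_masks(self):
        rel = relevance_from([[0.3], [0.5]])
        ones = pd.DataFrame(1, index=rel.magnitude.index, columns=rel.magnitude.columns)
        pd.testing.assert_frame_equal(apply_selection(rel, ones), rel.signed_relevance)
        assert (apply_selection(rel, ones * 0).to_numpy() == 0).all()


class TestNogueira:
    def test_identical_runs_give_one(self):
        est, lo, hi = nogueira_stability(np.array([[1, 0], [1, 0]]))
        assert est == pytest.approx(1.0)
        assert lo <= est <= hi

    def test_alternating_runs_give_minus_one(self):
        est, _, _ = nogueira_stability(np.array([[1, 0], [0, 1]]))
        assert est == pytest.approx(-1.0)

    def test_iid_null_is_near_zero(self):
        rng = np.random.default_rng(0)
        Z = (rng.random((200, 20)) < 0.3).astype(int)
        est, lo, hi = nogueira_stability(Z)
        assert abs(est) < 0.1
        assert lo <= est <= hi

    def test_null_mean_within_three_standard_errors(self):
        # fixed selection size k drawn uniformly at random each run
        rng = np.random.default_rng(1)
        d, k, M = 12, 4, 30
        estimates = []
        for _ in range(200):
            Z = np.zeros((M, d), dtype=int)
            for i in range(M):
                Z[i, rng.choice(d, size=k, replace=False)] = 1
            estimates.append(nogueira_stability(Z)[0])
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates)) <= 3 * se

    def test_degenerate_selection_undefined(self):
        with pytest.warns(UserWarning, match="degenerate"):
            est, lo, hi = nogueira_stability(np.zeros((3, 4)))
        assert math.isnan(est)

    @given(st.integers(2, 12), st.integers(2, 10), st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_estimate_never_exceeds_one(self, M, d, seed):
        rng = np.random.default_rng(seed)
        Z = (rng.random((M, d)) < rng.uniform(0.1, 0.9)).astype(int)
        kbar = Z.sum(axis=1).mean()
        if kbar in (0, d):
            return
        est, _, _ = nogueira_stability(Z)
        assert est <= 1.0 + 1e-12
        if est == pytest.approx(1.0):
            assert (Z == Z[0]).all()


@pytest.fixture(scope="module")
def boot(small_dataset):
    X, Y, _ = small_dataset
    hp = MorfHyperparams(n_trees=60, random_seed=0)
    return bootstrap_evaluate(X, Y, n_splits=8, hp=hp, seed=0)


class TestBootstrap:
    def test_score_table_layout(self, boot):
        assert MAP_AVERAGE_LABEL in boot.scores.index
        assert boot.scores.shape == (4, 6)
        circuits = boot.scores.drop(index=MAP_AVERAGE_LABEL)
        assert (circuits["r2_lo"] <= circuits["r2_point"]).all()
        assert (circuits["r2_point"] <= circuits["r2_hi"]).all()
        assert (circuits["stability_point"] <= 1.0).all()

    def test_stack_shapes(self, boot, small_dataset):
        X, Y, _ = small_dataset
        assert boot.Z_stack.shape == (8, X.shape[1], Y.shape[1])
        assert set(np.unique(boot.Z_stack)) <= {0, 1}

    def test_determinism(self, boot, small_dataset):
        X, Y, _ = small_dataset
        hp = MorfHyperparams(n_trees=60, random_seed=0)
        again = bootstrap_evaluate(X, Y, n_splits=8, hp=hp, seed=0)
        pd.testing.assert_frame_equal(boot.scores, again.scores)
        assert np.array_equal(boot.Z_stack, again.Z_stack)

    def test_pure_noise_fails_the_gate(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(
            rng.normal(size=(120, 10)),
            index=[f"s{i}" for i in range(120)],
            columns=[f"g{j}" for j in range(10)],
        )
        Y = pd.DataFrame(
            rng.normal(size=(120, 2)), index=X.index, columns=["c0", "c1"]
        )
        hp = MorfHyperparams(n_trees=40, random_seed=0)
        boot = bootstrap_evaluate(X, Y, n_splits=6, hp=hp, seed=0)
        circuits = boot.scores.drop(index=MAP_AVERAGE_LABEL)
        assert circuits["r2_point"].median() <= 0
        assert boot.Z_stack.sum() == 0  # nothing passes the R2 gate

    def test_too_few_splits(self, small_dataset):
        X, Y, _ = small_dataset
        with pytest.raises(ConfigurationError):
            bootstrap_evaluate(X, Y, n_splits=1)
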