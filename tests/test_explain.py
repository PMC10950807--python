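from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from circuitrx import (
    MorfHyperparams,
    fit_morf,
    shap_attributions,
    shap_oracle,
    signed_relevance,
    split_background_validation,
)
from circuitrx.errors import ConfigurationError, FeatureGuardError
from circuitrx.explain import ShapTensor
from circuitrx.morf import MorfModel

from conftest import random_forest_instance


class FakeModel:
    """Minimal model exposing predict_array, for oracle axiom checks."""

    def __init__(self, fn, n_outputs=1):
        self.fn = fn
        self.n_outputs = n_outputs

    def predict_array(self, X):
        out = np.apply_along_axis(self.fn, 1, np.asarray(X, dtype=float))
        return np.atleast_2d(out.T).T if out.ndim == 1 else out


class TestSplit:
    def test_partition_contract(self):
        ids = [f"s{i}" for i in range(10)]
        bg, val = split_background_validation(ids, 0.75, seed=0)
        assert len(bg) == 8 and len(val) == 2
        assert set(bg) | set(val) == set(ids)
        assert set(bg) & set(val) == set()

    def test_determinism(self):
        ids = [f"s{i}" for i in range(9)]
        assert split_background_validation(ids, 0.6, 3) == split_background_validation(ids, 0.6, 3)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
    def test_fraction_bounds(self, fraction):
        with pytest.raises(ConfigurationError):
            split_background_validation([f"s{i}" for i in range(10)], fraction, 0)

    def test_too_few_samples(self):
        with pytest.raises(ConfigurationError):
            split_background_validation(["a", "b", "c"], 0.5, 0)


class TestAttributions:
    def test_constant_model_attributes_nothing(self):
        X = pd.DataFrame(
            np.random.default_rng(0).normal(size=(30, 3)),
            index=[f"s{i}" for i in range(30)],
            columns=["a", "b", "c"],
        )
        Y = pd.DataFrame({"c0": np.full(30, 2.5), "c1": np.full(30, -1.0)}, index=X.index)
        model = fit_morf(X, Y, MorfHyperparams(n_trees=5, random_seed=0))
        shap = shap_attributions(model, X.iloc[:20], X.iloc[20:], seed=0)
        assert np.allclose(shap.values, 0.0)
        assert np.allclose(shap.baseline, [2.5, -1.0])

    def test_stump_attributes_only_the_split_feature(self):
        # single depth-1 tree splitting on feature a: x_a > 0 -> 1 else 0
        rng = np.random.default_rng(1)
        xa = np.repeat([-1.0, 1.0], 20)
        X = pd.DataFrame({"a": xa, "b": rng.normal(size=40)},
                         index=[f"s{i}" for i in range(40)])
        Y = pd.DataFrame({"c0": (xa > 0).astype(float)}, index=X.index)
        model = fit_morf(X, Y, MorfHyperparams(n_trees=1, max_depth=1,
                                               max_features_per_split=2, random_seed=0))
        background = pd.DataFrame({"a": [-1.0], "b": [5.0]}, index=["b0"])
        explain = pd.DataFrame({"a": [1.0], "b": [-3.0]}, index=["v0"])
        shap = shap_attributions(model, background, explain, seed=0)
        assert shap.values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        assert shap.values[0, 1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_feature_is_exact_dummy(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"a": rng.normal(size=50), "const": np.ones(50), "b": rng.normal(size=50)},
            index=[f"s{i}" for i in range(50)],
        )
        Y = pd.DataFrame({"c0": X["a"] + X["b"]})
        model = fit_morf(X, Y, MorfHyperparams(n_trees=10, random_seed=0))
        shap = shap_attributions(model, X.iloc[:35], X.iloc[35:], seed=0)
        const_idx = model.feature_ids.index("const")
        assert np.all(shap.values[:, const_idx, :] == 0.0)

    def test_oracle_equivalence_randomized(self):
        """Exact per-tree algorithm equals full coalition enumeration."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            model, bg, x = random_forest_instance(rng)
            explain = pd.DataFrame([x], index=["v0"], columns=model.feature_ids)
            background = pd.DataFrame(bg, columns=model.feature_ids,
                                      index=[f"b{i}" for i in range(len(bg))])
            shap = shap_attributions(model, background, explain, seed=0)
            phi_oracle = shap_oracle(model, bg, x)
            worst = max(worst, float(np.abs(shap.values[0] - phi_oracle).max()))
        assert worst < 1e-8

    def test_local_accuracy_every_sample(self, small_model, small_dataset):
        X, _, _ = small_dataset
        bg, val = X.iloc[:100], X.iloc[100:]
        shap = shap_attributions(small_model, bg, val, seed=0)
        pred = small_model.predict_array(val.to_numpy())
        gap = shap.values.sum(axis=1) - (pred - shap.baseline)
        assert np.abs(gap).max() < 1e-6

    def test_linearity_over_trees(self, small_model, small_dataset):
        X, _, _ = small_dataset
        bg, val = X.iloc[:30], X.iloc[100:105]
        whole = shap_attributions(small_model, bg, val, seed=0).values
        per_tree = []
        for est in small_model.estimator.estimators_:
            sub = MorfModel(
                estimator=SimpleNamespace(estimators_=[est], predict=est.predict),
                feature_ids=small_model.feature_ids,
                output_ids=small_model.output_ids,
                hyperparams=small_model.hyperparams,
            )
            per_tree.append(shap_attributions(sub, bg, val, seed=0).values)
        assert np.allclose(whole, np.mean(per_tree, axis=0), atol=1e-10)

    def test_background_subsample_deterministic(self, small_model, small_dataset):
        X, _, _ = small_dataset
        s1 = shap_attributions(small_model, X.iloc[:100], X.iloc[100:110],
                               background_subsample=20, seed=5)
        s2 = shap_attributions(small_model, X.iloc[:100], X.iloc[100:110],
                               background_subsample=20, seed=5)
        assert np.array_equal(s1.values, s2.values)


class TestOracle:
    def test_symmetry_axiom(self):
        model = FakeModel(lambda row: row[0] + row[1])
        bg = np.array([[0.3, 0.3], [-0.7, -0.7]])
        phi = shap_oracle(model, bg, np.array([1.2, 1.2]))
        assert phi[0, 0] == pytest.approx(phi[1, 0], abs=1e-12)

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(3)
        model = FakeModel(lambda row: row[0] * row[1] - 2 * row[2])
        bg = rng.normal(size=(7, 3))
        x = rng.normal(size=3)
        phi = shap_oracle(model, bg, x)
        total = model.predict_array(x[None, :]).ravel() - model.predict_array(bg).mean(0)
        assert phi.sum(axis=0) == pytest.approx(total, abs=1e-10)

    def test_additive_closed_form(self):
        g1 = lambda v: 2.0 * v
        g2 = lambda v: v**2
        model = FakeModel(lambda row: g1(row[0]) + g2(row[1]))
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(9, 2))
        x = np.array([0.7, -1.3])
        phi = shap_oracle(model, bg, x)
        assert phi[0, 0] == pytest.approx(g1(x[0]) - g1(bg[:, 0]).mean(), abs=1e-10)
        assert phi[1, 0] == pytest.approx(g2(x[1]) - g2(bg[:, 1]).mean(), abs=1e-10)

    def test_feature_guard(self):
        model = FakeModel(lambda row: row.sum())
        with pytest.raises(FeatureGuardError):
            shap_oracle(model, np.zeros((2, 16)), np.zeros(16))


class TestSignedRelevance:
    @staticmethod
    def tensor(phi, x):
        phi = np.asarray(phi, dtype=float)
        n_val, n_feat, n_out = phi.shape
        samples = [f"s{i}" for i in range(n_val)]
        feats = [f"g{i}" for i in range(n_feat)]
        outs = [f"c{i}" for i in range(n_out)]
        val = pd.DataFrame(x, index=samples, columns=feats)
        st = ShapTensor(values=phi, baseline=np.zeros(n_out), sample_ids=samples,
                        feature_ids=feats, output_ids=outs)
        return st, val

    def test_zero_attributions_zero_relevance(self):
        st, val = self.tensor(np.zeros((3, 2, 2)), np.zeros((3, 2)))
        rel = signed_relevance(st, val)
        assert (rel.signed_relevance.to_numpy() == 0).all()
        assert (rel.sign.to_numpy() == 0).all()

    def test_monotone_feature_positive_sign(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        phi = (x - x.mean()).reshape(4, 1, 1)
        st, val = self.tensor(phi, x.reshape(4, 1))
        rel = signed_relevance(st, val)
        assert rel.sign.iloc[0, 0] == 1
        assert rel.magnitude.iloc[0, 0] == pytest.approx(np.abs(x - x.mean()).mean())

    def test_two_sample_hand_example(self):
        phi = np.array([0.2, -0.4]).reshape(2, 1, 1)
        st, val = self.tensor(phi, np.array([[1.0], [0.0]]))
        rel = signed_relevance(st, val)
        assert rel.magnitude.iloc[0, 0] == pytest.approx(0.3)
        assert rel.sign.iloc[0, 0] == 1
        assert rel.signed_relevance.iloc[0, 0] == pytest.approx(0.3)

    def test_single_sample_sign_undefined(self):
        st, val = self.tensor(np.ones((1, 2, 1)), np.ones((1, 2)))
        with pytest.warns(UserWarning, match="sign"):
            rel = signed_relevance(st, val)
        assert (rel.sign.to_numpy() == 0).all()
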