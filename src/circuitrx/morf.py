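"""Multi-output random forest (MORF) regression.

The learner maps known-drug-target (KDT) expression to circuit activity
with an ensemble of multi-output regression trees: each leaf stores one
value per circuit and each split minimizes the mean squared error summed
over all outputs, which regularizes splits toward features that matter
across the map.  Defaults follow the reference protocol: 200 trees,
maximum depth 8, MSE splits, per-node feature subsets of
``ceil(sqrt(n_kdt) + 20)`` capped at ``n_kdt``.

The ensemble engine is scikit-learn's :class:`RandomForestRegressor`
(natively multi-output); trees are exposed as flat node arrays so the
explainer can traverse them exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from .errors import AlignmentError, ConfigurationError, ImputationError

DEFAULT_N_TREES = 200
DEFAULT_MAX_DEPTH = 8


def default_max_features(n_kdt: int) -> int:
    """Per-split candidate-feature count: ceil(sqrt(n_kdt) + 20), capped."""
    return min(n_kdt, math.ceil(math.sqrt(n_kdt) + 20))


@dataclass(frozen=True)
class MorfHyperparams:
    """MORF hyperparameters; ``max_features_per_split=None`` applies the
    default rule at fit time."""

    n_trees: int = DEFAULT_N_TREES
    max_depth: int = DEFAULT_MAX_DEPTH
    max_features_per_split: int | None = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")

    def resolve(self, n_kdt: int) -> "MorfHyperparams":
        mf = self.max_features_per_split
        if mf is None:
            mf = default_max_features(n_kdt)
        if mf > n_kdt:
            raise ConfigurationError(
                f"max_features_per_split={mf} exceeds the {n_kdt} available features"
            )
        return replace(self, max_features_per_split=mf)


@dataclass
class TreeArrays:
    """Flat node-array view of one fitted tree (scikit-learn layout).

    ``feature[i] < 0`` marks a leaf; ``leaf_values`` has one value per
    output (circuit) at every node.
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    leaf_values: np.ndarray  # (n_nodes, n_outputs)


@dataclass
class MorfModel:
    """Fitted MORF plus the metadata needed for aligned prediction."""

    estimator: RandomForestRegressor
    feature_ids: list[str]
    output_ids: list[str]
    hyperparams: MorfHyperparams = field(repr=False)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_outputs(self) -> int:
        return len(self.output_ids)

    def trees(self) -> list[TreeArrays]:
        out = []
        for est in self.estimator.estimators_:
            t = est.tree_
            values = np.ascontiguousarray(t.value[:, :, 0], dtype=np.float64)
            out.append(
                TreeArrays(
                    feature=np.ascontiguousarray(t.feature, dtype=np.int64),
                    threshold=np.ascontiguousarray(t.threshold, dtype=np.float64),
                    children_left=np.ascontiguousarray(t.children_left, dtype=np.int64),
                    children_right=np.ascontiguousarray(t.children_right, dtype=np.int64),
                    leaf_values=values,
                )
            )
        return out

    def predict_array(self, X: np.ndarray) -> np.ndarray:
        """Predict on a raw (n, n_features) array in model feature order."""
        pred = self.estimator.predict(np.asarray(X, dtype=np.float64))
        if pred.ndim == 1:  # single-output edge case
            pred = pred[:, None]
        return pred


def _as_aligned_arrays(X: pd.DataFrame, Y: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not X.index.equals(Y.index):
        raise AlignmentError("X and Y rows are not aligned (sample ids/order differ)")
    return X.to_numpy(dtype=np.float64), Y.to_numpy(dtype=np.float64)


def fit_morf(X: pd.DataFrame, Y: pd.DataFrame, hp: MorfHyperparams | None = None) -> MorfModel:
    """Fit the MORF on row-aligned expression X and activity Y.

    Each tree trains on a bootstrap resample of the rows (with replacement,
    same size); training is deterministic given ``hp.random_seed``.
    Missing values must be imputed first (see :func:`impute_knn`).
    """
    hp = (hp or MorfHyperparams()).resolve(X.shape[1])
    Xa, Ya = _as_aligned_arrays(X, Y)
    if Xa.shape[0] < 2:
        raise ConfigurationError("need at least 2 samples to fit")
    if np.isnan(Xa).any() or np.isnan(Ya).any():
        raise ImputationError("missing values present; run impute_knn first")
    rf = RandomForestRegressor(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        max_features=hp.max_features_per_split,
        criterion="squared_error",
        bootstrap=True,
        random_state=hp.random_seed,
        n_jobs=1,
    )
    rf.fit(Xa, Ya.ravel() if Ya.shape[1] == 1 else Ya)
    return MorfModel(
        estimator=rf,
        feature_ids=[str(c) for c in X.columns],
        output_ids=[str(c) for c in Y.columns],
        hyperparams=hp,
    )


def predict_morf(model: MorfModel, X: pd.DataFrame) -> pd.DataFrame:
    """Predicted activity for every model output; the forest prediction is
    the arithmetic mean of the per-tree leaf vectors."""
    missing = [f for f in model.feature_ids if f not in set(map(str, X.columns))]
    if missing:
        raise AlignmentError(f"prediction input missing feature column(s): {missing[:5]}")
    Xa = X[model.feature_ids].to_numpy(dtype=np.float64)
    pred = model.predict_array(Xa)
    return pd.DataFrame(pred, index=X.index, columns=model.output_ids)


def impute_knn(X: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """k-nearest-neighbour imputation of missing cells.

    Each missing cell becomes the mean of that column over the *k* rows
    nearest in Euclidean distance computed on mutually observed features
    (rescaled by the fraction observed).  Observed cells are untouched.
    """
    fully_missing = [c for c in X.columns if X[c].isna().all()]
    if fully_missing:
        raise ImputationError(f"column(s) entirely missing, cannot impute: {fully_missing}")
    if not X.isna().any().any():
        return X.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    values = imputer.fit_transform(X.to_numpy(dtype=np.float64))
    out = pd.DataFrame(values, index=X.index, columns=X.columns)
    # observed cells are preserved by construction; assert cheaply
    observed = ~X.isna()
    assert np.allclose(out.to_numpy()[observed.to_numpy()], X.to_numpy()[observed.to_numpy()])
    return out


def tune_successive_halving(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_iters: int,
    candidate_grid: list[dict] | None = None,
    seed: int = 0,
    eta: int = 3,
    min_resource: int = 10,
) -> MorfHyperparams:
    """Successive-halving search over {max_depth, max_features_per_split}.

    The elimination resource is the number of trees: every candidate is
    scored (mean per-output R² on an internal 75/25 split) at the current
    tree budget, the top ``1/eta`` fraction survives, and the budget grows
    by ``eta`` each round, for at most ``n_iters`` rounds.  ``n_iters <= 0``
    skips tuning and returns the defaults.  The winner is returned with the
    default production tree count.
    """
    if n_iters <= 0:
        return MorfHyperparams(random_seed=seed)
    if candidate_grid is None:
        n_kdt = X.shape[1]
        depths = [4, 8, 16]
        feats = sorted({default_max_features(n_kdt), max(2, n_kdt // 3), n_kdt})
        candidate_grid = [{"max_depth": d, "max_features_per_split": f} for d in depths for f in feats]

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    cut = int(math.ceil(0.75 * n))
    tr, va = perm[:cut], perm[cut:]
    Xtr, Ytr = X.iloc[tr], Y.iloc[tr]
    Xva, Yva = X.iloc[va], Y.iloc[va]

    candidates = list(candidate_grid)
    resource = min_resource
    for _ in range(n_iters):
        scores = []
        for cand in candidates:
            hp = MorfHyperparams(
                n_trees=resource,
                max_depth=cand["max_depth"],
                max_features_per_split=min(cand["max_features_per_split"], X.shape[1]),
                random_seed=seed,
            )
            model = fit_morf(Xtr, Ytr, hp)
            pred = predict_morf(model, Xva)
            resid = ((Yva - pred) ** 2).sum(axis=0)
            total = ((Yva - Yva.mean(axis=0)) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = 1.0 - resid / total
            scores.append(float(np.nanmean(r2)))
        order = np.argsort(scores)[::-1]
        keep = max(1, math.ceil(len(candidates) / eta))
        candidates = [candidates[i] for i in order[:keep]]
        if len(candidates) == 1:
            break
        resource *= eta
    best = candidates[0]
    if len(candidates) > 1:
        warnings.warn(
            f"halving budget exhausted with {len(candidates)} survivors; keeping the best scored",
            stacklevel=2,
        )
    return MorfHyperparams(
        n_trees=DEFAULT_N_TREES,
        max_depth=best["max_depth"],
        max_features_per_split=min(best["max_features_per_split"], X.shape[1]),
        random_seed=seed,
    )
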