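"""Shapley attribution of KDTs to circuits.

The fitted forest is explained with interventional (background-conditional)
Shapley values: for a validation sample x and coalition S, the value
function is the mean over background rows b of the model evaluated at the
hybrid point taking features in S from x and the rest from b.  The Shapley
value of feature i for output k averages its weighted marginal
contributions over all coalitions.

For a single tree and a single (x, b) pair this game is computed *exactly*
in one traversal: a leaf is reached by the hybrid iff every feature the
paths disagree on is configured the right way, so each leaf contributes a
weighted term that depends only on the sets U (features that must come
from x) and W (features that must come from b) along its path:

    i in U:  +|U-1|! |W|! / (|U|+|W|)! * leaf_value
    i in W:  -|U|! |W-1|! / (|U|+|W|)! * leaf_value

Features on which x and b agree are exact dummies for that leaf.  Summing
over leaves, averaging over background rows and trees yields the forest
attribution; by linearity it equals the mean of per-tree attributions and
satisfies local accuracy sum_i phi_i = f(x) - E_b[f(b)] to machine
precision.  A brute-force coalition-enumeration oracle (guarded to <= 15
features) provides the independent check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import AlignmentError, ConfigurationError, FeatureGuardError
from .morf import MorfModel

_MAX_CONSTRAINTS = 64  # upper bound on distinct constrained features per path
_STACK_CAP = 2 * _MAX_CONSTRAINTS + 4


@njit(cache=True)
def _tree_interventional_shap(
    feature: np.ndarray,
    threshold: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    leaf_values: np.ndarray,
    Xv: np.ndarray,
    bg: np.ndarray,
    fact: np.ndarray,
    phi: np.ndarray,
) -> None:
    """Accumulate, into phi[v, i, k], the per-tree interventional Shapley
    values summed over background rows (caller divides by n_bg)."""
    n_val = Xv.shape[0]
    n_bg = bg.shape[0]
    n_out = leaf_values.shape[1]

    stack_node = np.empty(_STACK_CAP, np.int64)
    stack_nc = np.empty(_STACK_CAP, np.int64)
    stack_feats = np.empty((_STACK_CAP, _MAX_CONSTRAINTS), np.int64)
    stack_kind = np.empty((_STACK_CAP, _MAX_CONSTRAINTS), np.uint8)
    cur_feats = np.empty(_MAX_CONSTRAINTS, np.int64)
    cur_kind = np.empty(_MAX_CONSTRAINTS, np.uint8)

    for v in range(n_val):
        x = Xv[v]
        for b_i in range(n_bg):
            b = bg[b_i]
            top = 0
            stack_node[0] = 0
            stack_nc[0] = 0
            while top >= 0:
                node = stack_node[top]
                nc = stack_nc[top]
                for t in range(nc):
                    cur_feats[t] = stack_feats[top, t]
                    cur_kind[t] = stack_kind[top, t]
                top -= 1

                if feature[node] < 0:  # leaf
                    u = 0
                    w = 0
                    for t in range(nc):
                        if cur_kind[t] == 1:
                            u += 1
                        else:
                            w += 1
                    if u + w == 0:
                        continue
                    c_u = 0.0
                    c_w = 0.0
                    if u > 0:
                        c_u = fact[u - 1] * fact[w] / fact[u + w]
                    if w > 0:
                        c_w = fact[u] * fact[w - 1] / fact[u + w]
                    for t in range(nc):
                        f = cur_feats[t]
                        if cur_kind[t] == 1:
                            for o in range(n_out):
                                phi[v, f, o] += c_u * leaf_values[node, o]
                        else:
                            for o in range(n_out):
                                phi[v, f, o] -= c_w * leaf_values[node, o]
                    continue

                j = feature[node]
                go_left_x = x[j] <= threshold[node]
                go_left_b = b[j] <= threshold[node]
                constraint = -1
                for t in range(nc):
                    if cur_feats[t] == j:
                        constraint = cur_kind[t]
                        break

                if constraint == 1 or (constraint == -1 and go_left_x == go_left_b):
                    child = left[node] if go_left_x else right[node]
                    top += 1
                    stack_node[top] = child
                    stack_nc[top] = nc
                    for t in range(nc):
                        stack_feats[top, t] = cur_feats[t]
                        stack_kind[top, t] = cur_kind[t]
                elif constraint == 0:
                    child = left[node] if go_left_b else right[node]
                    top += 1
                    stack_node[top] = child
                    stack_nc[top] = nc
                    for t in range(nc):
                        stack_feats[top, t] = cur_feats[t]
                        stack_kind[top, t] = cur_kind[t]
                else:
                    # paths diverge on an unconstrained feature: branch
                    for kind in (1, 0):
                        go_left = go_left_x if kind == 1 else go_left_b
                        child = left[node] if go_left else right[node]
                        top += 1
                        stack_node[top] = child
                        stack_nc[top] = nc + 1
                        for t in range(nc):
                            stack_feats[top, t] = cur_feats[t]
                            stack_kind[top, t] = cur_kind[t]
                        stack_feats[top, nc] = j
                        stack_kind[top, nc] = kind


@dataclass
class ShapTensor:
    """Per-sample attributions phi[v, i, k] plus the background baseline."""

    values: np.ndarray  # (n_validation, n_kdt, n_circuits)
    baseline: np.ndarray  # (n_circuits,)
    sample_ids: list[str]
    feature_ids: list[str]
    output_ids: list[str]


@dataclass
class RelevanceMatrix:
    """Signed relevance of every KDT for every circuit (pre-selection).

    ``magnitude`` is the mean absolute attribution over validation samples;
    ``sign`` (+1/0/-1) is the direction of influence, taken from the
    correlation between a KDT's expression and its attributions.
    """

    magnitude: pd.DataFrame  # (n_kdt, n_circuits), >= 0
    sign: pd.DataFrame  # entries in {-1, 0, +1}

    @property
    def signed_relevance(self) -> pd.DataFrame:
        return self.magnitude * self.sign


def split_background_validation(
    sample_ids: list[str] | pd.Index, fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic disjoint, exhaustive split; the background receives
    ceil(fraction * n) samples."""
    ids = [str(s) for s in sample_ids]
    if len(ids) < 4:
        raise ConfigurationError(f"need >= 4 samples to split, got {len(ids)}")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError(f"fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    cut = int(math.ceil(fraction * len(ids)))
    background = [ids[i] for i in perm[:cut]]
    validation = [ids[i] for i in perm[cut:]]
    return background, validation


def _subsample_background(bg: np.ndarray, n: int, seed: int) -> np.ndarray:
    if bg.shape[0] <= n:
        return bg
    rng = np.random.default_rng(seed)
    idx = rng.choice(bg.shape[0], size=n, replace=False)
    return bg[idx]


def shap_attributions(
    model: MorfModel,
    background: pd.DataFrame,
    validation: pd.DataFrame,
    background_subsample: int = 1000,
    seed: int = 0,
) -> ShapTensor:
    """Exact interventional Shapley attributions for every validation
    sample, integrated over a deterministic background subsample."""
    for df in (background, validation):
        missing = [f for f in model.feature_ids if f not in set(map(str, df.columns))]
        if missing:
            raise AlignmentError(f"feature column(s) missing: {missing[:5]}")
    bg = background[model.feature_ids].to_numpy(dtype=np.float64)
    Xv = validation[model.feature_ids].to_numpy(dtype=np.float64)
    bg = _subsample_background(bg, background_subsample, seed)

    n_val, n_feat = Xv.shape
    n_out = model.n_outputs
    phi = np.zeros((n_val, n_feat, n_out), dtype=np.float64)
    fact = np.array([math.factorial(i) for i in range(_MAX_CONSTRAINTS + 1)], dtype=np.float64)

    trees = model.trees()
    for tree in trees:
        _tree_interventional_shap(
            tree.feature,
            tree.threshold,
            tree.children_left,
            tree.children_right,
            tree.leaf_values,
            Xv,
            bg,
            fact,
            phi,
        )
    phi /= bg.shape[0] * len(trees)
    baseline = model.predict_array(bg).mean(axis=0)
    return ShapTensor(
        values=phi,
        baseline=baseline,
        sample_ids=[str(s) for s in validation.index],
        feature_ids=list(model.feature_ids),
        output_ids=list(model.output_ids),
    )


def shap_oracle(
    model: MorfModel, background: np.ndarray, x: np.ndarray, max_features: int = 15
) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration (test oracle).

    Enumerates every subset S of features, evaluates the background-mean
    hybrid value function, and combines marginal contributions with the
    standard |S|! (|F|-|S|-1)! / |F|! weights.  Exponential: guarded to
    ``max_features`` features.  Returns (n_features, n_outputs).
    """
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    x = np.asarray(x, dtype=np.float64).ravel()
    n_feat = x.shape[0]
    if n_feat > max_features:
        raise FeatureGuardError(
            f"oracle enumeration guarded to {max_features} features, got {n_feat}"
        )
    n_bg = background.shape[0]
    n_sub = 1 << n_feat

    # value function for every coalition mask
    hybrids = np.repeat(background[None, :, :], n_sub, axis=0)  # (n_sub, n_bg, n_feat)
    for i in range(n_feat):
        masks = (np.arange(n_sub) >> i) & 1
        hybrids[masks == 1, :, i] = x[i]
    flat = hybrids.reshape(n_sub * n_bg, n_feat)
    preds = model.predict_array(flat).reshape(n_sub, n_bg, -1).mean(axis=1)  # (n_sub, n_out)

    fact = np.array([math.factorial(i) for i in range(n_feat + 1)], dtype=np.float64)
    phi = np.zeros((n_feat, preds.shape[1]), dtype=np.float64)
    sizes = np.array([bin(m).count("1") for m in range(n_sub)])
    for i in range(n_feat):
        bit = 1 << i
        for mask in range(n_sub):
            if mask & bit:
                continue
            s = sizes[mask]
            weight = fact[s] * fact[n_feat - s - 1] / fact[n_feat]
            phi[i] += weight * (preds[mask | bit] - preds[mask])
    return phi


def signed_relevance(shap: ShapTensor, validation: pd.DataFrame) -> RelevanceMatrix:
    """Reduce per-sample attributions to the signed relevance matrix.

    magnitude[i, k] = mean_v |phi[v, i, k]|; sign[i, k] is the sign of the
    Pearson correlation between the KDT's expression across validation
    samples and its attributions (0 when undefined or magnitude is 0).
    """
    ids = [str(s) for s in validation.index]
    if ids != shap.sample_ids:
        raise AlignmentError("validation rows do not match the attribution tensor samples")
    phi = shap.values
    Xv = validation[shap.feature_ids].to_numpy(dtype=np.float64)
    magnitude = np.abs(phi).mean(axis=0)  # (n_kdt, n_circuits)

    n_val = phi.shape[0]
    if n_val < 2:
        warnings.warn("single validation sample: relevance signs are undefined (0)", stacklevel=2)
        sign = np.zeros_like(magnitude)
    else:
        xc = Xv - Xv.mean(axis=0)  # (v, i)
        pc = phi - phi.mean(axis=0)  # (v, i, k)
        cov = np.einsum("vi,vik->ik", xc, pc)
        sign = np.sign(cov)
    sign[magnitude == 0] = 0.0

    mag = pd.DataFrame(magnitude, index=shap.feature_ids, columns=shap.output_ids)
    sgn = pd.DataFrame(sign, index=shap.feature_ids, columns=shap.output_ids)
    return RelevanceMatrix(magnitude=mag, sign=sgn)
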