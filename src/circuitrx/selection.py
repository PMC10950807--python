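"""KDT selection, per-circuit scoring and stability validation.

Per circuit, prediction quality is the coefficient of determination R²
(range (-inf, 1]; 0 for the column-mean predictor).  KDTs are selected per
circuit by a quantile gate on the mean absolute attribution: circuits whose
R² falls below the threshold select nothing ("ill-modeled circuits result
in fewer relevant genes"), otherwise every KDT whose magnitude reaches the
q-th quantile (linear interpolation, ties included) is kept.  Element-wise
multiplication of the signed relevance with the binary indicator yields the
repurposing profile S'.

Selection consistency across resampled runs is quantified with the
Nogueira stability estimator, a variance-based index in (-inf, 1] that is
1 only when every run selects the identical (non-degenerate) set and 0 in
expectation under independent random selection.  The bootstrap harness
repeats split/fit/score/select over seeded resamples and reports per-circuit
point estimates with 95% confidence intervals (percentile for R²,
asymptotic-normal for stability) plus a map-wise average row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigurationError
from .explain import RelevanceMatrix, shap_attributions, signed_relevance, split_background_validation
from .morf import MorfHyperparams, MorfModel, fit_morf, predict_morf

DEFAULT_R2_THRESHOLD = 0.5
DEFAULT_QUANTILE_THRESHOLD = 0.95
DEFAULT_N_SPLITS = 100
MAP_AVERAGE_LABEL = "map_average"

SCORE_COLUMNS = ["r2_point", "r2_lo", "r2_hi", "stability_point", "stability_lo", "stability_hi"]


def r2_per_output(Y_true: pd.DataFrame, Y_pred: pd.DataFrame) -> pd.Series:
    """Per-circuit R² = 1 - SS_res / SS_tot (SS_tot about the observed
    mean).  Zero-variance truth columns are undefined (NaN) with a warning."""
    if Y_true.shape != Y_pred.shape:
        raise AlignmentError(
            f"shape mismatch: truth {Y_true.shape} vs prediction {Y_pred.shape}"
        )
    yt = Y_true.to_numpy(dtype=np.float64)
    yp = Y_pred[Y_true.columns].to_numpy(dtype=np.float64)
    ss_res = ((yt - yp) ** 2).sum(axis=0)
    ss_tot = ((yt - yt.mean(axis=0)) ** 2).sum(axis=0)
    out = np.full(yt.shape[1], np.nan)
    ok = ss_tot > 0
    out[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    if not ok.all():
        bad = list(Y_true.columns[~ok])
        warnings.warn(f"zero-variance circuit(s), R2 undefined: {bad[:5]}", stacklevel=2)
    return pd.Series(out, index=Y_true.columns)


def select_kdts(
    relevance: RelevanceMatrix,
    r2: pd.Series,
    q_th: float = DEFAULT_QUANTILE_THRESHOLD,
    r2_th: float = DEFAULT_R2_THRESHOLD,
) -> pd.DataFrame:
    """Binary KDT-by-circuit indicator matrix Z.

    Circuit k selects nothing if R²_k < r2_th (or is undefined); otherwise
    KDTs with magnitude >= the q_th linear-interpolation quantile of that
    circuit's magnitudes (ties at the threshold included).
    """
    if not 0.0 < q_th < 1.0:
        raise ConfigurationError(f"q_th must lie in (0, 1), got {q_th}")
    mag = relevance.magnitude
    Z = pd.DataFrame(0, index=mag.index, columns=mag.columns, dtype=int)
    for circuit in mag.columns:
        score = r2.get(circuit, np.nan)
        if not np.isfinite(score) or score < r2_th:
            continue
        col = mag[circuit].to_numpy()
        threshold = np.quantile(col, q_th)  # linear interpolation
        Z[circuit] = (col >= threshold).astype(int)
    return Z


def apply_selection(relevance: RelevanceMatrix, Z: pd.DataFrame) -> pd.DataFrame:
    """Repurposing profile S' = signed_relevance ∘ Z (element-wise mask)."""
    signed = relevance.signed_relevance
    if signed.shape != Z.shape:
        raise AlignmentError(f"shape mismatch: relevance {signed.shape} vs indicator {Z.shape}")
    return signed * Z.to_numpy() + 0.0  # +0.0 normalizes -0.0 cells


def nogueira_stability(Z_stack: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Nogueira stability of a (runs x features) binary selection stack.

    estimate = 1 - mean_f(s_f^2) / ((kbar/d)(1 - kbar/d)) with s_f^2 the
    unbiased selection variance of feature f across runs and kbar the mean
    number selected per run.  The confidence interval uses the estimator's
    asymptotic-normal (influence-function) variance; the upper bound is
    clipped at 1, the estimator's range.  Degenerate stacks (nothing or
    everything selected on average) are undefined: returns NaNs.
    """
    Z = np.asarray(Z_stack, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ConfigurationError("stability needs a 2-D stack with >= 2 runs")
    M, d = Z.shape
    p = Z.mean(axis=0)
    k = Z.sum(axis=1)
    kbar = k.mean()
    if kbar == 0 or kbar == d:
        warnings.warn("degenerate selections (none or all features): stability undefined",
                      stacklevel=2)
        return (math.nan, math.nan, math.nan)
    denom = (kbar / d) * (1.0 - kbar / d)
    s2 = M / (M - 1.0) * p * (1.0 - p)
    A = s2.mean()
    estimate = 1.0 - A / denom

    # delta-method variance via per-run influence values
    alpha_i = (M / (M - 1.0)) * ((Z - p) @ (1.0 - 2.0 * p)) / d
    beta_i = (1.0 - 2.0 * kbar / d) * (k - kbar) / d
    psi = -alpha_i / denom + (A / denom**2) * beta_i
    se = math.sqrt(psi.var(ddof=1) / M) if M > 1 else math.nan
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    lo = estimate - z_crit * se
    hi = min(1.0, estimate + z_crit * se)
    return (float(estimate), float(lo), float(hi))


@dataclass
class BootstrapResult:
    """Everything the resampling harness measured."""

    scores: pd.DataFrame  # ScoreTable: circuits + map_average row x SCORE_COLUMNS
    Z_stack: np.ndarray  # (n_runs, n_kdt, n_circuits)
    r2_runs: pd.DataFrame  # (n_runs, n_circuits)
    feature_ids: list[str]
    output_ids: list[str]


def _one_run(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    hp: MorfHyperparams,
    run_seed: int,
    q_th: float,
    r2_th: float,
    train_fraction: float,
    background_subsample: int,
) -> tuple[np.ndarray, np.ndarray]:
    bg_ids, val_ids = split_background_validation(X.index, train_fraction, run_seed)
    hp_run = MorfHyperparams(
        n_trees=hp.n_trees,
        max_depth=hp.max_depth,
        max_features_per_split=hp.max_features_per_split,
        random_seed=run_seed,
    )
    model = fit_morf(X.loc[bg_ids], Y.loc[bg_ids], hp_run)
    pred = predict_morf(model, X.loc[val_ids])
    r2 = r2_per_output(Y.loc[val_ids], pred)
    shap = shap_attributions(
        model, X.loc[bg_ids], X.loc[val_ids], background_subsample=background_subsample,
        seed=run_seed,
    )
    relevance = signed_relevance(shap, X.loc[val_ids])
    Z = select_kdts(relevance, r2, q_th=q_th, r2_th=r2_th)
    return r2.to_numpy(), Z.to_numpy()


def bootstrap_evaluate(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_splits: int = DEFAULT_N_SPLITS,
    hp: MorfHyperparams | None = None,
    q_th: float = DEFAULT_QUANTILE_THRESHOLD,
    r2_th: float = DEFAULT_R2_THRESHOLD,
    seed: int = 0,
    train_fraction: float = 0.75,
    background_subsample: int = 1000,
    n_cpus: int = 1,
) -> BootstrapResult:
    """Resampling validation of the whole select-and-score procedure.

    Each run draws a fresh seeded 75/25 background/validation split, fits
    the MORF on the background, scores per-circuit R² on the validation
    samples, computes attributions and the per-run selection.  Reports the
    per-circuit R² mean with a percentile 95% CI over runs, the per-circuit
    Nogueira stability of the selection stack with its asymptotic CI, and a
    map-wise average row.  Deterministic given ``seed``.
    """
    if n_splits < 2:
        raise ConfigurationError("bootstrap evaluation needs n_splits >= 2")
    hp = (hp or MorfHyperparams()).resolve(X.shape[1])
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_splits)

    def _safe(run_seed: int):
        try:
            return _one_run(X, Y, hp, int(run_seed), q_th, r2_th,
                            train_fraction, background_subsample)
        except Exception as exc:  # degenerate resample
            warnings.warn(f"bootstrap run failed and was skipped: {exc}", stacklevel=2)
            return None

    if n_cpus == 1:
        results = [_safe(s) for s in run_seeds]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_cpus)(delayed(_safe)(s) for s in run_seeds)

    kept = [r for r in results if r is not None]
    if len(kept) < 0.8 * n_splits:
        raise ConfigurationError(
            f"{n_splits - len(kept)}/{n_splits} bootstrap runs failed; data too degenerate"
        )

    r2_runs = np.stack([r[0] for r in kept])  # (M, n_circuits)
    Z_stack = np.stack([r[1] for r in kept])  # (M, n_kdt, n_circuits)

    rows = {}
    for ci, circuit in enumerate(Y.columns):
        r2_c = r2_runs[:, ci]
        finite = r2_c[np.isfinite(r2_c)]
        if finite.size:
            r2_point = float(finite.mean())
            r2_lo, r2_hi = (float(v) for v in np.percentile(finite, [2.5, 97.5]))
        else:
            r2_point = r2_lo = r2_hi = math.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s_point, s_lo, s_hi = nogueira_stability(Z_stack[:, :, ci])
        rows[str(circuit)] = [r2_point, r2_lo, r2_hi, s_point, s_lo, s_hi]

    scores = pd.DataFrame.from_dict(rows, orient="index", columns=SCORE_COLUMNS)
    scores.loc[MAP_AVERAGE_LABEL] = scores.mean(axis=0, skipna=True)
    scores.index.name = "circuit"
    return BootstrapResult(
        scores=scores,
        Z_stack=Z_stack,
        r2_runs=pd.DataFrame(r2_runs, columns=[str(c) for c in Y.columns]),
        feature_ids=[str(c) for c in X.columns],
        output_ids=[str(c) for c in Y.columns],
    )


def final_fit(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    hp: MorfHyperparams | None = None,
    q_th: float = DEFAULT_QUANTILE_THRESHOLD,
    r2_th: float = DEFAULT_R2_THRESHOLD,
    r2_gate: pd.Series | None = None,
    seed: int = 0,
    train_fraction: float = 0.75,
    background_subsample: int = 1000,
) -> tuple[pd.DataFrame, RelevanceMatrix, MorfModel]:
    """One final fit on a fresh split yielding the reported S'.

    The R² gate defaults to the final fit's own validation scores; passing
    ``r2_gate`` (e.g. the bootstrap point estimates) gates the selection on
    validated predictability instead.  Returns (S', relevance, model).
    """
    hp = (hp or MorfHyperparams()).resolve(X.shape[1])
    bg_ids, val_ids = split_background_validation(X.index, train_fraction, seed)
    model = fit_morf(X.loc[bg_ids], Y.loc[bg_ids], hp)
    pred = predict_morf(model, X.loc[val_ids])
    r2 = r2_per_output(Y.loc[val_ids], pred)
    if r2_gate is not None:
        r2 = r2_gate
    shap = shap_attributions(
        model, X.loc[bg_ids], X.loc[val_ids], background_subsample=background_subsample,
        seed=seed,
    )
    relevance = signed_relevance(shap, X.loc[val_ids])
    Z = select_kdts(relevance, r2, q_th=q_th, r2_th=r2_th)
    sprime = apply_selection(relevance, Z)
    return sprime, relevance, model
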