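# Methods

## The model

`circuitrx` prioritizes known drug targets (KDTs) for a disease by learning
the map from KDT gene expression to mechanistic signaling-circuit activity
and then attributing that map back to individual targets.

Given a normalized expression matrix **X** (samples × KDT genes, Entrez
identifiers) and a circuit-activity matrix **Y** (samples × circuits,
produced upstream by a signal-propagation method and consumed here as
input), the procedure is:

1. **Split** the samples into a *background* set (default 75%, seeded) used
   to fit the model and integrate attribution expectations, and a
   *validation* set on which attributions are computed.
2. **Fit** a multi-output random forest (MORF): an ensemble of regression
   trees whose leaves hold one value per circuit and whose splits minimize
   the squared error summed over all circuits. The multi-output criterion
   regularizes splits toward features informative across the map.
3. **Explain** the fitted forest with interventional Shapley values: for
   validation sample *x* and coalition *S*, the value function is
   f_x(S) = E_b[ f(x_S, b_{S̄}) ], the model applied to hybrid points taking
   features in *S* from *x* and the rest from background rows *b*. The
   Shapley value φ_{ik} of KDT *i* for circuit *k* combines marginal
   contributions over all coalitions with the standard
   |S|!(p−|S|−1)!/p! weights, p the number of features.
4. **Reduce** to a signed relevance matrix: magnitude is the mean absolute
   attribution over validation samples; the sign is the direction of
   influence, taken as the sign of the correlation between a KDT's
   expression and its per-sample attributions (a sign of the mean
   attribution would vanish for symmetric effects; the correlation rule
   does not).
5. **Select** per circuit: circuits with validation R² below a threshold
   select nothing; otherwise KDTs whose magnitude reaches the per-circuit
   quantile threshold (linear-interpolation convention, ties at the
   threshold included) are kept. The element-wise product of the signed
   relevance with the binary indicator is the repurposing profile **S′**
   (KDTs × circuits).

### Exact interventional attribution

For a single tree and a single (x, b) pair, the coalitional game
decomposes over leaves: a leaf is reached by the hybrid point iff every
path feature on which x and b diverge is configured correctly, so each
leaf defines an AND/NOT unanimity game with "must come from x" set U and
"must come from b" set W. Its Shapley contribution is available in closed
form — +(|U|−1)!|W|!/(|U|+|W|)! · leaf value for i∈U and
−|U|!(|W|−1)!/(|U|+|W|)! · leaf value for i∈W; features the paths agree
on are exact dummies. One depth-first traversal per (x, b) pair
accumulates these terms (numba-compiled); averaging over background rows
and trees gives the forest attribution. The computation is exact: it
satisfies local accuracy Σᵢφᵢ = f(x) − E_b[f(b)] to machine precision and
is tested against a brute-force coalition-enumeration oracle (guarded to
≤ 15 features) on randomized forests.

The background is subsampled to at most 1000 rows (seeded, without
replacement) before integration; validation sets at the scales used here
are explained in full.

## Validation: resampled R² and selection stability

The whole select-and-score procedure is validated by repeated resampling
(default 100 runs; each run draws a fresh seeded 75/25 split, fits on the
background part, scores per-circuit R² on the held-out part, and computes
that run's selection). Reported per circuit and as a map-wise average:

- **R²** = 1 − SS_res/SS_tot: point estimate is the mean over runs, 95% CI
  the (2.5, 97.5) percentiles over runs. R² is 0 for the column-mean
  predictor and 1 for a perfect one; zero-variance circuits are flagged
  undefined rather than scored.
- **Nogueira stability** of the selection stack Z (runs × KDTs, per
  circuit): Φ = 1 − (d⁻¹Σ_f s_f²) / ((k̄/d)(1−k̄/d)), with s_f² the
  unbiased between-run variance of feature f's selection indicator and k̄
  the mean number selected. Φ = 1 iff all runs select the identical
  non-degenerate set; Φ has expectation 0 under independent random
  selection. The 95% CI uses the estimator's asymptotic-normal variance
  obtained by the delta method on per-run influence values; the upper
  bound is clipped at 1, the estimator's range. Degenerate stacks
  (nothing/everything selected) are undefined. Stability bands follow the
  usual effect sizes: poor (s ≤ 0.4), mid (0.4 < s < 0.75), excellent
  (s ≥ 0.75).

The final reported S′ comes from one additional fit on a fresh split with
the full configuration; its selection is gated on the bootstrap R² point
estimates rather than the final split's own R², so the gate reflects
validated predictability rather than one split's luck.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 200 | trees in the forest |
| `max_depth` | 8 | depth bound per tree |
| `max_features_per_split` | ⌈√n_kdt + 20⌉, capped at n_kdt | candidate features per node |
| `q_th` | 0.95 | per-circuit relevance quantile for selection |
| `r2_th` | 0.5 | per-circuit R² gate |
| `background_subsample` | 1000 | background rows integrated per attribution |
| `n_splits` | 100 | resampling runs in the validation harness |
| split fraction | 0.75 | background share of each split |
| imputation `k` | 5 | neighbours for kNN imputation |

Missing expression values are imputed before fitting with kNN imputation
(column mean over the k nearest rows; distances ignore missing dimensions
and are rescaled by the fraction observed). Hyperparameter tuning, when
requested (`--n-iters > 0`), runs successive halving over
{max_depth, max_features_per_split} with the tree count as the elimination
resource (minimum 10 trees, elimination factor 3, scored by mean
per-output R² on an internal 75/25 split); the winner is refit with the
production tree count.

The `activity_normalizer` flag applies a per-circuit min–max rescaling of
the activity matrix to [0, 1]; upstream producers that emit
length-normalized activities can leave it off.

## What the synthetic generator emulates — and what it does not

The generator plants a known truth: each circuit's activity is a weighted
sum (or thresholded sum) of a small driver set of KDTs plus Gaussian noise
(driver weights |w| ∈ [0.5, 1.5] with random signs, noise σ = 0.3 by
default — roughly a tenth of the signal variance for three drivers, i.e. a
clearly learnable but not noiseless regime). Expression is i.i.d. standard
normal per gene: the method consumes *normalized* expression, so
count-distribution realism is deliberately not simulated. Drivers may
overlap across circuits, as pleiotropic targets do in real maps.

Passing tests on these fixtures demonstrates the machinery — recovery of
planted drivers, calibrated selection stability, correct attribution — not
performance on real cohorts: real expression is correlated, batch-affected
and non-Gaussian, and real circuit activities are deterministic functions
of expression subsets rather than noisy linear sums.

A scale note on the recovery checks: the acceptance-level recovery run
uses 500 samples, 50 KDTs, 5 circuits with 3 drivers each and 25
resampling runs — sizes at which the full procedure (forest fits plus
exact attribution) completes in minutes on one CPU while leaving the
selection problem non-trivial (q_th = 0.95 over 50 KDTs admits ≈ 3
selections per circuit, matched to the planted driver count by
construction of the protocol, not by tuning).

One interaction worth knowing: bounded-depth forests are piecewise
constant, so even noiseless additive signals are not fit perfectly — with
3 drivers per circuit the held-out R² of the default learner plateaus
near 0.87, with 2 drivers above 0.94. The noiseless "sanity ceiling" test
therefore uses a 2-driver fixture; the noisy 3-driver recovery conditions
are unaffected.

## Numerical choices and degenerate inputs

- Quantile convention: linear interpolation between order statistics;
  ties at the threshold are selected.
- Selection with all-equal magnitudes selects everything (every value
  ties the quantile).
- R² with zero-variance truth, stability with degenerate selections, and
  relevance signs with a single validation sample are all *undefined*
  (NaN / sign 0) with a warning, never silently zero or one.
- Bootstrap runs that fail on degenerate resamples are skipped with a
  warning; more than 20% skipped aborts the evaluation.
- Background/validation splitting assigns ⌈fraction·n⌉ samples to the
  background; all splits, subsamples and fits are seeded, and a fixed seed
  reproduces result files byte for byte.
- TSV round trips preserve values to full float precision; missing cells
  are written as empty fields and read from empty or literal `NA`.

## Design choices where the design was open

- **Route priority** when several map sources are configured:
  explicit circuits > disease identifier > seed genes, with a warning
  (arbitration, not union).
- **Gene-disease score threshold** defaults to 0.0 (all curated
  associations) and is exposed as a parameter; 0.3 is a common stricter
  choice.
- **Sign rule** for S′: correlation of expression with attribution (see
  above).
- **Resampling scheme**: fresh 75/25 splits per run (the stability
  protocol requires multiple runs over perturbed datasets; subsampling
  splits are the standard way to get them).
- **Per-circuit display scaling** in the heatmap divides by the row's
  max |S′| (symmetric about 0), so every displayed row touches ±1 and
  sign structure is preserved; circuits whose stability CI lower bound is
  below 0.4 are excluded, as are all-zero rows/columns.
- **Drug aggregation** sums (not averages) target rows, preserving
  additivity with the ℓ1 ranking; the per-(drug, pathway) view sums over
  the stable circuits only. Hierarchical clustering in the heatmap
  (correlation distance, average linkage) is cosmetic.

## Known limitations

- **Multi-output dilution on unrelated circuits.** A MORF tree's splits
  must serve every circuit simultaneously, which is efficient when
  circuits share signal (the normal situation inside a disease map) and
  wasteful when they do not. On synthetic maps whose circuits have
  disjoint driver sets, per-circuit held-out R² drops well below what
  per-circuit forests would achieve (we measure ≈ 0.3–0.6 versus
  0.83–0.88 for five disjoint-driver circuits over 50 KDTs, while one or
  two circuits — or five circuits sharing one driver set — recover their
  drivers perfectly with R² 0.72–0.88). Circuits diluted below the R²
  gate select nothing, by design. Practitioners analyzing maps of
  weakly-related circuits should expect conservative selections; the
  single-model-for-the-whole-map design is intrinsic to the method.
- Attribution cost grows with background × validation × leaves; very
  large cohorts should lower `background_subsample` or batch validation
  samples. No GPU path is provided.
- The stability CI is asymptotic in the number of runs; with few runs
  (< ~20) it is wide and the plot-level stability filter may legitimately
  hide everything.
- Circuit construction consumes a prepared circuit→gene table; pathway
  topology parsing and activity inference belong to upstream tools.
- The disease-identifier route requires a local gene-disease association
  table; no remote database is queried.
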