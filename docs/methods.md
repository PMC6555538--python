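# Methods

## Model

`dsfa` fits a sparse discriminative factor model to a drug-by-cell-line
sensitivity matrix `Y` (D×N, continuous scores such as active area, missing
entries allowed) and a feature-by-cell-line matrix `F` (P×N):

```
Y = G X + ε,   ε_dn ~ N(0, 1/λ_d)        (per-drug noise)
X = B F + w,   w_kn ~ N(0, 1/λ'_k)       (per-LC noise)
```

The latent characteristics (LCs) `X` are shared across drugs, so statistical
strength is pooled over the panel (multitask prediction), and they are
regressed on the genomic features, so the model is predictive for cell lines
never screened.  The assumptions worth keeping in mind:

* **Linearity and Gaussianity** throughout; heavy-tailed response scores
  should be transformed before fitting.
* **Exact sparsity** in both coefficient matrices via spike-and-slab priors
  with a unit-variance slab.  The unit slab is a scale convention, not a
  restriction, because rows of `Y` and continuous rows of `F` are z-scored
  internally (see Preprocessing).
* **Diagonal noise**: one precision per drug and one per LC, with
  hierarchical priors `λ | b ~ Gamma(shape 1, scale 1/b)`, `b ~ Gamma(1, 1)`.
  The shape/scale reading makes the conditional of `b` conjugate
  (`b | λ ~ Gamma(1 + D, rate 1 + Σλ)`), so every variable admits a standard
  Gibbs update.  Per-entry precisions would be unidentifiable without
  replicate measurements, so precisions are indexed by drug (row), not entry.
* **Finite-truncation IBP** on the drug-by-LC support `Z`:
  `v_k ~ Beta(α/K, 1)`, `Z_dk ~ Bernoulli(v_k)` with `K = k_max` columns.
  The truncation (rather than unbounded IBP moves) is required by the MRF
  extension, which needs an explicit inclusion rate `v_k` per column.  Empty
  columns cost O(1) per sweep, are never deleted, and can be re-born, so the
  *active* LC count remains data-driven; the fit logs a warning if it ever
  reaches `k_max`.  Left-ordering of the columns is not implemented: it
  matters only for the measure-theoretic construction of the IBP limit, and
  LC labels are arbitrary.
* **Missing `Y` entries** are excluded from every likelihood and sufficient
  statistic.  This is exact because the diagonal noise factorizes the
  likelihood over entries.  Each drug and each cell line must retain at
  least one observation.

### MRF coupling

Prior knowledge about related drugs (shared inhibition targets) or related
features (same gene) enters as a pairwise Markov random field.  The
unnormalized log prior of a column `Z_:k` gains
`Σ_{(d′,d)∈E} w_{d′d} Z_{d′k} Z_{dk}`; the analogous term applies to rows of
`V` over the feature graph.  Only differences of this quantity are ever
used (Gibbs flip odds, trace diagnostics), so the partition function —
constant for a fixed graph — is never computed.  The conjugate Beta updates
for `v` and `π` are unaffected because the MRF terms do not involve them.
Graphs whose edges all carry zero weight are normalized to "no graph" before
sampling, so a zero-weight graph reproduces the uncoupled chain bit for bit.

## Inference

Standard Gibbs sampling with the scan order

```
X  →  (Z, G)  →  X  →  (V, B)  →  (v, π)  →  (λ_y, b_y, λ_x, b_x)
```

* `(Z_dk, G_dk)` and `(V_kp, B_kp)` are updated jointly with the coefficient
  integrated out against the slab: the flip log-odds are the prior log-odds
  (including the MRF neighbour sum) plus the log Bayes factor
  `A²/(2s) − log(s)/2`, `A = λ Σ x·r`, `s = 1 + λ Σ x²`, computed on the
  partial residual; the active coefficient is then drawn from N(A/s, 1/s).
  Within a `Z` column the drugs are conditionally independent given the rest
  unless a drug graph is present, in which case they are scanned
  sequentially; rows of `V` are always conditionally independent across LCs
  and are updated as a block per feature.
* Each column `X_:n` has an exact multivariate Gaussian conditional with
  precision `diag(λ') + Gᵀ diag(λ ⊙ mask) G`; with no missing data one
  Cholesky factorization serves all N columns.
* `X` is refreshed twice per sweep — once before the loadings block and once
  before the regression block.  Any fixed scan order of exact conditionals
  is a valid Gibbs sampler; the extra refresh lets `X` re-align with the
  just-updated loadings before the feature supports are resampled, and in
  recovery experiments it roughly halves the rate at which chains linger in
  merged/rotated factor modes at a ~20% cost per sweep.
* Initialization is an over-dispersed draw from the prior (supports and
  coefficients from their priors, `X = BF` plus unit noise) with all
  precisions at 1.  A prior draw is also what the Geweke consistency check
  requires.
* Default schedule: 10,000 sweeps, first half discarded, 1-in-10 thinning.
  Fixed seeds make runs bit-reproducible.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1.0 | IBP concentration; prior E[#active LCs] ≈ α·H_D (≈3.6 at D=20).  α=2 roughly doubles the prior active count and, in recovery experiments at the defaults below, over-fragments the support. |
| `beta` | 0.01·P | feature-sparsity concentration; `π_p ~ Beta(β/P, 1)` so the prior inclusion rate parameter is 0.01 per feature regardless of P. |
| `k_max` | 50 | truncation level; choose comfortably above the expected active count (the recovery experiments use 10 against 3 true LCs). |
| `mrf_weight` | 1.0 | edge weight used when building relation graphs. |

α and β are fixed, not sampled.

### Preprocessing and prediction

`fit()` aligns cell lines by label, z-scores each `Y` row and each
continuous `F` row on training data only (binary mutation rows pass
through), and stores the transforms on the returned trace.  Predictions for
new cell lines apply the stored feature transform, average `G·B·F_new` over
all post-burn-in snapshots (label-invariant, so no alignment of LCs across
snapshots is needed), and invert the response transform.  Point predictions
only; posterior uncertainty on predictions is not reported.

For interpretation (`lc_association_table`) the trace is summarized by its
maximum-log-joint snapshot instead, because LC labels are *not* aligned
across snapshots; for each active LC the table tests every selected
(drug, feature) pair by Spearman rank correlation over that drug's observed
cell lines, with the two-sided t-approximation p-value and optional
Benjamini–Hochberg adjustment.

## Evaluation protocol

* **Cross-validation** holds out *cell lines* (columns), 10 folds by seeded
  shuffle, sizes differing by at most one; standardization statistics are
  recomputed inside each training fold, so held-out columns never leak into
  preprocessing.  Each fold's sampler is seeded with `cfg.seed + fold_id`.
* **PVE** is pooled over all observed held-out entries:
  `1 − SS_res/SS_tot`, with the per-drug training mean as the null
  prediction.  Pooling (rather than averaging per-drug PVEs) weights drugs
  by their held-out variance; both views can be computed from the per-fold
  outputs.  PVE may be negative.
* **Concordance index** per drug over held-out cell lines: pairs tied in the
  observations are excluded, tied predictions score 1/2.
* **Active area** summarizes a dose-response curve as the trapezoidal
  integral of `max(0, 1 − viability)` over log10 dose (units: inhibition ×
  dose-decades).  It is defined even when 50% inhibition is never reached
  (where an IC50 would not be), and clipping at zero means super-viability
  cannot produce negative area.  Doses must be positive and strictly
  increasing; unit conversion is the caller's responsibility.

## Synthetic data

`simulate.generate` draws from the model's own generative process: features
i.i.d. standard normal with a configurable fraction of rows thresholded at
the 90th percentile into rare binary mutation-like features; fixed-size LC
supports drawn without replacement (default 5 drugs and 4 features per LC —
identifiable, interpretable ground truth; a Bernoulli-density mode is also
available); unit-variance slab coefficients; Gaussian noise at configurable
precisions.  Default conditions: D=20 drugs, N=300 cell lines, P=40
features, K_true=3, both noise precisions 25 (noise sd 0.2 against
unit-scale signal).  The drug graph links drugs sharing a true LC (standing
in for shared inhibition targets); the feature graph links features grouped
into synthetic genes of 1–3 features.

What the generator does **not** emulate: correlated expression programs,
batch effects, dose-response measurement error (only the active-area
summary), heavy-tailed responses, and the ~1000-fold larger feature spaces
of real screens.  Passing recovery tests therefore demonstrate correctness
of the inference machinery under the model's own assumptions, not
performance on real pharmacogenomic data.

## Numerical choices

* Rates `v`, `π` are clipped to `[1e−12, 1−1e−12]` after Beta draws so flip
  log-odds stay finite; precisions and their rate hyperparameters are kept
  in `[1e−100, 1e100]` so the prior-only random walk (rows with no data)
  cannot reach 0 or ∞.
* `X` conditionals use Cholesky factorizations; the precision matrix is
  positive definite by construction (`diag(λ') > 0`).
* Constant rows get unit scale in the standardizer instead of dividing by
  zero.
* Flip probabilities use the numerically stable `expit`; ties in the greedy
  LC matching of `z_support_f1` are broken by match quality, then column
  order.
* Trace snapshots serialize to per-snapshot TSV files plus a JSON manifest
  with full `%.17g` precision, so a saved trace reproduces predictions
  exactly.

## Problem sizes used by the test suite and acceptance script

Sampler-level checks run on instances with one or two unknowns against
quadrature/enumeration oracles (tolerance 1e−6).  The Geweke prior-invariance
check uses D=4, N=6, P=3, k_max=3 with 20,000 sweeps.  Recovery experiments
use the generator defaults above with k_max=10, 2,000 sweeps (half burn-in),
ten seeds, with and without the drug graph; cross-validation uses 10 folds
at 1,500 sweeps per fold.  These sizes make the full suite run in minutes on
one CPU while leaving the statistical conclusions stable across seeds.

## Known limitations

* With the drug MRF at edge weight 1.0 on densely cliqued graphs (the
  synthetic truth graph links all drugs sharing an LC, producing 5-cliques),
  support recovery can *degrade*: a clique member with several active
  neighbours receives a prior log-odds boost that can exceed the Occam
  penalty of the marginal Bayes factor for drugs with little signal, and the
  conjugate `v_k` update then ratchets column occupancy upward.  Held-out
  predictive accuracy is unaffected in our experiments, and weights ≤ 0.5
  are roughly neutral for support recovery.  On sparser, more realistic
  target-sharing graphs (pairs/triples) the boost is correspondingly
  smaller.  If support interpretation is the goal, inspect sensitivity to
  `mrf_weight`.
* Single-site Gibbs mixes slowly between near-rotational modes of (G, X);
  short chains can merge two true LCs into one column.  Use the default
  10,000-sweep budget for real analyses and monitor the log-joint trace and
  active-LC counts.
* The sampler is O(D·K + P·K) per sweep in dense linear-algebra operations
  on N-vectors; at CCLE scale (tens of thousands of features) a fit is
  hours, not minutes.
* No uncertainty intervals on predictions; no non-Gaussian likelihoods; no
  per-cell-line noise.
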