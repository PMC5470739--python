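# Methods

## Model and procedure

`rots` ranks features of a two-group expression matrix (G features × N
samples, preprocessed and normalized upstream) by a data-adapted member of
the modified t-statistic family

d_α(i) = |x̄₁ᵢ − x̄₂ᵢ| / (α₁ + α₂ sᵢ),

where sᵢ is the classical pooled two-sample standard error

sᵢ = sqrt( (SS₁ᵢ + SS₂ᵢ)/(n₁+n₂−2) · (1/n₁ + 1/n₂) ).

With this definition the (α₁=0, α₂=1) member is exactly the magnitude of
the ordinary pooled-variance t-statistic, and (α₁=1, α₂=0) is the absolute
mean difference (log fold change for log-scale data); both identities are
enforced by tests against independent computations.  A Welch-type standard
error would also be defensible; the pooled form is chosen precisely so the
ordinary-t special case holds exactly.

The parameters are selected by maximizing the reproducibility Z-score
Z_k = (R_k − R⁰_k)/s_k over a lattice (α₁, α₂, k):

* **R_k** — B group-preserving bootstrap draws (columns resampled with
  replacement within each group, group sizes preserved, original labels
  applying positionally) are formed into B/2 disjoint consecutive pairs;
  R_k is the mean over pairs of |top-k(a) ∩ top-k(b)|/k.
* **R⁰_k** — the same computation on B label-permutation draws (each draw a
  full shuffle of the columns), paired the same way.  Permutations are
  drawn independently of the bootstrap stream; the null is *not* a
  bootstrap of one fixed permuted dataset.
* **s_k** — the sample standard deviation (n−1 denominator) of the B/2
  pair-level bootstrap overlaps at k.

The final statistic, p-values and FDR are computed on the original data at
the selected (α₁, α₂).

## Parameters

| parameter | default | meaning |
|---|---|---|
| B | 1000 | bootstrap draws; the same count of permutation draws feeds the null surface and, later, the p-value/FDR null.  Must be even (disjoint pairs). |
| K | min(500, G) | largest top-list size searched.  If the selected k lands within 5% of K a warning advises raising K; an explicit K > G is an error. |
| α₁ grid | 0, 0.01, …, 5 | denominator offset (units of the data scale). |
| α₂ grid | {0, 1} | pooled-SE switch; (0,0) excluded. |
| seed | — | one user-visible integer; bootstrap, optimizer-permutation and inference-permutation streams are derived with fixed tags, so enlarging one resampling set never perturbs another. |

## Inference

With P = B permutations at the selected parameters:

* **p-values** pool all G·P null values: pᵢ = #{null ≥ d_obs(i)}/(G·P),
  floored at 1/(G·P).  Pooling across features gives resolution ≈ 1/(G·P)
  rather than 1/P; it assumes the null statistic values are comparable
  across features, which the denominator regularization encourages.
* **FDR** is SAM-style: rawᵢ = (mean per-permutation count of null values ≥
  d_obs(i)) / #{observed ≥ d_obs(i)}, capped at 1, then monotonized along
  decreasing d by a running minimum from the least significant feature
  upward, so FDR is non-increasing in the statistic value.  This is
  numerically equivalent to Benjamini–Hochberg applied to the pooled
  permutation p-values; no π₀ estimate is applied, which makes the
  estimator mildly conservative when many features are truly changed.

## Numerical choices

* Rankings use a stable descending sort; ties keep the original row order,
  making every ranking, surface and argmax bit-reproducible across
  platforms.
* Zero denominators (α₁ = 0 with sᵢ = 0): d = 0 when the mean difference is
  also 0, otherwise the largest finite double, so the feature ranks first
  without producing non-finite values in the grid search.
* Degenerate surface cells (all pair overlaps identical, s_k = 0) receive
  Z = −∞ and can never win the argmax; identical-overlap detection is exact
  (max = min over pairs) rather than relying on floating-point standard
  deviations, which are not exactly zero for identical rationals.  If every
  cell is degenerate, `optimize` raises and advises a larger B;
  `ROTS.fit` retries accepting the degenerate surface so that trivial
  inputs (e.g. an all-constant matrix) still yield d = 0, p = 1.
* Argmax ties break toward the smallest k, then smallest α₁, then α₂ = 1
  before 0: the most parsimonious top list and the most t-like statistic.
  Distinct cells can tie in Z exactly (overlap profiles are rationals), in
  which case the tie rule, not noise, decides.
* The whole α₂ = 0 branch shares one ranking per dataset (α₁ only rescales
  d), and per-pair overlap profiles over all k are computed as a cumulative
  histogram of per-feature maximum ranks, O(G) per pair per statistic.
  Per-pair overlap matrices are stored densely when they fit in ~300 MB and
  otherwise reduced with running sums; only the ulp-level association order
  of the variance computation differs between the two paths.

## Synthetic data

The generator emulates spike-in benchmark designs: feature baselines are
uniform on a log-intensity range (default 19–26, matching typical log₂
label-free proteomics abundances), within-group noise is Gaussian with
SD 0.5 (a typical replicate SD on that scale), and a fraction π_DE of
features (default 10%) is shifted in group 1 by ±effect·SD (default 3,
alternating sign so both tails are exercised).  An optional heteroscedastic
mode draws per-feature SDs log-normally (σ = 0.25) around the common value.
Benchmarks in the tests and acceptance script use G = 1000, n = 5+5,
B = 100 — sizes at which a full-lattice run takes seconds while leaving the
bootstrap and permutation pairings non-trivial.

What the simulation does **not** model: count noise (the generator works on
the normalized log scale by design), single-cell dropout, correlated
features, batch effects, and library-size differences.  Passing the
synthetic benchmarks therefore demonstrates correctness of the algorithm
and calibration under idealized Gaussian conditions, not performance on raw
counts or structured real data.

## Known limitations

* Two groups only; no paired designs and no multi-group (F-type) extension.
* Single-threaded; the default lattice with B = 1000 on large matrices is
  compute-heavy (K and the optional k-stride are the main speed levers).
* The permutation FDR needs enough distinct label permutations to be
  informative: with n = 3+3 there are only 10 distinct splits, and FDR
  granularity suffers accordingly.
* Missing values are rejected at read time; imputation/normalization are
  upstream concerns.
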