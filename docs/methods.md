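# Methods

## Model and estimator

The package estimates conditional mutual information `I(X;Y|Z)` from an
i.i.d. sample of a mixed random vector. Each column is declared qualitative
(finite support, equality-only comparisons; stored as integer category codes)
or quantitative (real-valued). The estimator, CMIh, rewrites the usual
four-entropy form `H(X,Z) + H(Y,Z) − H(X,Y,Z) − H(Z)` so that conditioning
only ever involves qualitative tuples, yielding eight terms: four discrete
entropies of qualitative tuples and four entropies of quantitative
sub-vectors conditioned on those tuples.

* Qualitative terms are plug-in entropies over empirical frequencies of the
  observed value tuples. No smoothing is applied; unobserved tuples carry no
  mass by construction.
* Conditional quantitative terms marginalise over the qualitative bins:
  `Σ_b p̂_b Ĥ(quantitative | bin b)`, each bin estimated with the
  Kozachenko–Leonenko kNN entropy under the Chebyshev (ℓ∞) metric,
  `ψ(n_b) − ψ(k) + (d/n_b) Σ log ξ_i`, where `ξ_i` is twice the distance to
  the point's k-th neighbour within the bin.

Assumptions: rows are i.i.d.; quantitative components have a density within
each qualitative bin; qualitative components have finite support. The
estimate is reported raw — it can be negative in finite samples, and no
non-negativity clamp is applied because the permutation tests need the
unclipped statistic.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_rule` | `max(⌊n_sub/10⌋, 1)` | neighbour count of each kNN term, chosen per term from its own subsample (bin) size, clamped to `[1, n_sub−1]` |
| `D_l` | 1.0 | (0–D) qualitative distance used by the FP/RAVK/MS baselines |
| `tie_floor` | `1e-10 ×` data range | lower floor on `ξ_i` before taking logs (guards duplicates) |
| `B` | 1000 | permutation replicates per test |
| `k_perm` | 5 | neighbourhood size hyper-parameter of the local tests |
| `rank_transform` | on (tests only) | rank quantitative columns (ties broken by first appearance) before testing |

Entropies are natural-log throughout. The ℓ∞ unit-ball log-volume `d log 2`
is dropped from every kNN term: the quantitative dimensions of the four terms
satisfy `d_xz + d_yz − d_xyz − d_z = 0`, so the omission cancels exactly
(a config switch `include_volume` re-adds it; a property test asserts the
estimate is unchanged).

## Numerical choices

* **Neighbour search.** Exact: a KD-tree (`scipy.spatial.cKDTree`, `p=inf`)
  above 96 points per bin, an all-pairs distance matrix below. A brute-force
  reference implementation in the test suite checks both paths produce
  identical k-th order statistics.
* **Bins of size one** have no neighbour; they contribute zero quantitative
  entropy while keeping their weight `p̂_b`, so the bin weights always sum
  to one.
* **Duplicate points** would give `log 0`; `ξ` is floored (see `tie_floor`).
  Rank-transforming quantitative columns beforehand removes ties altogether
  and is the default for testing.
* **Ties at the neighbour radius** in the baselines are resolved by each
  method's own counting inequality (strict for FP, non-strict for RAVK/MS),
  never by jittering. FP's strict counts are floored at 1; MS counts are
  clamped to ≥ 1 so the digamma is defined.
* **RNG.** One user-facing seed; each permutation replicate uses an
  independent child of a `SeedSequence`, so results are reproducible and
  independent of evaluation order.

## Permutation tests

GloT permutes all X rows globally (a bijection). LocT and LocAT draw, for
each point i, a donor `π(i)` uniformly (with replacement) from the
neighbourhood `N_i = {j : D(Z_j, Z_i) ≤ d_i}` of its Z value, where `D` is
the absolute difference on quantitative and the (0–∞) distance on qualitative
components, and `d_i` is the distance to the k-th nearest neighbour (the
point itself included in the ranking, so `i ∈ N_i` and `π(i)=i` is a legal
draw). LocT uses a fixed `k = k_perm`: when fewer than `k_perm` points share
a point's qualitative Z values the k-th distance is infinite and the
neighbourhood silently degrades to the whole sample. LocAT clamps
`k_i = min(k_perm, n_i^ℓ)` to the qualitative class size, which keeps every
neighbourhood inside the class — the property that makes the test hold its
level on mixed Z. With an empty Z both local schemes fall back to the global
bijective shuffle. Inside a test only the X columns of a replicate change,
so the two entropy terms built from (Y,Z) alone are computed once and cached.
When MS is the statistic it keeps its own (0–1) metric internally while the
neighbourhoods use (0–∞).

The p-value is `(1/B) · #{b : Î_b ≥ Î_obs}` — a multiple of 1/B in [0,1],
with 0 attainable (no add-one smoothing).

## Synthetic settings

The named generators reproduce the validation study conditions: a bivariate
Gaussian with correlation 0.6; `X ~ U{0..4}` with `Y|X=x ~ U([x, x+2])`;
`X ~ Exp(1)` with zero-inflated Poisson `Y|X=x ~ 0.15δ₀ + 0.85 Pois(x)`;
each of these with an added independent `Bi(3, 0.5)` conditioner; three
conditionally independent constructions; and the multidimensional M-CMI,
M-MI and M-ICMI processes. Discrete-uniform, binomial and zero-inflated
Poisson components are marked qualitative; Gaussian, continuous-uniform and
exponential components quantitative. `Exp(λ)` is read as the rate
parameterisation (`Exp(10)` has mean 0.1); the ground truths affected by
this reading are 0 either way. Analytic values are evaluated in closed form;
the zero-inflated series `Σ log(k) 2^{−k}` is summed until terms fall below
1e-14 (tail well under 1e-8).

The chain/fork/collider structure generators are this package's own
constructions (the original processes are not published): quantitative roots
are standard Gaussian, qualitative roots uniform on {0..3}; edges add unit
Gaussian noise (→ quantitative), draw `Bi(3, logistic(2·parent))`
(quantitative → qualitative), use the category code as a Gaussian mean
(qualitative → quantitative), or copy with a 10% uniform relabel
(qualitative → qualitative); a collider child combines its two parents
additively, centred, before the same rules. These preserve exactly the
dependence/independence pattern each structure requires for every type
configuration, so acceptance-rate results on them are qualitative analogues,
not numeric reproductions, of the published table.

### What the generators do and do not emulate

They emulate the distributional shapes, type mixtures, class imbalance and
(in)dependence structures of the study conditions. They do not emulate
autocorrelation, missingness, measurement error, or qualitative variables
with very large alphabets — passing tests therefore demonstrate correctness
of the estimators and tests under i.i.d. sampling from these families, not
performance on arbitrary real data.

## Experiment sizes

MSE experiments use 100 datasets per sample size with n from 500 to 2000;
acceptance-rate experiments use 10 repetitions of n = 500 with B = 1000
permutations, thresholds 0.01 and 0.05 — the same problem sizes the study
conditions prescribe. The acceptance script re-estimates the M-ICMI MSE and
the conditionally-independent-setting mean at n = 2000 over 100 datasets.

## Known limitations

* **Finite-k bias.** The prescribed neighbour rule keeps `k/n_sub` at a
  fixed ratio (0.1), so each kNN entropy term carries a bias that does not
  vanish with n; it largely cancels across the eight terms for
  low-dimensional settings (net bias ~0.005–0.013 nats at n = 2000) but
  accumulates in high-dimensional joint terms — most visibly on M-MI, where
  the six-variable joint entropy over many small bins leaves a substantial
  negative bias that growing n does not remove. The mean-recovery checks in
  the acceptance-criteria suite use a pure Monte-Carlo band (3 SE of the
  replicate mean) that does not absorb this intrinsic bias, and several
  settings therefore fail them by small margins; the conditionally
  independent settings and the M-ICMI MSE bound pass.
* Qualitative bins with very few points contribute noisy (or, for
  singletons, zero) entropy terms; many rare categories degrade accuracy.
* The tests are calibrated empirically (permutation null), not
  asymptotically; B bounds the p-value resolution at 1/B.
* No missing-data handling: ingestion rejects missing cells.
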