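# mixedcmi

Conditional mutual information (CMI) estimation and conditional-independence
testing for **mixed data** — samples whose variables combine *qualitative*
components (finite support, compared only by equality: nominal codes, small
ordinal scales) and *quantitative* components (real-valued). Such data are the
norm in systems biology, monitoring systems and epidemiology, and CMI is the
workhorse dependence measure behind constraint-based causal discovery,
graphical-model inference and feature selection: `I(X;Y|Z) = 0` iff
`X ⊥⊥ Y | Z`.

## What the package implements

**The hybrid estimator (CMIh).** Writing `Xᵗ`/`Xˡ` for the quantitative /
qualitative sub-vectors of a block, CMI decomposes into entropies in which the
conditioning involves only qualitative tuples:

```
I(X;Y|Z) =  H(Xᵗ,Zᵗ|Xˡ,Zˡ) + H(Yᵗ,Zᵗ|Yˡ,Zˡ) − H(Xᵗ,Yᵗ,Zᵗ|Xˡ,Yˡ,Zˡ) − H(Zᵗ|Zˡ)
          + H(Xˡ,Zˡ)       + H(Yˡ,Zˡ)       − H(Xˡ,Yˡ,Zˡ)          − H(Zˡ)
```

The qualitative entropies are plug-in entropies `−Σ p̂ log p̂` over empirical
bin frequencies; each conditional term is a bin-weighted sum of
Kozachenko–Leonenko k-nearest-neighbour entropies

```
Ĥ = ψ(n_b) − ψ(k) + (d / n_b) Σᵢ log ξᵢ ,   ξᵢ = 2 · (ℓ∞ distance of i to its k-th neighbour)
```

computed inside each qualitative bin, with `k = max(⌊n_b/10⌋, 1)` chosen per
term from its own subsample size. All entropies are in nats. The unit-ball
log-volume terms cancel exactly across the combination and are omitted.

**Baselines.** The shared-form kNN estimators FP (Frenzel–Pompe), RAVK
(Rahimzamani et al.) and MS (Mesner–Shalizi), including the exact degeneracy
of MS (estimate ≡ 0 once every neighbour radius reaches the qualitative
distance `D_ℓ`), reproduced as a regression test.

**Permutation tests.** GloT (global shuffle), LocT (local permutation with a
fixed neighbourhood size) and **LocAT** (local adaptive test): donor
neighbourhoods in Z-space under a distance that is `|·|` on quantitative and
(0–∞) on qualitative components, with a per-point neighbour count
`kᵢ = min(k_perm, nᵢˡ)` clamped to the size of the point's qualitative class.
The p-value is the fraction of `B` locally permuted replicates whose statistic
reaches the observed one.

**Synthetic benchmarks.** Generators for the validation settings with analytic
ground truths (bivariate Gaussian; discrete-uniform with conditional uniform;
exponential with zero-inflated Poisson; conditioned, conditionally
independent and multidimensional variants) plus chain / fork / collider
structures over every type configuration, and MSE / acceptance-rate harnesses.

## Worked example

```python
import numpy as np
from mixedcmi import TestConfig, cmih, generate, ground_truth, run_test

# mixed pair (X qualitative, Y quantitative) with an independent qualitative Z
gd = generate("cmi_mixed", n=1000, seed=7)
est = cmih(gd.sample, gd.x, gd.y, gd.z)
print(f"CMIh estimate: {est.value:.4f}  (truth {ground_truth('cmi_mixed'):.4f})")

res = run_test(gd.sample, gd.x, gd.y, gd.z, estimator="cmih",
               config=TestConfig(B=500, scheme="locat", seed=7))
print(f"LocAT p-value: {res.p_value:.3f}")
```

prints

```
CMIh estimate: 1.0950  (truth 1.0549)
LocAT p-value: 0.000
```

The estimate is within finite-sample error of the analytic value
`log 5 − (4/5) log 2 ≈ 1.0549`, and the test rejects conditional independence
(X and Y are dependent; Z is an independent conditioner, so rejecting is
correct). On the conditionally independent variant (`cmi_mixed_indep`) the
same test yields `p = 0.956` — no rejection, as it should be.

The same operations are available from a shell:

```sh
mixedcmi estimate --input data.csv --spec columns.yaml --estimator cmih
mixedcmi test --input data.csv --spec columns.yaml --test locat -B 1000 --seed 7
mixedcmi benchmark mse --setting mi_mixed --n-grid 500:2000:500 --reps 100 --estimators cmih,ms --seed 7
```

where `columns.yaml` declares each column, e.g.

```yaml
latitude:    {type: quantitative, block: X}
longitude:   {type: quantitative, block: Y}
temperature: {type: qualitative,  block: Z}
```

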