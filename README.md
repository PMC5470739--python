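# rots — reproducibility-optimized statistical testing

`rots` performs two-group differential expression analysis on omics
expression matrices — microarray intensities, normalized bulk or single-cell
RNA-seq counts, label-free proteomics abundances — for analysts who need a
test statistic that adapts to the data instead of being fixed a priori.
Different modified t-statistics are known to perform best on different
datasets; `rots` picks the member of the family that maximizes the
reproducibility of its top-ranked feature lists under resampling of the
observed data.

## The method

For feature *i* with group means x̄₁ᵢ, x̄₂ᵢ and pooled two-sample standard
error *sᵢ*, the statistic family is

    d_α(i) = |x̄₁ᵢ − x̄₂ᵢ| / (α₁ + α₂·sᵢ),      α₁ ≥ 0,  α₂ ∈ {0, 1}

which contains the absolute log fold change (α₁ = 1, α₂ = 0) and the
ordinary pooled two-sample t-statistic (α₁ = 0, α₂ = 1) as special cases.
For each candidate (α₁, α₂) and each top-list size *k*, the observed
reproducibility R_k(d_α) is the average fraction of features shared by the
top-*k* lists of paired group-preserving bootstrap datasets; R⁰_k(d_α) is
the same quantity on datasets whose sample labels have been permuted.  The
parameters are chosen by maximizing the reproducibility Z-score

    Z_k(d_α) = (R_k(d_α) − R⁰_k(d_α)) / s_k(d_α)

over the lattice α₁ ∈ {0, 0.01, …, 5}, α₂ ∈ {0, 1}, k ∈ {1, …, K}, where
s_k(d_α) is the standard deviation of the pair-level bootstrap overlaps.
The final statistic is computed on the original data with the winning
(α₁, α₂); empirical p-values and a SAM-style FDR are then estimated by
permuting the sample labels.

## Worked example

```python
from rots import ROTS, SyntheticSpec, generate, evaluate_detection
from rots.synthetic import groups_for

spec = SyntheticSpec(G=500, n1=5, n2=5, pi_de=0.1, effect=3.0, seed=42)
m, truth = generate(spec)                 # 50 of 500 features shifted by 3 SD
res = ROTS(m, groups_for(spec)).fit(B=100, seed=42)
print(res.summary())
print(evaluate_detection(res, truth, 0.05))
```

prints

```
Reproducibility-Optimized Test Statistic
==========================================================
Features (G): 500    Samples: 5 + 5 ('A' vs 'B')
Bootstraps (B): 100    Max top-list size (K): 500    Seed: 42
----------------------------------------------------------
Selected statistic:  alpha1 = 2.03, alpha2 = 1
Top-list size k = 53    R = 0.8102    Z = 11.0002
Features at FDR < 0.01 / 0.05 / 0.10:  0 / 45 / 49
----------------------------------------------------------
Top 10 features by d:
         d  logfc  pvalue  fdr
F38  1.005   -2.3   2e-05 0.01
...
```

The optimizer settled on a variance-regularized t-type statistic
(α₁ = 2.03, α₂ = 1) whose top-53 list is 81% reproducible across bootstrap
pairs, 11 bootstrap standard deviations above chance.  At FDR < 0.05 it
recovers 45 of the 50 truly shifted features with no false positives
(`precision=1.000, recall=0.900`).  `res.plot("volcano", path="v.png")`
renders any of the six diagnostic plots (volcano, ma, reproducibility,
pvalue, pca, heatmap).

The same analysis from the shell:

```sh
rots simulate --G 500 --pi-de 0.1 --effect 3 --seed 42 --out-prefix sim
rots run --input sim.matrix.tsv --groups A,A,A,A,A,B,B,B,B,B \
         --B 100 --seed 42 --out-prefix sim
rots plot --results sim.results.tsv --type volcano --out volcano.png
```

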