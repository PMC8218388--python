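# sparkx

Scalable, non-parametric detection of spatially variable (SE) genes in large,
sparse spatial transcriptomic count data — an independent Python
implementation of the SPARK-X covariance test, together with the simulation
and calibration/power harness used to study it.

Modern platforms (Slide-seq, Slide-seqV2, HDST, Visium, STARmap) measure
expression of tens of thousands of genes on 10⁴–10⁵ spatial locations, with
up to 99.9% zero counts. Kernel-based SE tests that materialize n × n
covariance matrices need cubic time and memory and become unusable at this
scale; parametric count models are numerically fragile on such sparse data.
This package tests each gene for dependence between expression and location
with a projection covariance (kernel independence) statistic whose algebra
collapses to d × d problems, giving O(nd² + p·n′·d) time and O(nd²) memory
for p genes, n locations, d ∈ {2, 3} spatial dimensions and n′ non-zero
locations per gene.

## The test

For one gene let y ∈ ℝⁿ be its (standardized) expression and S the n × d
matrix of (standardized) coordinates. With the projection covariance
matrices E = y(yᵀy)⁻¹yᵀ and Σ = S(SᵀS)⁻¹Sᵀ, centered as E_C = HEH and
Σ_C = HΣH with H = I − X(XᵀX)⁻¹Xᵀ (X = 1ₙ without covariates), the statistic
is

    T = trace(E_C Σ_C) / n .

Under independence of y and S, T is asymptotically a mixture
(1/n²) Σᵢⱼ λ_{E,i} λ_{Σ,j} z²ᵢⱼ of χ²₁ variables, where λ_E = (yᵀy)⁻¹yᵀHy and
λ_{Σ,j} are the eigenvalues of (SᵀS)⁻¹SᵀHS — all computable without ever
forming an n × n matrix. Tail probabilities of the mixture are evaluated
essentially exactly (see `docs/methods.md`).

A single projection kernel is blind to focal or periodic patterns, so the
test is repeated on transformed coordinates: five Gaussian transformations
s′ = exp(−s²/2σ²) and five cosine transformations s′ = cos(2πs/φ), with σ
and φ set per axis to the 20/40/60/80/100% quantiles of the absolute
standardized coordinates (making everything invariant to rescaling the raw
coordinates). The eleven per-kernel p-values are combined with the Cauchy
combination rule, and multiplicity is controlled with Benjamini–Yekutieli
(default) or Benjamini–Hochberg step-up adjustment. In the presence of
covariates (e.g. cell-type compositions), X absorbs them and the test reads
on spatial structure beyond the covariates.

The `simulate` module generates the matching synthetic data: locations from
a uniform point pattern, counts from a negative binomial with mean μ and
variance μ + φμ² (so μ = 0.5, φ = 0.2 gives ~62.1% zeros and μ = 0.005,
φ = 2.5 gives ~99.5% zeros), and SE genes carrying hotspot, streak or
gradient patterns with known truth labels. The `evaluate` module provides
permutation nulls, type-I-error / genomic-inflation reports, truth-based
power at an FDR level, and empirical-FDR thresholds.

## Worked example

```python
import numpy as np
from sparkx import (SimulationConfig, simulate_dataset, sparkx_test,
                    power_at_fdr)

cfg = SimulationConfig(
    n_locations=2000, n_genes=500, n_se_genes=50, pattern="streak",
    mean=0.5, dispersion=0.2, fold_change=3.0, marked_fraction=0.2, seed=42,
)
ds = simulate_dataset(cfg)
results = sparkx_test(ds.counts, ds.coords)

p = np.array([r.combined_p for r in results])
ok = np.array([r.status == "ok" for r in results])
top = results[int(np.nanargmin(p))]
print(f"top gene: {top.gene_id}  combined p = {top.combined_p:.3e}")
rep = power_at_fdr(p[ok], ds.truth[ok], 0.05, "truth_fdr")
print(f"power at truth-FDR 0.05: {rep.power_at_fdr:.2f}")
```

prints

```
top gene: gene_8  combined p = 5.899e-52
power at truth-FDR 0.05: 1.00
```

i.e. on a moderately sparse streak simulation (a 3-fold elevated central
band covering 20% of 2,000 locations) the test recovers all 50 SE genes at
a truth-based FDR of 0.05 (52 genes declared, 50 of them true); the 50
planted genes are also exactly the genes significant at BY-adjusted
p ≤ 0.05.

The same pipeline is available from the shell:

```sh
sparkx simulate --pattern streak --n 2000 --genes 500 --se 50 \
    --mu 0.5 --phi 0.2 --fc 3 --seed 42 --out sim
sparkx run --counts sim.mtx --coords sim.coords.tsv --out results.tsv
sparkx eval-power --results results.tsv --truth sim.truth.tsv --out power.json
```

`results.tsv` carries one row per gene: the eleven per-kernel p-values
(`p_identity`, `p_gaussian_1..5`, `p_cosine_1..5`), `combined_p`,
`adjusted_p` and a `status` column (constant genes are reported as
`degenerate_skipped`, never silently dropped).

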