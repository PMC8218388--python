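# Methods

## Model and statistic

Each gene is tested marginally for dependence between its expression vector
y ∈ ℝⁿ and the n × d coordinate matrix S (d ∈ {2, 3}). The statistic is a
covariance (kernel independence) test built from projection covariance
matrices, E = y(yᵀy)⁻¹yᵀ for expression and Σ = S(SᵀS)⁻¹Sᵀ for space. Both
are centered through H = I − X(XᵀX)⁻¹Xᵀ, where X is the n × q covariate
design (a column of ones, plus optional encoded covariates), and compared
via

T = trace(E_C Σ_C)/n,  E_C = HEH,  Σ_C = HΣH.

T sums, over all location pairs, the product of the two similarity
measurements (coordinated deviation from the mean in expression, and in
space); it is large exactly when the two relationship structures align.
Under the null that y ⟂ S, T is asymptotically distributed as
(1/n²) Σᵢⱼ λ_{E,i} λ_{Σ,j} z²ᵢⱼ with independent z ~ N(0, 1). Because E_C has
rank one, only λ_E = (yᵀy)⁻¹yᵀHy and the d eigenvalues λ_{Σ,j} of
(SᵀS)⁻¹SᵀHS enter. The asymptotics are in n with d and q fixed; no
distributional assumption is placed on the counts, which is what makes the
test robust across platforms with very different generative processes.

Assumptions worth stating: (i) locations are exchangeable under the null —
spatially structured technical variance (e.g. region-dependent capture
efficiency) would read as signal; (ii) residual variance after covariate
adjustment is exchangeable — see "Covariate adjustment" below; (iii) n is
large relative to d + q.

## Linear-time algebra

Nothing n × n is ever formed. Per kernel, the one-time cost is SᵀS, XᵀS,
XᵀX and the eigenvalues of (SᵀS)⁻¹SᵀHS, obtained from the symmetric
congruent form L⁻¹(SᵀHS)L⁻ᵀ with L the Cholesky factor of SᵀS — this
guarantees real eigenvalues, which are clipped to [0, 1] at tolerance 1e-8
(they are eigenvalues of a product of projections). Per gene, only yᵀS, yᵀX
and yᵀy are needed; with raw counts c, mean m and sample sd s, the identity
yᵀv = (cᵀv − m·sum(v))/s lets every reduction touch only the non-zero
counts. `sparkx_test` evaluates all genes at once through sparse
matrix-matrix products (Y·S, Y·X, row sums); this batch path is tested for
exact agreement with the per-gene `gene_statistic`, and both are tested
against explicitly materialized dense E_C, Σ_C for n ≤ 200.

Standardization uses the sample standard deviation (n − 1 denominator), so
with an intercept-only design yᵀy = n − 1 and λ_E = 1 exactly. The choice of
denominator only rescales y and the statistic is scale-free in y, so
p-values are unaffected (asserted in the tests). Constant genes cannot be
standardized and are reported with status `degenerate_skipped` rather than
p = 1, so downstream FDR is not distorted.

## Kernel set

Coordinates are standardized per axis (which makes the whole procedure
invariant to translating and rescaling the raw coordinates) and expanded
into eleven versions: identity, five Gaussian transformations
s′ = exp(−s²/2σ²) aimed at focal patterns, and five cosine transformations
s′ = cos(2πs/φ) aimed at periodic patterns. The k-th kernel of each family
uses the k-th of the 20/40/60/80/100% quantiles of |standardized
coordinate|, taken per axis (so σ₁ ≠ σ₂ in general within one kernel; the
100% level is the axis maximum; quantiles use linear interpolation). A zero
quantile — possible on an axis with many repeated values — is replaced by
the smallest positive absolute value, with a warning. Transformed
coordinates are deliberately not re-centered: centering is H's job inside
the statistic, and rescaling a column of S cannot change its projection.

Per-kernel p-values are combined with the Cauchy rule: C = (1/K) Σ
tan((0.5 − p_k)π), combined p = 1/2 − arctan(C)/π. Inputs are guarded to
[1e-300, 1 − 1e-15]; below p ≈ 1e-16 the tangent is evaluated as 1/(πp) to
avoid overflow. The rule is exact for independent uniform p-values and
tail-robust under arbitrary dependence.

## Mixture-of-chi-square tail probabilities

P(Σ c_k z_k² ≥ t) is needed for k ≤ 3 components. Rather than inverting the
characteristic function numerically (the route taken by Davies-style
integrators, whose oscillatory truncation is delicate for extreme tails),
the implementation conditions on one component at a time: peeling the
smallest coefficient c and substituting w = sqrt(t/c)·sin ψ turns the
square-root kink of the inner chi-square survival function into an analytic
integrand on (0, π/2), so 128-point Gauss–Legendre quadrature converges
spectrally. All terms are positive, preserving relative accuracy deep into
the tail; against exact scaled-χ² cases the error is at machine level, and
a 10⁷-draw Monte-Carlo oracle confirms unequal-coefficient cases within
Monte-Carlo error. When the kink lies beyond 8.5 null standard deviations
its region is bounded by 2Φ(−8.5) ≈ 2e-17; results below 1e-14 are therefore
delegated to a Kuonen (Lugannani–Rice) saddlepoint approximation, accurate
to a few percent relative there. Coefficients below 1e-12 of the largest are
dropped (their effect on p is smaller than the quadrature error; keeping
them would concentrate the integrand into an unresolvable peak). Final
p-values are clamped to [1e-300, 1].

Only the relative sizes of the coefficients and t/λ_E matter, so the
per-kernel eigenvalues are shared across genes and only the threshold varies
per gene.

## Covariate adjustment

Covariates enter exclusively through X: categorical columns are one-hot
encoded with a reference level dropped, an intercept is always included, and
constant or collinear columns are removed (with a warning) so X has full
column rank. Adjusting for a covariate that fully determines a gene's
spatial pattern returns that gene to the null in terms of error control: in
the harness's construction (hotspot mean shift carried by a binary
covariate, negative binomial counts) the adjusted rejection rate at
α = 0.05 is nominal. The adjusted p-value distribution is, however, mildly
conservative in its body (median ≈ 0.59 rather than 0.5): a negative
binomial mean shift is also a variance shift, and H removes the mean
difference but not the heteroskedasticity, which the exchangeable-variance
null does not model. Tail behavior — what significance calls use — is
unaffected in our checks.

## Synthetic data

The generator reproduces the simulation design the method was studied
under. Locations: n i.i.d. uniform points on the unit square (a Poisson
point process conditioned on its count; the domain's shape is irrelevant
after standardization). Counts: negative binomial with mean μ and dispersion
φ under variance = μ + φμ² (size = 1/φ; φ = 0 falls back to Poisson). This
parameterization is pinned down by the sparsity regimes it must reproduce:
P(0) = (1 + φμ)^(−1/φ) gives 62.1% zeros at (μ = 0.5, φ = 0.2) and 99.5% at
(μ = 0.005, φ = 2.5). Defaults follow the study grids: μ ∈ {0.5, 0.005},
φ ∈ {0.1, 0.2, 1} (moderate sparsity) or {1, 2.5, 5} (high sparsity),
fold changes {1.5, 2, 3} or {2, 3, 4}, marked fractions {10, 20, 30}%,
gradient fractions {20, 30, 40}%, n from 300 to 50,000.

SE genes split half/half into up- and down-regulated (hotspot/streak:
marked-location mean μ·fc or μ/fc) or increasing/decreasing (gradient). The
hotspot disc and streak band are defined by empirical quantiles (distance to
the centroid; central x-ranks), so the marked fraction is exact for any
point pattern. Gradient genes draw from the same marginal distribution as
null genes and acquire signal purely by re-ordering a random subset of their
values along x — the count multiset is untouched.

What the generator does not emulate: per-location size factors / depth
variation, gene-gene correlation, segmentation noise, spatially varying
capture efficiency, and multi-gene mean-dispersion trends. Passing
calibration and power checks on these simulations therefore demonstrates
correctness of the statistic and its null distribution under exchangeable
noise, not robustness to platform artifacts.

## Harness definitions

- Genomic inflation factor: λ_gc = median(F⁻¹_{χ²₁}(1 − p)) / 0.45494.
- Truth-based power at FDR α: sweep p-value thresholds (tie boundaries
  only, since a threshold declares all tied values), keep the largest whose
  realized false-discovery proportion is ≤ α, and report the fraction of
  true SE genes declared. BY/BH-adjusted variants are provided alongside;
  BY is the default multiplicity adjustment elsewhere because it is valid
  under the dependence across genes.
- Permutation null: coordinates (and covariate rows, jointly) are permuted
  across locations, the full test re-run, and combined p-values pooled
  across replicates (ten by default).
- Empirical FDR threshold: the largest cutoff t with
  mean(perm_p ≤ t)·n_real / #(real_p ≤ t) ≤ level.

## Known limitations and observed behavior

- The combined (Cauchy) p-value is exactly uniform under independence of
  the per-kernel p-values, but the eleven kernels share the same y; under
  this dependence the combination is tail-robust yet not body-exact. On
  null simulations the result is a ~2% conservative deflation of the body
  (λ_gc ≈ 0.90, rejection at α = 0.05 around 0.046-0.048), visible to a KS
  test with 10⁴ p-values though irrelevant to significance calling. The
  effect is independent of n and persists under rank-uniformized per-kernel
  p-values, i.e. it is a property of the combination rule, not of the
  per-kernel approximation (each kernel's p-values pass KS uniformity on
  their own).
- Detection requires information: at n = 3,000 locations with μ = 0.005,
  a 3-fold hotspot on 20% of locations amounts to roughly 9 versus 12
  expected total counts inside/outside the disc per gene — below what any
  test can rank reliably against 900 nulls at FDR 0.05. Power climbs
  steeply with n (≈ 0 at 3,000; ≈ 0.2 at 20,000 under the same signal),
  which is the regime the method is designed for.
- Problem sizes in the test harness (e.g. 10,000 genes × 3,000 locations
  for calibration; 40-50 genes at n = 50,000 for the scaling check) are the
  package's chosen desk-scale study conditions; the method itself has been
  exercised unchanged at larger n.
- Only d ∈ {2, 3} coordinates are supported; arbitrary user kernel matrices
  are out of scope because the linear-time algebra requires the low-rank
  projection structure.
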