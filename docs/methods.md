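# Methods

## The statistic

`towcm` tests whether a set of M genetic variants in a region (a gene or
pathway) is associated with any linear combination of K correlated
quantitative traits measured on n unrelated individuals. Genotypes are
additively coded (x ∈ {0, 1, 2}); traits are continuous.

For a fixed trait-weight vector w, the combination Yw is regressed on all
M variants jointly and H₀: β = 0 is tested with the score statistic

    S(w) = n · wᵀYᵀPX (XᵀPX)⁻¹ XᵀPY w / (wᵀYᵀPY w),

where P = I − (1/n)11ᵀ centers columns (we never materialize P; columns
are demeaned in O(nq)). The test statistic is the maximum of S(w)/n over
all w. Writing D = YᵀPY = LLᵀ (Cholesky) and
A = YᵀPX (XᵀPX)⁻¹ XᵀPY, the maximum T is the largest eigenvalue of
C = L⁻¹AL⁻ᵀ, attained at w° = L⁻ᵀc with c the top unit eigenvector of C.
Because A is D compressed through the orthogonal projector onto the
column space of PX, A ⪯ D and hence 0 ≤ T ≤ 1. T is invariant to
per-column shifts, variant rescaling, joint row permutation, and (with no
ridge) any invertible linear recombination of the traits.

With a single trait and a single variant and mutually independent traits,
the maximizing weight has the closed form w_k = xᵀPy_k / (y_kᵀPy_k) — the
trait–variant correlation divided by the trait's (centered) variance — so
the method up-weights traits that are strongly associated and/or have low
variance. This serves as an independent check on the eigen-solution.

### Ridge stabilization

Strongly correlated traits make D ill-conditioned or singular. Policy
`auto` (default) adds λ₀I with λ₀ = 1/n when the raw Cholesky fails or
when D's smallest eigenvalue is below 1e−10 times its largest; `always`
and `never` are exposed for testing and for the exact generalized-
eigenvalue oracle. When the ridge is applied, the same adjusted D is used
in both the maximization and the reported ratio, so T ≡ λ_max(C) exactly
and the [0, 1] range is preserved. (Using the raw D only in the final
ratio would break that identity with no statistical benefit.)

Degenerate top eigenvalues are resolved deterministically: among
eigenvectors tied within 1e−12, each is sign-fixed (first nonzero
component positive) and the lexicographically largest is taken. T itself
is unaffected by the choice.

### Collinear variants

Variants whose centered columns are numerically linearly dependent
(pivoted-QR rank detection, relative tolerance 1e−10) are dropped
deterministically and reported, rather than silently absorbed by a
pseudo-inverse, which would change the statistic. Monomorphic variants
are removed before testing.

## Covariates and inference

Covariate adjustment regresses every trait and every variant column on an
intercept plus all covariates (OLS) and replaces them by their residuals.
The statistic is then computed on residuals throughout.

T has no usable asymptotic null distribution, so p-values come from
permutation: rows of the residualized genotype matrix are shuffled
(equivalently, the trait rows by the inverse permutation — identical
cross-products, cheaper), the full statistic *including re-maximized
weights* is recomputed per shuffle, and p = (1 + #{T_b ≥ T_obs})/(B + 1).
Freezing the observed weights across permutations would bias p downward,
since the observed maximum would be compared against non-maximized
replicates. Residualization is done once, before permuting: under H₀ the
residualized genotype rows are exchangeable up to O(p/n) edge effects,
and the alternative (re-residualizing inside every permutation) is B
times more expensive for no measurable calibration gain at the sample
sizes studied (the calibration tests bear this out).

The adaptive ("step-up") schedule runs permutations in increasing stages
(e.g. 300, then 1000, then more) and stops early when the one-sided 99%
Clopper–Pearson lower bound on the exceedance probability lies above the
significance level of interest: such a gene can no longer become
significant, so further permutations are wasted. A gene whose observed
statistic exceeds all permuted values always proceeds through every
stage. Fixed-B testing is the single-stage special case and both share
one seeded permutation stream, so results are bit-identical across runs
given (inputs, seed, B).

## Comparators

- **MANOVA** — the multivariate linear model of all (residualized) traits
  on all (residualized) variants, jointly testing every variant
  coefficient with Wilks' Λ and Rao's F approximation (statsmodels'
  multivariate machinery; for K = 1 this reduces to the overall
  regression F-test, which we compute directly).
- **minP** — each trait is tested separately with the K = 1
  specialization of the score statistic above, all traits sharing one
  permutation stream; the reported p-value is min(1, K·min_k p_k), i.e.
  the Bonferroni rule that makes "compare to α" equivalent to the α/K
  per-trait threshold. A permutation null for the minimum itself is
  deliberately not used, matching how such comparisons are usually run.
  Note the single-trait statistic here weights variants uniformly (it is
  this package's own statistic with K = 1), not a variant-weighted
  single-trait test; minP power numbers are therefore indicative, not a
  reimplementation of any specific published single-trait method.

No ordering between the minP and TOW-CM p-values holds in general; only
calibration is asserted in tests.

## Synthetic data

The generator emulates the study design used to validate the method:

- **Genotypes.** Target MAFs: `M_common` = 8 draws uniform on
  (0.05, 0.5) and `M_rare` = 40 draws from Beta(0.5, 8) truncated to
  (0.001, 0.05) — a rare-skewed, exome-like spectrum standing in for an
  empirical haplotype pool. Two haplotypes per individual are drawn with
  independent loci by default (an optional first-order Markov mode
  induces adjacent-locus LD with correlation ≈ λ_LD); their sum gives
  the additive score. Real genes have block-wise LD that neither mode
  fully reproduces, so calibration results transfer but fine-grained LD
  effects on power do not.
- **Traits.** y_k = 0.5·z₁ + 0.5·z₂ + η_k + ε_k for K = 4 traits, with
  z₁ ~ N(0, 1), z₂ ~ Bernoulli(0.5), and error rows multivariate normal
  with unit variances and compound-symmetry correlation of magnitude
  |ρ| ∈ {0.2, 0.5, 0.8}. Correlation signs use the rank-one pattern
  Σ_kl = s_k·s_l·|ρ| with random s ∈ {−1, +1}^K, which is congruent to
  the all-positive compound-symmetry matrix and therefore positive
  definite for any sign draw — an arbitrary per-entry sign assignment
  would not be.
- **Genetic effects.** One random common variant and a fraction
  (default 20%) of rare variants are causal:
  η_k = β_ck·x_c + Σ_j β_kj·x_j for the first `n_assoc` traits, η_k = 0
  for the rest. Total heritability h is split across associated traits
  via normalized Uniform(0, 1) draws (fresh per replicate by default;
  `freeze_t` holds one draw fixed across replicates). Effect sizes are

      β_ck  = sqrt( h_k / (var(x_c)·(1 − h_k)·(1 + R)) )
      |β_kj| = sqrt( h_k·R / (var(x_j)·(1 − h_k)·n_c·(1 + R)) )

  so the common variant carries 1/(1+R) of h_k and the rare set carries
  R/(1+R); the default R = 0.5 gives the 2:1 common : total-rare split.
  Using each rare variant's own genotype variance in the denominator
  (switchable to the common variant's variance via `eq8_variance`)
  makes the rare:common heritability ratio exactly R by construction.
  An alternative reading — the common variant carrying twice the
  heritability of *each single* rare variant — is not the default and
  not implemented. Heritability is coded relative to genetic-plus-error
  variance: Var(η_k)/(Var(η_k) + 1) = h_k, with the covariate
  contribution excluded from the denominator; simulation tests verify
  this accounting to Monte-Carlo precision. A causal variant's effect
  sign is positive ("risk") for a fraction `risk_fraction` of the
  causal set (common + rare) and negative for the rest.

## Experiment scales and numerics

The full-scale published calibration used 10,000 replicates with 10,000
permutations per test. The packaged experiments default to desk scale:
1,000–2,000 replicates with a 300 → 1000 step-up schedule, which resolves
levels down to 0.01 and keeps a complete type-I-error cell in minutes on
one core; binomial 95% intervals are reported with every estimate, and
cells whose level is at or below 1/n_reps are flagged as underpowered
rather than asserted. Permutations are evaluated in vectorized chunks:
row-shuffling genotypes leaves XᵀPX, YᵀPY and the ridge decision
unchanged, so each permuted statistic costs one n×M×K contraction and a
K×K eigendecomposition.

All "within tolerance" comparisons use relative 1e−8 unless stated.
Master seeds spawn independent per-replicate child seeds
(`numpy.random.SeedSequence`), recorded in experiment outputs; every
result is reproducible bit-for-bit from (inputs, seed).

## Known limitations

- Binary or survival traits, related samples, and kinship adjustment are
  out of scope; traits are assumed continuous and individuals unrelated.
- No asymptotic p-value for T; permutation cost is the price of the
  maximized statistic (mitigated by the step-up schedule).
- VCF input is GT-based biallelic only; multi-allelic records are
  skipped, dosage fields are not read.
- The Bonferroni minP comparator is conservative under strong trait
  correlation; that conservatism is visible in its calibration tests.
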