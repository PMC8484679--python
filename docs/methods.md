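# Methods

## The statistical model

The unit of analysis is a species-by-trait table aligned to a rooted
phylogeny with branch lengths. Under Brownian motion the among-species
covariance of a trait is σ²·**C**, where C(i,j) is the root-to-MRCA path
length of tips i and j and the diagonal holds root-to-tip depths. Pagel's
λ multiplies the off-diagonal of **C**, interpolating between full
phylogenetic dependence (λ = 1) and independence (λ = 0); this one-knob
family absorbs a range of intermediate dependence patterns, including ones
that resemble Ornstein–Uhlenbeck shrinkage, without fitting a second
process.

### PGLS with ML λ

For a regression y = Xb + e with e ~ N(0, σ²C_λ), the coefficients and σ²
have closed forms at fixed λ, so the likelihood is profiled down to one
dimension and maximised on [0, 1] by an 11-point grid followed by bounded
scalar search (tolerance 1e-6 on λ). The grid guarantees the reported
optimum dominates both endpoints; ties within 1e-8 log-units resolve to
the smaller λ. On ultrametric trees C and C_λ share eigenvectors, so the
whole profile costs one eigendecomposition; non-ultrametric trees use a
Cholesky factorisation per λ.

Two σ² conventions coexist deliberately:

- `sigma2_ml` = RSS_w/n (whitened residual sum of squares over n) enters
  the reported log-likelihood — λ is estimated by ML;
- standard errors, t and p use RSS_w/(n−k) on n−k degrees of freedom, the
  standard GLS small-sample convention. This makes the λ = 0 (or star
  tree) fit coincide with OLS exactly, which is both the sensible limit
  and a sharp correctness check.

REML is exposed (`method="reml"`) for comparison; ML is the default and
the convention used throughout the pipeline.

Adjusted R² is computed on the whitened scale: R² = 1 − RSS_w/TSS_w with
TSS_w from the GLS intercept-only fit under the same C_λ̂, then
1 − (1−R²)(n−1)/(n−k−1). The quantity is reported for comparability;
there is no single canonical GLS R².

p values are two-sided t with no multiple-testing adjustment, matching
how such comparative tables are conventionally reported. Missing data are
handled by casewise deletion per model (the reported N varies by model),
or by multiple imputation (below).

Branch-length units are irrelevant to inference: rescaling the tree by k
rescales σ̂² by 1/k and leaves λ̂, t and p unchanged (tested).

### Phylogenetic multiple imputation

Stacking the n×p trait matrix row-major, the joint model is

    vec(X) ~ N(1_n ⊗ a,  C_λ ⊗ R)

with per-trait root means a, a p×p cross-trait Brownian rate covariance R,
and a single common λ (the simplest defensible reading; a per-trait λ
vector is accepted by the conditioning step, but the fitter estimates only
the common λ). Parameters are estimated by maximising the observed-data
likelihood: EM over (a, R) at fixed λ — the M-step is the complete-data
GLS update plus the usual trace correction from the conditional covariance
of the missing cells — nested in a bounded search over λ (tolerance 1e-3;
λ̂ precision matters little for imputation accuracy). R is floored at a
relative eigenvalue of 1e-10 to keep the next E-step factorisable; a
perfectly collinear trait pair therefore shows an estimated correlation
just below 1.

Imputation then conditions the missing block on all observed cells exactly
(Schur complement of the joint covariance): every missing cell gets a
conditional mean and variance, with conditional variance never exceeding
the marginal model variance. m completed tables (default 10) are drawn
with independent normal draws at those per-cell moments — deliberately
"improper" imputation without parameter-uncertainty draws, matching
standard phylogenetic-imputation practice — each table is analysed
separately, and parameters are pooled as mean ± sample SD across the m
fits. Rubin's rules (within + (1+1/m)·between variance, t on Rubin's df)
are available as a non-default option.

Species observed for only a subset of traits (auxiliary taxa) enter the
model fit and the conditioning but not the regressions. This mirrors how
comparative studies pad the imputation model with extra literature species
to pin down cross-trait covariances; without them, covariances between
sparsely co-observed variables are estimated from few species, and the m
completions jointly inherit that sampling noise — the main driver of
anti-conservative pooled inference under heavy missingness.

What is imputed matters as much as how. The pipeline's complete mode
imputes the *measured* quantities — the six life-history traits on the
natural-log scale plus the three selection effect sizes (nine variables)
— and re-derives the composite indices (SSD, gametic biases) per completed
table. Imputing composites directly is supported but discouraged: a
five-input composite is missing whenever any input is, so its cross-trait
covariances rest on a much smaller joint support and pooled tests on null
predictors become markedly anti-conservative. Care scores are never
imputed, and models involving care use only species exhibiting some care.

The leave-one-out reliability check masks each observed cell in turn and
recomputes its conditional mean given everything else. By default model
parameters are fitted once and re-used per deletion (a rank-style identity
on the observed-block precision makes all deletions one matrix inverse);
`refit=True` refits per deletion, the exact but n-times costlier reading.

## The synthetic-data generator

The generator emulates a 64-species cross-taxon compilation:

- **Tree**: pure-birth (Yule) with rate 1, built forward with an extra
  exponential tail so all pendant edges are strictly positive; a Kingman
  coalescent is available. Both are ultrametric, like a timetree.
- **Life-history traits**: six log-scale traits (male/female body mass,
  male gamete size, female gamete mass, testis mass, clutch size) drawn
  from the λ-Brownian model with λ = 0.8, unit Brownian rate and pairwise
  cross-trait correlation 0.5 — log-normal traits spanning orders of
  magnitude with strong but imperfect phylogenetic signal, as real
  compilations show. Root means (≈500 g adult masses, ≈1 g eggs, ≈5 g
  testes, ≈4 eggs/clutch) set realistic scales; they cancel in every
  log-ratio index.
- **Selection effect sizes**: a latent male-care fraction ~ Beta(2, 2) per
  species drives the target sex difference in selection,
  effect·(care − ½) plus phylogenetically correlated noise (λ = 0.5,
  marginal SD 0.3); per-sex (mean, SD, n) summaries of reproductive and
  mating success are constructed to realise the target lnCVR exactly, with
  per-sex sample sizes 20–50 and baseline CV 0.6. The default effect is
  −1.0 — a strong negative care→selection association, the direction the
  comparative evidence reports. Gametic traits are generated independently
  of the selection indices, so every gamete→selection effect is null by
  construction.
- **Care**: each species exhibits care with probability 37/64 (the
  observed fraction in the emulated compilation); no-care species receive
  no care score and are excluded from care models.
- **Missingness**: missing-completely-at-random with exact per-column
  counts round(rate·n); default rates are the emulated compilation's
  (31% female mass, 20% male mass, 48% testis mass, 36% male gamete size,
  31% female gamete mass, 27% clutch size, 14% ΔI, 7% ΔIₛ, 23% Δβ_ss).
  Care is never masked. Original values are retained for recovery tests.
- **Auxiliary species**: optional extra tips observed for a subset of
  columns only, emulating the literature padding described above.

What the generator does **not** emulate: structured (non-random)
missingness, measurement error in the per-sex summaries, non-Gaussian
trait distributions beyond log-normality, fossil (non-ultrametric) tips,
or trait evolution beyond Brownian+λ (no OU simulation). Tests passing on
this generator show the machinery is correct under its own model; they do
not certify robustness to model misspecification in real data.

## Numerical choices

- All logarithms are natural, including the size-dimorphism and gametic
  indices (the lnCVR definition forces natural logs; adopting them
  everywhere keeps the indices commensurable).
- Sample (n−1) variance everywhere a variance is computed from
  individuals.
- The lnCVR small-sample correction 1/(2(n_m−1)) − 1/(2(n_f−1)) is ON by
  default and cancels at equal sample sizes.
- Care-score bins: 0 iff exactly 0% male care, 4 iff exactly 100%;
  (0, 33⅓], (33⅓, 66⅔], (66⅔, 100) map to 1, 2, 3, with boundary percents
  in the lower bin. The published five-point scale lists "77–99%" for
  bin 3; only 67–99% partitions the interval, so that reading is used.
- Index functions raise on invalid input (non-positive sizes, zero SDs,
  constant mating success) rather than returning NaN; NaN appears only as
  the explicit missing-value marker in tables.
- Zero-length branches are accepted (identical-covariance tips); negative
  lengths are rejected; polytomies are true multifurcations.
- Degenerate EM/conditioning cases raise typed errors (unidentifiable
  trait, singular observed block, incompatible pooled fits).

## Problem sizes in the verification battery

The acceptance script and test suite simulate at the sizes that make each
property sharp while staying desk-scale: 200 random instances (n ≤ 15) for
the dense-GLS oracle, 100 for the OLS limit, 100 replicates per λ on
200-tip trees for λ recovery, 1000 zero-slope replicates at n = 64 for
type-I calibration, all tips×traits ≤ 12 shapes for conditioning
equivalence, one 64-species 9-trait table at cross-trait correlation 0.9
for the leave-one-out bar, and 50 end-to-end replicates (64 species,
m = 10) for directional recovery of the built-in care effect.

## Known limitations

- The care score is treated as a continuous variable in PGLS, replicating
  common comparative practice; an ordinal model would be more principled.
- Mean ± SD pooling of p values across completions has no exact reference
  distribution; with heavy missingness and no auxiliary species the
  pooled tests on null predictors are mildly anti-conservative (the
  Rubin option mitigates this at the cost of departing from the
  conventional reporting format).
- How Δβ_ss is reduced to per-sex (mean, SD, n) summaries upstream is the
  caller's responsibility; the package computes Hedges' d from whatever
  summaries are supplied.
- A published formulation of the gametic indices states both that positive
  values indicate male bias and that they indicate female bias; the
  algebra of the formulas (positive = relatively larger male investment)
  is followed here, and the contradiction is noted rather than silently
  resolved.
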