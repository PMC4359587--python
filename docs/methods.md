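# Methods

## Model and test

The unit of analysis is a metabolite-set: a group of MS features (unique
m/z + retention time) tested jointly as one hypothesis. For a set
measurement *x* ∈ (ℝ⁺∪{0})^p and binary group label *y*, the model is

    logit Pr(y = 1) = β₀ + f(x),

with *f* a centered smooth function in the RKHS generated by the chosen
kernel. H₀: *f* = 0 means the set is not differentially expressed. The
null model is intercept-only, so its MLE is closed-form: μ̂₀ is the case
fraction and β̂₀ = logit(μ̂₀).

The score statistic at bandwidth ρ is Q(ρ) = (y − μ̂₀1)ᵀ K_ρ (y − μ̂₀1).
Its null moments account for the estimated intercept through the
centering projection H = I − 11ᵀ/n: with v = μ̂₀(1 − μ̂₀) and A = H K H,

    μ_Q = v · tr(A),    σ_Q² = 2 v² · tr(A²).

This is the Gaussian working-model variance of the quadratic form. It is
validated in the test suite against a Monte-Carlo oracle — Q averaged
over 10⁵ i.i.d. Bernoulli(μ₀) relabelings, each with its own refitted
intercept — under which the mean identity is exact. The Bernoulli
fourth-cumulant correction to σ_Q² is omitted; at μ₀ near 1/2 the
correction is negative, so the working-model σ_Q is slightly
conservative (it shrinks |S|).

## Sup-bandwidth p-value bound

The bandwidth ρ does not enter the model under H₀, so no single S(ρ) has
a null distribution to calibrate against; the test statistic is
sup_ρ S(ρ) over ρ ∈ [L, U]. The p-value is bounded by

    p ≤ Φ(−M) + V · exp(−M²/2) / √(8π),

with M the profile maximum over the grid and V = Σ_j |S(ρ_{j+1}) −
S(ρ_j)| its total variation (endpoints included). The exponent is −M²/2:
the bound combines the normal tail at the maximum with an expected
upcrossing count, and a positive exponent would diverge for large M. The
bound is capped at 1; underflow is reported as the smallest positive
float.

Grid: 200 evenly spaced bandwidths on [10⁻³, 10³] by default, a
log-spaced alternative via `BandwidthGrid(spacing="log")`; both are
recorded in output metadata. Grid points where the kernel is
uninformative (σ_Q numerically zero, e.g. a constant Gram matrix) are
dropped from the profile and logged, with M and V computed over the
surviving points in grid order; a profile that loses every point raises
`DegenerateKernelError`.

**Scope of the bound.** This is a *tail* bound. At small bandwidths the
Gram matrix tends to the identity, where S(ρ) takes the same value for
every relabeling of the samples; the permutation distribution of the sup
therefore has a sharp lower edge, and a dataset carrying no
kernel-visible signal sits at that edge with an exact p-value of ~1
while the bound evaluates to ~0.6–0.8. Conversely, at n = 20 the extreme
upper tail of the exact permutation distribution of the sup is heavier
than the Gaussian-process approximation, so bounds below ~10⁻³ should be
read as "very small" rather than literally. Neither regime affects
rejection decisions at conventional levels, but the mid-range
conservativeness does bias Storey's π̂₀ downward when applied to these
p-values (see below).

## Kernels

Both bespoke families are bounded in [0, 1], symmetric, and positive
semidefinite (verified numerically over random zero-inflated datasets in
the test suite rather than re-deriving the analytic proof).

- **Distance-based**: d²(x, y) = #{i: presence differs} + Σᵢ(xᵢ − yᵢ)²;
  k = exp(−d²/ρ). The presence count is a metric on {0,1}^p and the
  Euclidean part a metric on ℝ^p, so d is a metric on the product; the
  triangle inequality is property-tested on random triples. When no
  zeros occur the penalty vanishes and the kernel *is* the Gaussian.
- **Stratified**: k(x, y) = 0 unless x and y share a presence pattern;
  within a stratum a Gaussian kernel is evaluated on the full vectors.
  Coordinates zero in both samples contribute nothing to the sum, so
  this equals the Gaussian on the present coordinates; the full-vector
  form is used because it is unambiguous and needs no index bookkeeping.
- **Gaussian**: exp(−‖x − y‖²/ρ), the reference family.

Per-feature normalization (dividing each feature's nonzero entries by
the standard deviation of those entries) is available via
`normalize=True` but off by default: it matters when abundances are
large enough for the quantitative term to swamp the unit presence
penalty, which is not the case for the simulated studies here.

Kernel values are never thresholded; underflow of exp(−d²/ρ) to 0 at
tiny bandwidths is accepted (the Gram matrix then approaches the
identity, which is handled like any other bandwidth).

## Feature grouping

Features are nodes; an edge joins i and j when |corr(i, j)| > c
(strictly), and the feature-sets are the connected components. Pearson
(default) or Spearman correlations; default c = 0.95, always settable.
Connectivity rather than all-pairs correlation is deliberate — requiring
every pair in a set to correlate fragments pathways into tiny sets.
Zeros enter the correlation as ordinary values by default (an option
restricts each pair to jointly-present samples); constant features get
correlation 0 with everything and so always end up as singletons, which
avoids NaN propagation and cannot spuriously merge sets. Raising c can
only refine the partition, a property the tests check directly.

## FDR and FWER

Storey's estimator with tuning parameter λ (default 0.7):

    π̂₀(λ) = #{pᵢ > λ} / (M(1 − λ)),  capped at 1,
    FDR̂(c) = M π̂₀ c / #{pᵢ ≤ c},

with cutoffs spanning (0, 0.05] by default and cutoffs rejecting nothing
excluded. Rejection counting uses p ≤ c; the Bonferroni FWER variant
counts p < α/M (strict). Validity of FDR̂ rests on null p-values being
roughly uniform; a KS diagnostic on the p-values above 0.05 is reported
but never enforced. Note the sup-bound p-values of the kernel test are
conservative and concentrate below 1, so π̂₀ estimated from them is
biased downward; on data where the diagnostic flags non-uniformity the
estimated-FDR curve should be read comparatively, not calibrated.

For simulations the ground truth is known, so no estimator is needed:
`true_fdp_rejections` returns the largest rejection count over cutoffs
at observed p-values whose realized false-discovery proportion stays at
or below the level, with tied p-values rejected as a block and an
"unattainable" flag when no nonempty rejection set qualifies.

## Simulated studies

Complete data follow the linear fixed-effects model

    X_ijkl = S_i + M_ij + G_ik + Err_ijkl

- 1000 metabolite-sets of 1–15 metabolites (discrete uniform), 10
  samples per group;
- S_i ~ Uniform(10, 14): set baseline (arbitrary abundance units);
- M_ij ~ Uniform(−2, 2): metabolite offset within its set;
- G_i1 ∈ {−1, −2} ("low") or {−3, −4} ("high"), split equally at random
  among the differential sets (the first 25% or 50% of sets); G_i1 = 0
  for null sets and G_i2 = 0 for identifiability;
- Err ~ N(0, σ_i²) with σ_i ~ Uniform(0.5, 1.0) per set. The error-SD
  distribution is the one generative parameter with no canonical value;
  this range keeps set-average noise (σ_i/√n_i at n̄ ≈ 8) small relative
  to the low effects, giving the near-complete power regime the
  benchmark targets. It is the main uncertainty of the whole generator.

Missingness is then detection-limit censoring: exactly
⌊proportion · #entries⌋ of the globally smallest entries (20% or 40%)
are set to 0. Censoring is performed on the complete matrix as a whole,
so low-abundance metabolites lose many or all samples and case samples
of differential sets (pushed down by the negative group effect) lose
more than controls — the presence layer itself carries group signal.

What the generator does *not* emulate: correlation between metabolites
within a set beyond the shared S_i (real adduct/fragment groups are
nearly collinear), skewed or heteroscedastic abundance distributions,
batch effects, and missingness from peak-picking failures unrelated to
abundance. Passing benchmarks therefore demonstrate correct behavior
under an idealized additive model, not performance on real studies.

## Benchmark

One study per scenario; per-set p-values from four methods — Kernd
(distance kernel), Kerns (stratified kernel), T and Wilcox (pooled
t-test and two-sided Mann–Whitney rank-sum on the set-averaged
abundances, zeros included) — and rejection counts at true FDP 0.05.
The rank-sum test is used where "Wilcoxon" is named: the comparison is
between two independent groups, so the signed-rank variant does not
apply. It is exact for small untied samples and normal-approximated
with tie correction otherwise. A fully censored set (all samples
identical) is uninformative at every bandwidth; the benchmark assigns it
p = 1 rather than propagating the degeneracy error.

At 1000 sets a scenario runs in seconds: pairwise distances are computed
once per set and the whole bandwidth grid is evaluated as one vectorized
exponential map. With low effect and 20% missingness the distance
kernel, t and rank-sum baselines all recover essentially every
differential set. The stratified kernel does not: under cell-level
censoring, borderline metabolites are present in some samples and absent
in others, the 2^p strata fragment into singletons, the Gram matrix
collapses toward the identity, and the affected sets become untestable —
the fragmentation failure mode of stratified kernels at large p. This
is a real limitation of the stratified construction on data whose
missingness varies within feature, and the reason the distance-based
kernel is the default.

## Numerical choices

- σ_Q degeneracy threshold: 10⁻¹² · n (absolute, on the unit-bounded
  kernel scale).
- Censoring ties are broken by entry order (stable argsort), making
  studies bit-identical for a fixed seed.
- p-values are written with 6 significant digits; p_upper is floored at
  the smallest positive float, never at zero.
- Zero-variance comparisons: t-test on identical groups returns p = 1;
  rank-sum on an all-tied sample returns p = 1.
- Partition output order is canonical (sets by smallest member, members
  sorted), so feature order cannot change results.

## Known limitations

- The sup bound is conservative in the mid-range and approximate in the
  extreme tail at small n (see above); it is an upper bound where
  rejection decisions happen.
- The stratified kernel degrades with set size under within-feature
  missingness (see Benchmark).
- Storey π̂₀ applied to conservative bound p-values underestimates the
  null fraction.
- The grouping threshold c = 0.95 is a pragmatic default for
  adduct/isotope redundancy, not an inferred quantity.
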