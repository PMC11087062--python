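# Methods

## Setting

A finite population of `N` primary sampling units (psus) of sizes
`M_1..M_N` is sampled in two stages: `n` psus by SRSWOR or by randomized
systematic probability-proportional-to-size (IPPS) selection, then `m_i`
elements per selected psu by SRSWOR, independently across psus.  The package
estimates a population total through the Horvitz–Thompson (HT) estimator and
general estimating-equation parameters (mean, distribution function,
quantiles) through the weighted sample estimating equation, and provides
analytic and bootstrap estimators of their design variance.

Throughout, `f1 = n/N`, `f2i = m_i/M_i`, `π_i` and `π_{k|i}` are first- and
second-stage inclusion probabilities, `t̂_i = (M_i/m_i) Σ_k y_ik`,
`s_t²` is the sample variance of the `t̂_i`, and `s_yi²` the within-psu
element variance.  The textbook SRSWOR/SRSWOR variance estimator is

    V̂ = N²(1−f1) s_t²/n + (N/n) Σ_i M_i² (1−f2i) s_yi²/m_i .            (*)

## Synthetic populations

`generate_population(N, mean_psu_size, rho, seed)` draws cluster sizes
`M_i ~ Poisson(mean_psu_size)` (zero draws redrawn — an empty cluster is
meaningless), a cluster effect `x_i ~ N(0, rho/(1−rho))` and element errors
`ε_ij`, and sets `y_ij = 10 + x_i + ε_ij`.  The stream order is sizes →
cluster effects → errors, from a single seeded generator, so populations are
bit-reproducible.

The generator's documented default centres `ε_ij` at `M_i`.  The simulation
harness (`SimulationConfig`, `study_population`) instead uses mean-zero
errors, `ε_ij ~ N(0,1)`, and this is a deliberate design decision: with
errors centred at the cluster size, psu totals grow like `M_i²`, the design
variance of the estimated total inflates by two orders of magnitude, and
confidence-interval lengths and variance-estimator CVs leave the range any
survey comparison of this kind reports.  The mean-zero model produces totals
`t_i ≈ 10·M_i + M_i x_i`, an intraclass correlation of `rho` after removing
the size component, and the familiar metric ranges; it is the model all
package-level results refer to.  The switch `mean_zero_errors` selects
between the two.

What the generator does *not* emulate: stratification, nonresponse, unequal
within-psu selection, skewed or heavy-tailed outcome distributions, and
covariates.  Passing tests show the procedures track their design-based
calibration targets under a well-behaved Gaussian random-effects population;
they do not certify behaviour under informative sampling or extreme outcome
distributions.

Finite-population parameters: the total `t_y = Σ_i Σ_k y_ik` and the
left-continuous inverse-CDF quantile (smallest value whose CDF mass reaches
τ; ties kept as data).  The same left-inverse convention is used for the
weighted sample quantile, which makes it the exact root-crossing of the
non-smooth estimating function `u(y;θ) = I(y≤θ) − τ`.

## Designs

* SRSWOR/SRSWR/Poisson sampling are thin wrappers over the numpy generator.
* IPPS uses randomized systematic selection: a uniformly random permutation
  of the units followed by a systematic pass over the cumulated `π_i` scale
  with a uniform random start.  The permutation is what gives every pair of
  units a positive joint selection probability (verified by exhaustive
  enumeration over permutations × start intervals in the tests).  The size
  measure is `M_i`, so `p_i = M_i/M_0` and `π_i = n p_i`; units with
  `π_i > 1` raise an error rather than being silently taken with certainty.
* `draw_two_stage` populates every inclusion probability and design weight
  the estimators need; weights are `w_k = (π_i π_{k|i})⁻¹`.

## Analytic variance estimators

The general double-sum estimator takes caller-supplied `Δ_ij/π_ij` matrices
(available in closed form for SRSWOR via `srswor_joint_matrices`; an
explicit unsupported-design error otherwise) and reduces algebraically to
(*) under SRSWOR/SRSWOR — asserted to 1e−10 in the tests.  The simplified
estimator keeps only the first-stage double sum (bias always negative); the
with-replacement estimator is the standard PPSWR form
`(1/(n(n−1))) Σ_i (t̂_i/p_i − t̂_wr)²` with `t̂_wr` the mean of the
`t̂_i/p_i`; it is the "textbook" comparator under IPPS, where exact joint
probabilities are impractical.

Quantile variance (comparator only): Woodruff linearization — apply the
design variance estimator to `z_ik = I(y_ik ≤ θ̂) − τ`, scale by `M0⁻²`, and
divide by the squared density at `θ̂` estimated with a Gaussian kernel and
Silverman's bandwidth on the weighted sample.  Degenerate samples (no
spread) raise an error.  This estimator is a documented stand-in: the
reference comparison names a linearization row without defining it.

## Bootstrap procedures and their calibration

All methods implement one interface: `method(sample, estimator, cfg, rng)
-> ReplicateSet` of B replicate estimates; `bootstrap_variance` applies the
`(B−1)⁻¹` replicate variance (for the double bootstrap, the mean over outer
iterations of inner replicate variances).  Every source of randomness flows
through an injected generator, so replicates are reproducible and any
simulation cell can be re-run in isolation.  Five methods are calibrated so
that the bootstrap variance of the HT *total* under SRSWOR/SRSWOR equals (*)
— exactly, not asymptotically.  The calibration algebra, verified by exact
enumeration in `tests/_oracles.py`:

**Rescaled bootstrap (`rao_wu`).**  Draw n psus SRSWR; within each drawn psu
draw `m_i* = m_i` elements SRSWR; form pseudo-values

    ỹ_ik = Ȳ̂ + [n(1−f1)/(n−1)]^{1/2} (t̂_i*/M̄0 − Ȳ̂)
                + [m_i* f1 (1−f2i*)/(m_i*−1)]^{1/2} (M_i* y_ik*/M̄0 − t̂_i*/M̄0),

with `M̄0 = M0/N`, `Ȳ̂ = t̂_y/M0`, and `t̂_i*` the *original* psu-total
estimate of the drawn psu.  The replicate statistic applies the original
estimator to the pseudo-values with per-element weight `(N/n)(M̄0/m_i*)` —
i.e. the psu size is replaced by the average size, because the pseudo-values
already carry the `M_i*/M̄0` scale.  Total-variance decomposition then gives
the first term of (*) from the psu draws and the second from the element
draws, exactly.  Because the rescaling acts on y-values, the method is
invalid for quantiles; requesting a non-smooth estimator warns and proceeds
(the failure mode is itself a result the harness reproduces: several hundred
percent relative bias for the median).

**Mirror-match (`mirror_match`).**  Concatenate `k_1 = n(1−f1*)/(n′(1−f1))`
independent SRSWOR draws of `n′` psus (`f1* = n′/n`), and within each drawn
psu `k_2i = N m_i (1−f2i*)/(n* m_i′ (1−f2i))` independent SRSWOR draws of
`m_i′` elements (`n* = k_1 n′`, `f2i* = m_i′/m_i`), with HT weights
`(N/n*)(M_i/m_i*)`.  Non-integer `k`'s are randomized between bracketing
integers with exact expectation.  Defaults mirror the sampling fractions:
`n′ ≈ f1·n`, `m_i′ ≈ f2i·m_i` (clamped to [1, ·−1]).  A census second stage
is copied verbatim rather than subsampled.

**Modified without-replacement pseudo-population (`bwo_sitter`).**  A fixed
pseudo-population replicates each sampled psu `k_1` times and each sampled
element `k_2i = round(M_i/m_i)` times; replicates redraw `n′` psus and
`m_i′` elements SRSWOR with HT weights `(ν/n′)(M_i′/m_i′)`, `ν = k_1 n`.
The classical integer matching conditions cannot hold exactly for arbitrary
samples, so the resample sizes are *solved* from the matching contract:
because the bootstrap design on the pseudo-population is genuine
SRSWOR/SRSWOR, its variance has the closed form (*) evaluated on the
pseudo-population, which is linear in `1/n′` (first stage) and in
`g(m_i′) = 1/m_i′ − 1/M_i′` (second stage).  `plan_bwo` therefore picks
`k_1 ≈ 1/f1` (increased until feasible), equates the second-stage term
per psu *conditionally on the realized first-stage size* by randomizing
`m_i′` between bracketing integers on the `g` scale, and then equates the
first-stage term by randomizing `n′` on the `1/n′` scale.  Since the HT
weights use the realized sizes, the replicate mean is the pseudo-population
total for every randomization outcome, so randomization contributes no
squared-mean term and the expected bootstrap variance equals (*) exactly —
enumeration confirms this to 1e−8 including both randomization layers.

**Bernoulli bootstrap (`bernoulli`).**  Per replicate, a donor pool of
`n−1` SRSWR psu draws; each original psu is kept with probability `p1`
(and then its elements are themselves kept/replaced with probability `p2i`
against a donor pool of `m_i−1` element draws) or replaced by a random
donor.  The keep probabilities are solved from the matching contract:

    p1  = 1 − (1−f1) / (2(1−1/n)),
    p2i = 1 − f1(1−f2i) / (2 p1 (1−1/m_i)).

Decomposing the replicate total over the donor pool, the keep indicators and
the donor picks gives replicate variance
`(N/n)²[2n(1−p1)σ_t² + p1 Σ_i v_i]` with `σ_t² = (n−1)s_t²/n` and
`v_i = 2 M_i²(1−p2i)(m_i−1)s_yi²/m_i²`; the stated probabilities make both
pieces equal the corresponding terms of (*).  Both probabilities stay in
[0,1] across the whole study grid.

**Bootstrap weights, half-sample form (`preston`).**  SRSWOR indicators
`δ_i` (n′ of n) and `δ_ik` (m_i′ of m_i inside selected psus) define

    w_ik* = {1 + λ1 (n/n′ δ_i − 1) + λ2i (n/n′)^{1/2} δ_i (m_i/m_i′ δ_ik − 1)} / (π_i π_{k|i}),

`λ1 = [n′(1−f1)/(n−n′)]^{1/2}`, `λ2i = [m_i′ f1 (1−f2i)/(m_i−m_i′)]^{1/2}`.
Defaults `n′ = ⌊n/2⌋`, `m_i′ = ⌊m_i/2⌋` keep all weights non-negative.
The replicate weights average back to the design weights and are exported in
the standard one-row-per-element bootstrap-weights file.

**Bootstrap weights, with-replacement form (`rwy`).**  `n′` SRSWR psu draws
with multiplicities `n_i*` give
`w_ik* = {1 + [n′/(n−1)]^{1/2}(n n_i*/n′ − 1)} / (π_i π_{k|i})`; `n′ ≤ n−1`
(default `n−1`) keeps weights non-negative.  Valid for smooth and non-smooth
statistics and for any first stage, but the replicate variance of the total
is exactly `N² s_t²/n` — the with-replacement form without the `(1−f1)`
correction — so the method carries a structural positive bias of roughly
`f1 s_t²/((1−f1)s_t² + second-stage share)` (≈ +23% at `f1 = 20%` under the
study conditions, ≈ +5% at 5%), which the harness reproduces.

**Pseudo-population double bootstrap (`chauvet`).**  Each outer iteration
builds a pseudo-population: within each sampled psu, every element gets
`⌊M_i/m_i⌋` copies and a without-replacement random subset of elements gets
one extra copy so the pseudo-psu size is exactly `M_i` (giving all elements
the same rounded count would distort pseudo-psu totals by up to
`(m_i/2)·ȳ_i`, an order of magnitude above the element scale, and flips the
sign of the method's small-sample bias); each (sample, pseudo-psu) pair is
duplicated `⌊1/π_i⌋` times and completed by Poisson sampling with
probabilities `1/π_i − ⌊1/π_i⌋`.  Inner replicates re-run the original
first-stage design on the pseudo-population (IPPS sizes re-derived from the
pseudo-psu sizes), and within each selected pseudo-psu take an SRSWOR
subsample of the duplicated elements with probability `π_i` or the original
subsample otherwise, weighting elements by `(M_i*/m_i)/π_i^boot` in both
branches.  The variance estimate averages the inner replicate variances over
`A` outer iterations (defaults A=10, B=50).  The method is consistent for
high-entropy designs but shows the known moderate negative bias at small
`f1`, which the harness reproduces under both first-stage designs.

## Monte Carlo harness

Study conditions: `N = 200` psus of mean size 50; ρ ∈ {0.1, 0.3} (one fixed
population per ρ, constant across all samples of a run); first stage SRSWOR
or IPPS with n ∈ {10, 40} (`f1` of 5% and 20%); `m_i = 5`; `K = 3000`
samples; `B = 500` bootstrap replicates (A=10 × B=50 for the double
bootstrap); 95% t-intervals with `n−1` degrees of freedom.  A `--reduced`
profile (K=500, B=200) serves quick runs.  Metrics per (method, parameter,
cell):

* relative bias `100·(mean(v̂) − V_MC)/V_MC`, where `V_MC` is the empirical
  variance of the K point estimates (for the median, of the K medians);
* CV `100·SD(v̂)/mean(v̂)` — the square-root convention, which is the one
  that produces CVs in the 19–46% range reported for totals;
* coverage and average length of `θ̂ ± t_{0.975,n−1}·se`, with the truth for
  the median being the finite-population median of the fixed population.

Method admissibility per design is enforced (the SRSWOR-calibrated methods
are rejected under IPPS).  Seeds: one master seed; population seeds and one
seed per (replicate, method, parameter) are derived by spawn-key splitting,
so cell metrics are bit-reproducible and invariant to the order in which
methods are evaluated.

Problem sizes in the shipped checks: the enumeration suite uses n = 2–3,
m_i = 2 samples (exact arithmetic); design unbiasedness uses K = 20 000
samples; the table-reproduction and signature checks use the full K = 3000 /
B = 500 cells, which complete in a few minutes on one CPU.

## Numerical choices

* Smooth estimating equations: bisection/Brent on an auto-expanding bracket,
  relative tolerance 1e−10; no sign change raises.
* Weighted quantiles: left-continuous inverse of the weighted CDF, ties to
  the smallest qualifying value (matches the sign-change definition of the
  non-smooth estimating function).
* Randomized integer brackets: `⌊x⌋ + Bernoulli(x−⌊x⌋)`, independent per
  replicate (and per outer iteration for the double bootstrap).
* Variance estimates are reported as non-negative by construction of each
  formula; degenerate cases (n < 2, undefined within-psu variances at
  non-census second stages) raise explicit errors.
* Population files round-trip through 12-significant-digit text.

## Known limitations

* Single-stage strata, three-stage designs, nonresponse adjustment and
  calibration of bootstrap weights, and variance estimation for imputed
  estimators are out of scope.
* Exact joint inclusion probabilities for randomized-systematic IPPS are not
  computed; IPPS analytic variance uses the with-replacement form.
* The modified pseudo-population constants are this package's own solution
  of the variance-matching contract; other resolutions of the (unspecified)
  modification exist and will differ at second order for nonlinear
  statistics.
* The rescaled-bootstrap median row is a documented failure mode, not an
  estimator anyone should use; its magnitude is sensitive to the
  pseudo-value conventions described above.
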