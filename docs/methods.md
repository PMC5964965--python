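# Methods

## Data model

One record per compound: EC50 (mol% carrier/lipid, the loading releasing
50% of vesicle-encapsulated chloride within 300 s), Hill coefficient n,
initial chloride-release rate k_ini (% s⁻¹, measured at 0.05 mol% loading),
the ALOGPs estimate of log P, HPLC retention time (min, an experimental
lipophilicity proxy), and optional substituent annotations (R4 ring
substituent, R5 enamine substituent, R6 substituent class). The packaged
43-compound table marks four retention times as missing ("not determined")
and flags one EC50 (compound 43) as imputed from its initial rate rather
than measured by Hill analysis. Missing is always representable and
distinct from zero; "n.d." is normalised to missing on load and never
stored as a string.

All logarithms are base 10, consistent with log P conventions; potency is
log10(1/EC50).

## Kinetic parameter extraction

Dose–response curves are fitted to the Hill form
y = ymax·xⁿ/(EC50ⁿ + xⁿ) by least squares, with ymax fixed at 100% by
default because detergent lysis defines complete release (fitting ymax is
an option). Efflux traces are fitted to y(t) = a − b·cᵗ with b > 0 and
0 < c < 1, and the initial rate is the closed form k_ini = −b·ln c.

Both fits use deterministic multi-start nonlinear least squares: 8 starts
on a log-spaced grid (EC50 starts spanning the loading range; decay-rate
starts spanning half-lives from span/50 to 5·span), ties broken by lowest
SSE then lowest EC50. The constraint c ∈ (0, 1) is enforced smoothly via
c = exp(−exp(θ)) and b > 0 via b = exp(β), so the optimiser runs
unconstrained. On noiseless traces the multi-start loop exits early once an
essentially exact fit (relative SSE ≤ 1e-18) is found. Degenerate inputs
(constant traces, all-zero responses, fewer than 4 distinct loadings or 5
trace points) are rejected up front.

EC50 imputation from k_ini uses an OLS calibration of log10(EC50) on
log10(k_ini) over records with both quantities measured (never imputed
ones, ≥ 3 required), back-transforming the prediction. The log–log form is
the package default because it reproduces the packaged dataset's one
imputed EC50 to 0.15%; semi-log and linear calibrations are selectable.

## Descriptor cleaning and screening

Cleaning removes columns in a fixed order: any missing value → incomplete;
not coercible to numeric → non-numeric; sample standard deviation ≤
threshold × |mean| (exactly constant columns always) → low variation. The
default threshold 1e-8 is deliberately conservative — effectively "constant
only" — because any stricter rule is a modelling choice the analyst should
make explicitly; the report lists every removed column by rule, and the
operation is idempotent.

Candidate lipophilicity descriptors are ranked by |Pearson r| against
measured retention times, pairwise-complete (records with missing RT are
dropped per candidate, 39 of the 43 packaged compounds remain), ties broken
by name.

## The parabolic model and enumeration

OLS fits go through statsmodels; confidence intervals are t-based with
n − k − 1 degrees of freedom at a fixed 95% level. Squared terms are named
derived columns ("ALOGPs-sq"), generated on demand so model specifications
stay name-based. Rank-deficient designs raise an error naming the collinear
terms. On the packaged dataset the two-term fit (all 43 records, including
the imputed EC50 — this is the variant that reproduces the published
coefficients) gives

    log10(1/EC50) = −0.5793 + 1.2036·ALOGPs − 0.1329·ALOGPs²,  R² = 0.6294,

with optimum log P = 4.527.

Enumeration fits every subset of candidate descriptors of size ≤ max_terms
(default 3; the cost is binomial in the column count, so four-term searches
should be run on a pre-selected candidate subset) and ranks by R²
descending with a lexicographic tie-break on term names, making the ranking
invariant to input column order.

## Stratified bootstrap

Strata are half-open bins on ALOGPs with default cut points (2.5, 5.0) —
low: 8 records, mid: 25, high: 10 on the packaged data. Each of the 999
resamples (default) draws with replacement within each stratum, preserving
stratum sizes exactly, so the high-leverage extreme-lipophilicity compounds
are present in every replicate. Intervals are plain 2.5%/97.5% percentiles
(numpy linear interpolation; no bias correction or acceleration). The
implementation solves the per-replicate normal equations in a single
batched operation; replicates with a numerically singular Gram matrix
(smallest eigenvalue ≤ 1e-9 × largest) are redrawn, counted, and capped at
10× the replicate budget. One generator is seeded once and index blocks are
drawn stratum-by-stratum in fixed stratum order, so results are a pure
function of (data, specification, seed).

Calibration, measured by this package's own tests: across 500 simulated
43-compound libraries at the default noise level, the 95% percentile
interval for the linear coefficient covers the truth ~93% of the time.

Boundary sensitivity on the packaged data (10 seeds, 999 resamples): cut
points (2.5, 5.0) give mean percentile bounds (0.85, 1.45) for the linear
coefficient; cut points (2.0, 6.0) — the edges of the range where the bulk
of the series lies — give (0.89, 1.47). The lower bound is the quantity
most sensitive to where the low-log P stratum boundary falls, because the
low stratum holds only ~8 compounds. The defaults are kept at (2.5, 5.0)
and are configurable (`--strata`).

## Subgroup models

Composite labels "R4.R5.R6" classify compounds; records with missing
annotations or an R5 outside {NH, NH-Ph} go to an explicit unclassified
bucket. Per-group quadratics are independent OLS fits, and groups with
fewer than 3 points are skipped, not fitted.

The shared-curvature model y = β₀ + aᵍ + β₁·x + β₂·x² keeps one curvature
for all groups — encoding the reading that curvature and optimum log P are
properties of the membrane — while group offsets aᵍ shift the parabola:

- **fixed_offsets**: group indicators under a sum-to-zero constraint, so
  β₀ is the cross-group mean intercept and offsets are deviations from it;
- **random_intercept**: aᵍ ~ N(0, σ²_b), estimated by profiling the REML
  criterion over the variance ratio λ = σ²_b/σ²_e: a 49-point log-spaced
  grid scan on λ ∈ [1e-8, 1e4] followed by golden-section refinement
  (deterministic, no random starts); offsets are returned as conditional
  means (BLUPs). The fit agrees with statsmodels MixedLM to ~1e-4 on the
  fixed effects in the cross-check test.

With a single group both variants reduce exactly to plain OLS with zero
offsets. The curvature is estimated from whatever records the caller
passes — the full classified set or one branch of it — so both "curvature
from everything, offsets per subset" and "curvature from the subset"
analyses are available by subsetting before fitting.

## Synthetic data

The generators exist so that every stage of the pipeline is testable with
a known answer, and they mirror the statistical model only — no physical
membrane-transport simulation. Traces are exact asymptotic curves plus
i.i.d. Gaussian noise; dose–response curves are exact Hill curves plus
noise; libraries plant a quadratic log10(1/EC50)–log P law (defaults:
intercept −0.58, linear 1.2, quadratic −0.13, noise sd 0.45 on the potency
scale — the scale of the measured series, yielding EC50s in roughly
0.003–0.35 mol% and fitted R² values centred in the 0.4–0.8 band), with
log P drawn stratified across low/mid/high thirds of [1.0, 7.5] so
high-leverage extremes always exist. Initial rates are generated
log-log-linear in EC50 (slope −1, sd 0.05 scatter) so the imputation path
is exercisable; decoy descriptors are rescaled standard normals,
uncorrelated with the response by construction. Noise is additive Gaussian
on the log-potency scale, consistent with least-squares fitting of
log10(1/EC50).

What passing tests on synthetic data do **not** show: real descriptor
matrices have correlated, heavy-tailed columns (the decoys here are
independent Gaussians); real potency noise need not be homoscedastic on the
log scale; and real subgroup memberships are confounded with lipophilicity
rather than assigned round-robin. Recovery results on synthetic libraries
are therefore necessary, not sufficient, evidence for behaviour on new
experimental series.

## Problem sizes and tolerances

Default problem sizes used by the tests and reproduction script: 999
bootstrap resamples (averaged over 10 seeds where a stochastic quantity is
reported), 500 simulated libraries for the coverage study, 200 Monte-Carlo
replicates for kinetic-fit bias checks, a 100-point (a, b, c) grid for the
noiseless initial-rate check (relative error < 1e-6). OLS results are
validated against explicit normal-equation solutions at 1e-10 relative;
exact constructions (noiseless inversions, collinear calibrations) are
checked at 1e-8 or tighter; published regression coefficients are checked
at printed precision (1e-3).

## Known limitations

- The packaged table carries no per-compound substituent annotations
  (only the two rare R5 variants are identifiable from the series
  description); subgroup analyses on the real series require a
  user-supplied annotation CSV, and the subgroup machinery is validated on
  constructed and simulated groups.
- Three- and four-descriptor models of the original analysis depend on
  external descriptor software output that is not redistributed here; the
  enumeration engine is validated against a brute-force oracle instead.
- The stratified-bootstrap lower bound depends visibly on the stratum cut
  points (see above); comparisons across studies should fix the boundaries
  explicitly.
- No descriptor computation (ALOGPs etc.), no structure parsing, no
  cross-validation (stratified resampling replaced it for this data shape),
  no PCA/PLS, no regularised regression.
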