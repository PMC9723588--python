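# Methods

`lakebrowning` asks one question of a site-by-taxon table collected along a
freshwater browning gradient: does bacterial community composition respond
*monotonically* to browning, or does it cross thresholds between
alternative community regimes?  Because field data cannot provide ground
truth for that question, the package is built around a synthetic community
generator with known thresholds; every downstream method is validated by
recovery of that truth.

## The synthetic community model

A site i has a browning value g_i drawn on an interval [g_min, g_max]
(defaults 0–12, in the spirit of a boreal-lake TOC range of a few tenths to
~13 mg C L⁻¹).  Its expected composition mixes two ingredients:

**Gradient-response taxa.**  Each taxon carries a response f(g): logistic
up or down (midpoint in the central 80% of the range, width 10–25% of the
range), Gaussian unimodal (optimum drawn from a truncated normal peaked
mid-gradient, so realized richness humps at intermediate browning), or a
step — a logistic with width 1% of the range whose location sits on a regime
threshold.  Amplitudes are log-normal(0, 1).  The default shape mixture is
0.20/0.20/0.45/0.15 (up/down/unimodal/step): nonmonotone responses dominate,
as they do along real browning gradients.

**Regime structure.**  Thresholds τ (defaults 3.0 and 7.0) cut the gradient
into segments.  Below a convergence point (default 7.0) each segment hosts
`n_alt_states` alternative states (default 2); above it exactly one state
exists — alternative community trajectories at low browning converging into
a single trajectory at high browning.  Each state owns
`state_taxa_per_regime` (default 8) indicator taxa that receive a fixed
fraction (`state_fraction`, default 0.45) of expected relative abundance at
that state's sites and zero elsewhere.  How alternative states manifest
compositionally is not observable in a survey; this disjoint-indicator
construction is our explicit operationalization.  The 0.45 mass sits at the
top of a "detectable but not trivial" band: crossing a threshold flips
nearly half of expected composition, while gradient-response turnover keeps
far-pair distances high enough that thresholds are not simply the largest
distances in the data.

Counts are one multinomial draw per site at fixed depth (default 10,000
reads), so row sums are exact and rarefaction is exercised by explicit
subsampling rather than unequal depths.  Absorption spectra follow the CDOM
exponential a(λ) = a400(g)·exp(−S(λ−400)) on 400–750 nm at 1 nm (S = 0.015
nm⁻¹, a400 increasing linearly in g), plus Gaussian noise clipped at 1e-6
so log and PCA stages stay defined.

The **standard scenario** used throughout testing is 80 sites, 300 taxa
(40 of them regime indicators), τ = (3, 7), two alternative states, depth
10,000.  What passing tests show is therefore conditional on this model:
multinomial noise only (no chimeras, no sequencing error, no overdispersion
beyond the mixture itself), no spatial autocorrelation, no phylogeny, and
regime structure expressed through indicator taxa.  Real data violate all
of these in degree; the pipeline's recovery rates here are an upper bound,
not a field guarantee.

## Beta-diversity response surfaces

Bray–Curtis distances d_ij between all site pairs are regressed on the pair
of browning values (g_i, g_j); both orderings of each pair enter, and
train/test splits (80/20, seeded) keep mirrored rows in one fold so the
identical target never leaks across folds.  Pairs sharing a site are not
independent; like the analyses this package reproduces, the default split
ignores that, and a site-blocked split is available behind a flag.

Models:

* **Gradient-boosted trees** (the workhorse): depth-3 exact-greedy trees on
  residuals, Newton leaf weights Σr/(n+λ) for squared loss, shrinkage
  ν = 0.1, λ = 1, 300 rounds, base score = training mean.  Training MSE is
  provably non-increasing per round for ν ∈ (0, 1]; the split criterion
  reduces to best-SSE search at λ = 0 and matches xgboost's exact method in
  tests.
* **Random forest** via scikit-learn (prediction = mean of trees).
* **Feed-forward network**: 2–16–16–1, Xavier-uniform init, ReLU, MSE loss,
  plain mini-batch gradient descent on z-scored inputs; with no hidden
  layers it converges to the OLS fit, which the tests use as an oracle.
* **Polynomial OLS by SVD** over all monomials g1^a·g2^b, a+b ≤ degree,
  with bootstrap bias–variance degree selection (reported "bias²" folds in
  irreducible noise, which is stated rather than pretending to separate
  them; error = variance + that term exactly).  Degree 1 is the monotone
  baseline the boosted trees are contrasted with.

Surfaces are predicted on a square meshgrid from min to max gradient with
step equal to the smallest positive pairwise difference of observed values,
capped at `max_grid` axis points (default 500 for the function, 300 in the
pipeline — the step rule is unbounded for near-duplicate values, and 300
points ≈ 0.04 gradient units resolves thresholds an order of magnitude
finer than site spacing).  Because the estimand d(g1, g2) is symmetric by
definition and greedy tree ensembles only approximate that symmetry, the
grid prediction averages the two query orientations by default.  The
surface mean over off-diagonal cells is reported as the baseline
beta-diversity.

## Threshold ("guardrail") detection

The turnover profile reads the surface next to the diagonal as
t(g_u) = mean_j S[u−j, u+j], j = 1..k — predicted distances between pairs
*straddling* g_u at small lags (pipeline default k = 5 grid steps ≈ 0.2
gradient units, one-sided at the axis ends).  A community threshold at g
makes every straddling pair distant regardless of lag, so t peaks exactly
at the threshold; a square near-diagonal average was tried first and blurs
the peak position by up to a site spacing or two, which is why the
cross-diagonal read is the default geometry.

Detection runs `scipy.signal.find_peaks` on t with every constant relative
to the surface's full value range R (hence invariant to affine rescaling):

* prominence ≥ `min_prominence_frac`·R (default 0.1);
* **ridge level gate**: the peak's turnover must reach
  `ridge_level_frac`·R (default 0.3) above the surface minimum.  This is
  the operational meaning of a threshold — a single near-diagonal step
  already produces a sizeable fraction of the whole system's compositional
  range.  Under smooth monotone turnover the near-diagonal is necessarily
  a small fraction of R (shift accumulates over the gradient), measured at
  0.11–0.19 across regime-free runs, versus 0.41–0.57 at true thresholds;
  0.3 sits between the two populations with symmetric margin.
* features closer than `min_separation_frac` (default 0.05) of the
  gradient range merge, keeping the more prominent; endpoint maxima use a
  boundary-prominence rule and are flagged `edge=true`.

Valleys are the mirror case: prominent local minima below the ridge line,
intervals where composition does not shift substantially.  Ridge positions
partition the gradient into regime intervals in the guardrail summary.

On the standard scenario the full pipeline recovers each true τ within
±0.5 gradient units in ≥ 95% of seeds (measured 79/80 per threshold over
80 generator seeds during development), and detects zero ridges on
regime-free monotone data in 60/60 runs.

## MINE screening of individual taxa

The maximal information coefficient (MIC) of a taxon–gradient pair is the
maximum over grid shapes (cols·rows ≤ B(n) = ⌊n^0.6⌋, both orientations)
of mutual information normalized by log2(min(cols, rows)).  One axis is
equipartitioned (adaptive bins, ties kept together); the other is optimized
exactly by a dynamic program over clumps — maximal runs of points no
optimal partition splits, with identical x-values forced together and a
superclump cap of c·max_cols (c = 15).  Mutual information decomposes
additively over columns once the row partition is fixed, so the prefix
recursion is exact for its subproblem; the test suite checks it against
exhaustive search on 100 random small instances.  The maximum asymmetry
score (MAS) is the largest |M[a,b] − M[b,a]| over the characteristic
matrix and measures deviation from monotonicity (a monotone relationship
grids symmetrically).  Kernels are numba-compiled; a full 300-taxon screen
with 199 permutations runs in seconds.

p-values come from seeded permutations of the gradient, shared across taxa:
p = (1 + #{MIC_perm ≥ MIC_obs})/(n_perm + 1), exact-level under
exchangeability (the original MINE used precomputed null tables; the
permutation route is self-contained).  The q-values are Benjamini–Hochberg;
a Hochberg step-up family-wise variant is available behind a flag since the
literature sometimes says "Hochberg" for either.  A taxon with q < 0.05 and
MIC ≥ 0.3 is *monotone* when MAS < 0.05 (strictly) and *nonmonotone*
otherwise.

Ground truth for recovery tests is deliberately defined on the *realized*
noiseless relative-abundance curve, in rank space
(`simulate.realized_monotonicity`): compositional closure divides each
response by the site total and can flip monotonicity, and MIC/MAS are
rank-based, so amplitude-space labels misdescribe what any grid statistic
can see (a two-level step curve's within-plateau ordering, for instance, is
normalization jitter that dominates rank space).  Curves with rank-reversal
score < 0.05 are clearly monotone; score > 0.3 with both branches holding
≥ 20% of sites is clearly nonmonotone; the remainder are ambiguous and
excluded from scoring.  With that definition, screen classes match truth
for ≥ 98% of scored taxa across generator seeds.

## Monotonic baselines

* **RDA R²**: multivariate OLS of the column-centered Hellinger matrix on
  z-scored predictors; R² = fitted/total sum of squares, adjusted by
  Ezekiel's 1 − (1 − R²)(n − 1)/(n − p − 1).  Rank-deficient predictors
  raise by default; variance partitioning passes
  `allow_rank_deficient=True`, which truncates small singular values and
  uses the effective rank as p, so a duplicated predictor set partitions
  into the shared fraction instead of erroring.
* **Variance partitioning** over 2–3 named predictor sets by
  inclusion–exclusion on adjusted R² of all subset unions (Möbius
  inversion), matching vegan's `varpart` to 1e-6 in tests; fractions plus
  residual sum to 1 exactly, and negative fractions (an adjustment
  artifact) are reported, not clipped.
* **Distance decay**: OLS of community on geographic distance over
  unordered pairs, Mantel permutation p (joint row/column permutation of
  the geographic matrix, one-sided on Pearson r, 999 default).
* **Alpha-diversity hump test**: linear vs quadratic OLS compared by
  AIC = n·ln(SSE/n) + 2k, with the peak −b/(2a) reported only for a
  concave fit with an interior vertex.  This is a deliberate, documented
  stand-in for GAM smoothing: the claim under test is the existence of an
  interior diversity optimum, which the quadratic captures without
  penalized-spline machinery.  Shannon entropy uses the natural log
  (configurable); "Simpson" is reported in both 1 − Σp² and 1/Σp²
  conventions because the term is ambiguous in the ecological literature.

## Estimators and numerical choices

ACE follows Chao–Lee with rare cutoff 10; a sample where every rare taxon
is a singleton leaves C_ace = 0 and raises rather than silently swapping
estimators.  Rarefaction (Hurlbert) and the analytical species accumulation
curve use log-gamma arithmetic throughout — binomial coefficients at depths
near 4×10⁵ overflow any naive evaluation.  The spectra PCA standardizes
columns, orients PC1 to correlate positively with mean absorbance (a fixed
"browning index" direction), and raises on constant columns.  Fisher's α is
bracketed and solved by Brent's method; it has no solution for S ≤ 1 or
S = N.  Bray–Curtis between two all-zero sites is undefined and raises.

## Reproducibility

Every stochastic step takes a seed; the pipeline fans one global seed into
per-stage seeds through SHA-256, so stage-level reruns reproduce exactly
and rerunning a pipeline with the same config yields byte-identical numeric
artifacts (TSV/JSON only, fixed float formatting).  Problem sizes used by
the validation experiments: 20 seeds × 80 sites for threshold recovery and
for the monotone false-positive control, 100 replicates for the MIC null,
200 for p-value uniformity, 99–199 permutations per screen.
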