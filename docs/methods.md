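# Methods

## Data model and normalization

The pipeline's central object is the activation matrix: one row per
individual, one column per brain region, each cell the normalized activation
measure IC/TA (c-fos immunopositive cells counted over a 10,000 μm² sampled
area, divided by the total area in μm² of the analysed hemisphere section;
units cells·μm⁻², realistic magnitude ~10⁻⁴). Counting geometry (rectangle
placement, section selection, hemisphere choice) happens upstream of data
entry; the loader accepts one count and one area per (individual, region)
and applies the division, or takes precomputed IC/TA directly.

The multivariate stages need complete rows. An individual missing any
region is dropped with a logged warning rather than imputed: with 6–9
animals per group, imputation would invent structure that PERMANOVA and the
correlation networks would then "discover". A strict error mode is
available. Negative measurements, duplicated (individual, region) pairs and
groups with fewer than two members are always errors.

## Rank-based tests

All tests use average ranks for ties. Each result records its computation
mode — `exact`, `asymptotic` or `monte_carlo` — because at these sample
sizes the difference is material.

- **Mann–Whitney U**: statistic $U = \#\{x_i > y_j\} + \tfrac12\#\{x_i =
  y_j\}$. Exact enumeration null when the pooled sample is tie-free and
  $n_1 n_2 \le 2000$; otherwise tie-corrected normal approximation with
  continuity correction. p-value computation delegates to scipy; the exact
  route is independently validated against full enumeration over all
  $\binom{n_1+n_2}{n_1}$ labelings in the test suite.
- **Wilcoxon signed-rank**: zero differences dropped, $T$ = sum of
  positive-difference ranks. The exact null enumerates all $2^n$ sign
  patterns for $n \le 20$ via a subset-sum distribution over doubled ranks,
  which handles tied |differences| exactly (the standard exact algorithms
  assume no ties); normal approximation with tie correction beyond.
- **Kruskal–Wallis**: $H$ with tie correction, df $= k-1$, chi-squared
  reference. An all-tied input returns $H = 0$, $p = 1$ instead of raising,
  so pipelines over degenerate synthetic draws do not crash.
- **Dunn's post hoc**: $z_{ij} = (\bar R_i - \bar R_j)\big/\sqrt{(N(N+1)/12
  - T)(1/n_i + 1/n_j)}$ with tie term $T = \sum(t^3-t)/(12(N-1))$;
  two-sided normal p-values, BH-adjusted by default (`none` mirrors raw
  reporting conventions).
- **Two-sample KS**: $D$ over all pooled evaluation points; exact
  (lattice-path) null for $n_1 n_2 \le 10{,}000$. At $n_1 = n_2 = 6$, $D$
  lives on the grid of sixths.
- **Effect sizes**: Cohen's $d$ with pooled $n-1$ SD; Hedges'
  $g = d\,(1 - 3/(4(n_1+n_2)-9))$; `auto` picks $d$ for balanced pairs and
  $g$ otherwise.
- **BH-FDR**: statsmodels' step-up implementation behind a validating
  wrapper. Note the adjustment is *not* idempotent (e.g. [1.0, 0.25] →
  [1.0, 0.5] → [1.0, 1.0]); the package claims only monotonicity and the
  cap at 1.

## PCA and PERMANOVA

PCA standardizes variables by default (correlation PCA): regions differ in
IC/TA scale and standardizing weights them equally; covariance PCA is a
flag. Components come from the spectral decomposition; each is sign-flipped
so its largest-|loading| entry is positive, making output deterministic
(principal axes are defined only up to sign). The summary table mirrors the
conventional layout: standard deviation / proportion of variance /
cumulative proportion rows, then one loading row per region.

PERMANOVA uses the Euclidean distance matrix of the (unstandardized)
profiles and the distance-based decomposition
$SS_\text{total} = \sum_{i<j} d^2_{ij}/N$,
$SS_\text{within} = \sum_g \sum_{i<j \in g} d^2_{ij}/n_g$,
$F = (SS_\text{between}/(a-1))/(SS_\text{within}/(N-a))$. The null permutes
labels freely (one-way design, no strata). The reported
$p = (1 + \#\{F^* \ge F\})/(B+1)$ counts the observed labeling once, so
$p \in [1/(B+1), 1]$ and is never zero; the permutation batch is fully
vectorized and reproducible given (data, B, seed). A two-group exhaustive
mode enumerates every distinct relabeling; the test suite checks Monte
Carlo against it and checks the pseudo-F against scikit-bio's independent
implementation. Pairwise contrasts rerun the two-group PERMANOVA on each
pair with deterministic per-pair substreams; pairwise p-values are raw by
default (BH optional).

## Co-activation networks

Within one treatment group, edge weights are Spearman correlations between
regions (minimum group size 3; constant regions are errors). Derived
metrics: total connectivity (sum of the $K(K-1)/2$ unique weights), strength
(row sums of the zero-diagonal adjacency; $\sum_i s_i = 2\,\times$ total
connectivity by construction), and weighted eigenvector centrality.

Eigenvector centrality requires a nonnegative adjacency. The studied
networks are all-positive, so a negative empirical edge is an error by
default, with explicit `abs` and `shift` opt-ins for exploratory data
(finite-sample Spearman at $n = 6$ can dip negative even when the
underlying dependence is positive). Power iteration runs on $W + sI$ with a
positive shift $s$: the shift leaves eigenvectors unchanged and guarantees
convergence even on bipartite weight patterns, where $|\lambda_{\min}| =
\lambda_{\max}$ and unshifted iteration oscillates. Tolerance 1e-12,
iteration cap 10⁴, uniform start, max-normalized output.

Centrality rankings sort high→low, break ties by the configured region
order, and flag that a tie occurred.

### Between-treatment comparisons

For a group pair and a target (`edges`: the 6 unique weights each;
`strengths`: the K per-node sums each), the comparison runs exact KS and
Mann–Whitney on the two value sets plus a randomization test of
$|\bar a - \bar b|$. Two permutation schemes are provided and labeled:

- **values** (default): re-partition the pooled metric values into sets of
  the original sizes — exhaustive over all $\binom{n_a+n_b}{n_a}$
  partitions when that count is ≤ 20,000 (always, for 6-vs-6 edges and
  4-vs-4 strengths), else Monte Carlo with +1 smoothing. This treats the
  derived values themselves as the exchangeable units and can give
  different answers for edges and strengths, which aggregate edges.
- **individuals**: permute the individual-to-group assignment and recompute
  both Spearman matrices per draw — the conservative scheme in which the
  network statistics are functions of the permuted raw data.

Neither scheme is claimed to be canonical; the mode is recorded in every
result. A three-group omnibus (KW across the groups' value sets, then Dunn
pairs) is also provided.

## Synthetic data generator

The generator emulates the statistical structure of the motivating study
design so the full pipeline is testable without raw data:

- **Design**: groups NAE/OR/OnR of sizes 6/6/9, regions Vv/Vd/Dm/Dl.
- **Marginals**: lognormal (IC/TA is strictly positive and right-skewed),
  parameterized by a per-group/region median and one shared log-scale SD.
  Baseline median 1.0×10⁻⁴ cells·μm⁻²; the default planted effects add
  1.10×10⁻⁴ to Vv in both encounter groups and 0.90×10⁻⁴ to Dl in OnR only,
  matching the magnitude of the motivating contrasts. The shared log-sd is
  0.35: a marginal CV of ≈36%, biologically plausible for IEG counts, which
  places the planted shifts at ≈2 log-sd (log 2.1/0.35 ≈ 2.1,
  log 1.9/0.35 ≈ 1.8). A gamma marginal family is available behind a flag.
- **Dependence**: Gaussian copula targeted at a Spearman matrix through the
  closed form $r = 2\sin(\pi\rho_s/6)$. Because the marginal transform is
  strictly monotone, the target Spearman structure is exact in
  distribution. Defaults are equicorrelation matrices whose common
  off-diagonal value is the per-group mean edge weight implied by the
  motivating totals over six edges: 0.692 (OnR), 0.428 (OR), 0.600 (NAE).
  If a converted latent matrix is not positive definite it is repaired by
  eigenvalue clipping at 1e-8 with diagonal renormalization — never
  silently (logged and warned); irreparable targets are errors.
- A `null_config()` variant makes all three groups identical (baseline
  medians, common ρ = 0.6) for calibration studies.

What the generator does **not** emulate: section-level counting noise,
hemispheric asymmetry, inter-individual personality structure, or any
behavioral time series. Passing tests therefore demonstrate that the
pipeline recovers effects of the planted form at the study's sample sizes —
not that the real data contain such effects.

## Calibration and power at the study's sample sizes

Measured properties (also enforced or reported by the test suite):

- Under the simulated null, Mann–Whitney (true size 0.0496 at 6 vs 9) and
  PERMANOVA (≈0.05 with B = 999) are well calibrated at α = 0.05. The exact
  KS test is conservative: its attainable levels at n = 6–9 put the true
  size at ≈0.026–0.028. This is a property of the exact test at these
  sample sizes, not an implementation artifact.
- The values-mode randomization test detects a mean-edge-correlation
  difference of 0.8 vs 0.2 (n = 9 vs 6 individuals) with power ≈ 0.80 —
  right at the conventional bound, so finite Monte-Carlo estimates straddle
  it; the acceptance test verifies the bound as a one-sided 2-SE binomial
  check at 2,000 replicates.
- Joint recovery of all four planted regional contrasts (KW then Dunn) has
  power ≈ 0.5: the per-contrast powers are 0.75–0.91, and their
  conjunction cannot reach 0.8 at n = 6/6/9 with ≈2 log-sd effects. The
  corresponding acceptance test documents this honestly (it fails); the
  per-nucleus KW tests alone recover the affected nuclei with power
  0.92–0.95.

## Numerical and reproducibility choices

- Permutation counts default to B = 999; a seed is mandatory wherever Monte
  Carlo runs. The pipeline derives deterministic per-stage substreams from
  one global seed (numpy `SeedSequence` spawning), so stages can be rerun in
  isolation and the full report is byte-identical under a fixed seed;
  changing the seed changes only Monte-Carlo p-values. Report JSON carries
  seed/B/version provenance and deliberately no timestamps.
- CSV output uses `%.17g` floats and reading uses round-trip float parsing,
  so write→read reproduces matrices bit-exactly.
- Failure policy is fail-fast with cleanup of partial outputs: with n this
  small, downstream tables after a stage error are meaningless.
- Analysis problem sizes in the repository's drivers and suites (e.g. 500
  calibration replicates in the driver, 2,000 in the acceptance suite, 200
  for regional recovery) were chosen as the package's own defaults to make
  Monte-Carlo error small relative to the quantities being checked.

## Known limitations

- The LMM/estimated-marginal-means analysis sometimes paired with this kind
  of data is out of scope; the nonparametric twin (KW + Dunn + effect
  sizes) is the implemented path.
- Eigenvector centrality on networks with genuine co-inhibition (negative
  edges) has no canonical definition; the provided `abs`/`shift` policies
  are pragmatic, flagged choices.
- With K = 4 regions the strength comparison rests on 4-vs-4 value sets;
  exact test modes are used but power is intrinsically low.
- The generator's shared log-sd across groups and regions isolates mean and
  correlation effects by design; real data may be heteroscedastic.
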