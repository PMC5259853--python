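# Methods

## Model and procedure

`gsnet` implements self-contained two-sample tests for gene sets.  The data
for one test are a p × N matrix of normalized expression values (p genes,
N = n₁ + n₂ samples) and a two-group label vector; group 1 plays the role
of X throughout, group 2 of Y.  Samples are treated as points in R^p and
all geometric structure derives from their Euclidean distance matrix.

The minimum spanning tree of the complete sample graph is the common
backbone.  Three statistics are read off it:

1. **Runs statistic** R: delete every tree edge whose endpoints carry
   different labels and count the remaining components (equivalently,
   cross-edges + 1).  Under phenotype separation same-group samples cluster
   in the tree and R is small.  The standardized form
   W = (R − E[R]) / √var(R) uses the permutation sample's mean and SD
   rather than closed-form moments: the permutation p-value on W is
   provably identical to the p-value on raw R (W is an increasing affine
   transform of R with coefficients fixed across permutations; the test
   suite asserts the identity exactly), and this avoids transcribing
   analytic moment formulas from secondary sources.  If sd(R) = 0 across
   permutations the test falls back to raw R with a warning.
2. **Rank CDF statistics** (KS and MD) over a vertex ranking of the tree.
   The HDP ranking roots the tree at a diameter endpoint and ranks by a
   height-ordered preorder, so the two groups' ranks separate under a mean
   shift.  The radial ranking roots at the centroid and ranks outward, so
   an inflated-variance group collects the high ranks.  Rankings depend on
   the data geometry only; label permutations are evaluated over fixed
   ranks (otherwise the runs statistic would be constant and the rank
   statistics incoherent).
3. **Gene-side structure** (GSNCA and MST2) built from intergene
   correlations within each condition, described below.

All significance is by label permutation with the corrected estimator
p = (#hits + 1)/(M + 1), so p ∈ [1/(M+1), 1] and a test can never report
zero.  When C(N, n₁) ≤ M the sampler switches to exhaustive enumeration of
all labelings, which removes Monte-Carlo noise and makes small-N results
exactly reproducible.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `nperm` | 1000 | label permutations M; the smallest attainable p is 1/(M+1) |
| `alpha` (MD) | 0.25 | rank-weight exponent in P(X, i); modest weighting of higher ranks |
| `mst_order` | 1 | radial tests may rank the union of the first k ≤ 5 MSTs; power gain fades beyond k = 3 |
| `cor_method` | pearson | intergene correlation (pearson, spearman, kendall; rank methods use average ranks for ties) |
| `min_sd` | 1e-3 | smallest within-group gene SD GSNCA accepts before erroring |
| `max_skip` | 10 | permutations that may be skipped when they push a gene's SD below `min_sd` |
| `min_size` / `max_size` | 10 / 500 | matched-gene bounds in batch mode; MST ranking and correlation estimates are unstable below ~10 genes and slow above ~500 |

## Conventions and numerical choices

* **MST construction**: Kruskal over edges sorted by (weight, i, j).  Any
  MST algorithm yields the same minimal weight; the lexicographic secondary
  key makes the tree a deterministic function of the data even under tied
  weights (duplicated samples), which permutation p-values require.  An
  all-zero distance matrix (all samples identical) is rejected: every
  spanning tree would be arbitrary and every statistic uninformative.
* **HDP traversal internals**: the root is the vertex of largest weighted
  eccentricity (a diameter endpoint); children are visited in decreasing
  subtree height measured in hops; every tie falls back to the smallest
  vertex index.  The traversal's published description does not fix these
  details, so this is a documented convention and may differ from other
  implementations in rank ties; observed and permuted statistics use the
  same procedure, so p-values are internally coherent.
* **Radial ranking**: root = minimum hop-count eccentricity (tree shape,
  not metric scale, determines the centroid); remaining vertices sorted by
  (hop depth, weighted distance from root, index).  On a k-MST union, depth
  is the unweighted shortest-path hop count.
* **MD summation**: the CDF deviations are indexed by sample ranks, so the
  sum runs over i = 1..N.
* **Permutation ties**: distinct labelings can produce analytically equal
  statistics whose floating-point values differ in the last digit depending
  on summation order.  Indicator comparisons therefore use a 1e-12 relative
  tolerance, making tie counts deterministic and exhaustive-mode p-values
  exactly reproducible.
* **Two-sided F p-value**: doubling the smaller tail of F(n₁−1, n₂−1)
  (equal-tailed); variances are unbiased (divisor n−1) to match those
  degrees of freedom.  Zero variance in both groups gives p = 1 with a
  warning (no evidence either way); per-gene p-values are floored at the
  smallest positive float before the Fisher log so a zero-variance gene
  under permutation never produces −∞.
* **GSNCA weights**: the weight equation wᵢ = Σ_{j≠i} wⱼ|r_ij| is solved
  as the leading eigenvector of the zero-diagonal |r| matrix (dense
  symmetric solver; correctness is defined by the residual
  ‖Aw − λw‖∞ < 1e-8, asserted in tests, not by the algorithm).  The
  Perron-Frobenius vector of an irreducible nonnegative matrix is positive;
  if a gene is uncorrelated with all others (zero row, reducible matrix)
  the off-diagonals are perturbed by 1e-12.  Each weight vector is scaled
  to mean 1 before the L1 difference — this makes the statistic
  dimensionless, exactly 0 for identical correlation structure, and
  comparable across set sizes.  Other scalings differ only by a constant
  factor and leave p-values unchanged when applied uniformly across
  permutations.
* **MST2 distance map**: edge weight 1 − |r|, so strongly correlated genes
  are close and hubs centralize.  In adjacency (PPI) mode present edges get
  unit weight and the deterministic tie-break chooses among the many
  spanning trees.  If the residual graph after removing the first MST is
  disconnected, the minimum spanning forest is used (this keeps MST2
  defined for all p ≥ 3).

## Behaviour worth knowing about

* **GSNCA under strong mean shifts.**  The test is insensitive to *moderate*
  mean shifts (correlations are location-invariant within groups), but the
  permutation null mixes the two populations: a large shift inflates all
  intergene correlations in permuted groups uniformly, shrinking the
  permuted statistics and producing spurious rejections.  In simulation
  (p = 10, n = 15/15, equicorrelation 0.2) rejection at α = 0.05 is ~0.03
  at a 0.5-SD shift but ~0.11 at 1 SD and approaches 1 at 2 SD.  Interpret
  GSNCA results for sets with strong differential expression cautiously —
  ideally alongside a mean-shift test.
* **KS-type tests are conservative at small, equal group sizes.**  The KS
  statistic is a maximum over CDF gaps on a lattice (multiples of 1/n₁ for
  n₁ = n₂), so its null tail probabilities jump discretely; at n₁ = n₂ = 15
  they skip from 0.076 to 0.026, and the exact 0.05-level type-I error of
  the permutation test is ~0.027 — no deterministic rejection rule can hit
  0.05.  The MD statistic is effectively continuous and calibrates tightly.
* **Radial tests have non-negligible shift power** (and HDP tests some
  scale power); the `scale_specific_filter` joint rule exists precisely to
  isolate variance-specific calls.
* **Planted-hub feasibility.**  A correlation matrix with one hub gene at
  r_hub against a background r_bg is positive definite only when
  r_hub² (p−1) < 1 + (p−2) r_bg; e.g. at p = 10, r_bg = 0.1 the hub can
  correlate at most 0.447 with the rest.  The generator raises on
  infeasible requests rather than repairing the matrix.

## Synthetic data

`simulate_mvn` draws two multivariate normal groups: group 1 from
N(0, Σ(ρ₁)) and group 2 from N(δ·1, σ_ratio² Σ(ρ₂)), with Σ(ρ) the
equicorrelation matrix.  This realizes a true null (δ = 0, σ_ratio = 1,
ρ₁ = ρ₂) and the three canonical alternatives — mean shift, scale change,
correlation change — plus `simulate_hub_correlation` for planted-hub
structure and `simulate_counts_with_zeros` for negative-binomial counts
with structurally silent genes (to exercise the GSNCA guards).  The
generators emulate the statistical structure these tests target, not real
RNA-seq complexity: no library-size variation, dispersion-mean trends,
outliers or heavy tails.  Passing calibration on them shows the tests hold
their level and detect the intended alternatives under clean multivariate
normality; it does not certify behaviour on skewed or contaminated data.

## Problem sizes in the test suite

The statistical acceptance checks use simulation studies sized to be
informative yet quick: the runs-test benchmark at p = 20, n = 20/20 with
9999 permutations over 10 seeds; type-I calibration at p = 10, n = 15/15
with 1000 replicates of nperm = 500 per test (rejection band [0.03, 0.07]
at α = 0.05); specificity grids of 200 replicates (500 for the GSNCA
shift-insensitivity band, matching the calibration band's replicate
scale); exhaustive-oracle equality at N = 8 (70 labelings) and brute-force
MST minima at N ≤ 6 via Prüfer-sequence enumeration.

## Limitations

* Asymptotic (normal/Smirnov) p-values are deliberately absent; inference
  is permutation-only.
* HDP/radial tie conventions are fixed but not verified against other
  implementations; ranks (not p-value validity) may differ on tied trees.
* Kendall correlations cost O(p² n log n) and dominate GSNCA runtime for
  large sets.
* The batch driver derives per-set seeds from the master seed and set name
  (CRC32), so results are reproducible and insertion-order independent,
  but not comparable across renamed sets.
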