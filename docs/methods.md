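# Methods

## Scope and data model

`coocnet` starts from an ESV-by-sample matrix of non-negative integer
counts with a per-sample environment label.  Upstream read processing
(denoising, trimming, chimera removal) is out of scope; the package assumes
a denoised count table.  Networks are undirected graphs whose vertices are
ESVs and whose edges carry: sign, Spearman ρ and Bray–Curtis similarity on
the environment where the edge was inferred, per-measure and merged and
adjusted p-values, and the set of environments supporting the edge.

## Preprocessing

1. **Total-reads filter** (default ≥ 25 reads summed over all samples),
   applied to the pooled table before the environment split.
2. **Environment split** into per-environment tables.
3. **Abundance/prevalence filter**, per environment: an ESV is dropped when
   its overall relative abundance is below 10⁻⁵ *or* it is present in fewer
   than 10 % of the environment's samples.  Equality keeps the ESV.  The
   disjunction is deliberate: either criterion alone marks an ESV whose
   counts cannot support rank statistics.  Relative abundance is computed
   within the environment table, not globally, because community
   composition differs radically between environments.
4. **Trimming** to uniform size (default 400 top-abundant ESVs ×
   360 random samples) removes taxon- and sample-number biases before
   cross-environment topology comparisons.  Abundance ties at the cutoff
   break lexicographically; the ESV set is seed-independent while the
   sample subset is drawn from the given seed.  An environment with fewer
   samples than the trim size raises an explicit exclusion signal rather
   than being silently truncated.

Filters are idempotent, and removal counts are reported per criterion in
application order.

## Association measures and significance

Both measures operate on relative abundances within one environment:
Spearman ρ (average ranks for ties; undefined for constant vectors) and
Bray–Curtis similarity 1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ).

**Permutation null.**  Each iteration shuffles the two ESVs' counts across
samples independently.  For Spearman, relative abundances are then
recomputed against the *perturbed* sample totals (only the pair's rows
moved, so totals change).  This renormalization makes the null carry the
compositional bias of fixed-sum data: a pair occupying a large share of the
community produces a genuinely negative null mean, and the p-value is
computed against that shifted null rather than against zero.  For
Bray–Curtis the pair's relative-abundance profiles are shuffled directly;
dividing shuffled counts by the fixed totals would couple the two profiles
through the shared denominator and bias the null positive.

**Bootstrap.**  Samples (columns) are resampled with replacement;
iterations whose resample contains fewer than three distinct samples are
redrawn (≤ 10 retries).  Both resampling loops are vectorized over
iterations and reproducible from a per-pair seed stream, so results do not
depend on the order in which pairs are processed.

**p-value.**  z = (mean(null) − mean(boot)) / sd(boot);
p = 2(1 − Φ(|z|)).  The two-sided form detects both co-presence and mutual
exclusion.  A degenerate bootstrap (sd = 0) yields p = 1 when the means
coincide and p = 0 otherwise.

**Brown's merge.**  T = −2(ln p₁ + ln p₂) is referred to a scaled χ² with
scale c = Var/2E and df = 2E²/Var, where E = 4 and
Var = 8 + 2·cov(−2 ln p₁, −2 ln p₂).  The covariance is estimated once per
environment from the empirical covariance of the log-p pairs across all
resampled pairs (a single pair gives one observation, so per-pair
estimation is impossible), clamped to [0, 4].  At zero covariance the
formula is exactly Fisher's method; at the maximal covariance 4 it returns
the common p unchanged.  Merged p-values are BH-adjusted.

**RMT thresholds.**  For each candidate cutoff t in a scan (default
0.30…0.95, step 0.01) entries with |score| < t are zeroed and the
eigenvalue nearest-neighbour spacing distribution (NNSD) of the resulting
matrix is tested.  Correlated noise produces GOE (Wigner–Dyson) spacings;
genuine modular signal produces Poisson spacings.  Numerical choices:

* duplicate eigenvalues (within 10⁻⁸) are removed before unfolding;
* unfolding fits the cumulative spectral density with a degree-5
  polynomial, forced monotone, and normalizes spacings to unit mean;
* the Poisson e^(−s) and GOE (π s/2)e^(−π s²/4) fits are compared by a
  binned χ² with *equal-probability bins under the law being tested*; the
  bin count adapts to the spacing sample (≈ 5 spacings per bin, between 5
  and 30 bins).  Fixed equal-width bins would put near-zero expected counts
  in most bins for the few dozen distinct eigenvalues a desk-scale matrix
  yields and explode the statistic even for genuinely Poisson spacings;
* a threshold qualifies when the Poisson χ² is below both the GOE χ² and
  the critical value at level 0.001 with df = bins − 1;
* a matrix with no off-diagonal entries at the scan start is trivially
  uncorrelated and qualifies immediately; if the off-diagonal empties
  mid-scan without any qualifying t, the scan is inconclusive and the
  configured fallback (default: scan start) is returned with a warning
  flag;
* fewer than 10 distinct eigenvalues at some t makes that t untestable.

**Retention.**  An edge is kept iff its BH-adjusted merged p ≤ 0.05 *and*
both measures support it: |ρ| at or above the ρ threshold, per-measure
BH-adjusted significance for both measures, and the Bray–Curtis criterion —
similarity at least the BC threshold for positive edges, or at most
1 − threshold for negative edges.  Bray–Curtis similarity cannot be
negative, so mutual exclusion manifests as *low* similarity; the
complementary low-tail criterion is this package's reading of "support by
both measures" for exclusions.

**Candidate restriction.**  Retention is conjunctive, so a pair whose
scores fail the RMT thresholds is discarded regardless of its p-values.
The pipeline therefore runs the resampling machinery only for pairs passing
the score thresholds; all other pairs enter the BH step with p = 1, which
is conservative (their true p-values could only push candidate ranks down).
`InferenceConfig(exhaustive=True)` forces resampling for every pair; a test
verifies both modes retain the same edge set.

**Deconvolution.**  The retained signed score matrix is scaled so its
extreme eigenvalues respect the β = 0.9 bound (largest positive eigenvalue
maps to β/(1−β)), eigenvalues are transformed λ → λ/(1+λ), and the matrix
is reconstructed.  With α = 1 (the default) no edges are removed; the
direct score is stored as an edge attribute.  α < 1 keeps the top-α
fraction of edges by observed magnitude.  Deconvolution acts on signed
scores; acting on |scores| is a flagged sensitivity alternative.

## Merging and edge ecology

Subnetworks merge by vertex and edge union under canonical
(lexicographically ordered) pair keys.  A shared edge keeps its
per-environment record; its representative score comes from the environment
with the largest |ρ| and edges positive in one environment but negative in
another are flagged sign-discordant rather than resolved.  Vertices without
incident edges are dropped.

*Generalist* edges occur in ≥ 2 subnetworks; *specialist* edges in exactly
one, subdivided by whether both endpoints occur (as network vertices) in
≥ 2 subnetworks.  Per-subnetwork class proportions sum to 1.

**Omission scores.**  For a generalist edge and an environment, the OS is
|ρ| recomputed over all samples except that environment's; the ratio
OS/|original ρ| measures how much the environment drives the edge.  The
nonparametric p is the fraction of 1000 random same-sized removals whose OS
is *strictly* smaller than the environment's OS (ties count against
locality, exactly as the counting rule states).  An edge is localized when
ratio < 1 and BH-adjusted p < 0.05.  The literal ratio < 1 rule admits
ratios arbitrarily close to 1; a configurable margin exists but defaults to
the literal rule.  Under exchangeable environments the p-values are
uniform; an acceptance test verifies this within a KS 1 % band.

Environment similarity is the Jaccard distance between subnetwork edge
sets; subnetworks are clustered by average linkage and reported as a
two-group cut.  Hubs are the 10 highest-degree vertices per subnetwork
(boundary ties broken lexicographically); hubs present in exactly one
subnetwork are specialist hubs.  Negative-edge profiles count both
endpoints of each negative edge at class rank.

## Overrepresentation

The hypergeometric urn for a taxon pair (A, B) at a chosen rank: population
N = all unordered vertex pairs, successes K = pairs with one endpoint in A
and one in B (C(|A|, 2) within a taxon), draws n = realized edges, observed
k = A–B edges; p = P(X ≥ k).  This tests edge placement against a uniform
null conditional on network size; it does **not** condition on the degree
sequence, so degree-driven enrichment is a known confounder.  Mutual
exclusion within a pair is Binomial(m, q) upper tail with q the
network-wide negative-edge frequency; co-presence is the symmetric lower
tail.  Both families are BY-adjusted.

## Synthetic data

The generator draws, per environment, latent per-ESV log-abundances from a
multivariate Gaussian whose correlation matrix embeds the planted latent
correlations (Gaussian copula; eigenvalue-clipping repair at 10⁻⁸ for
overconstrained designs, with an error if the repair destroys a planted
association), exponentiates, applies a per-ESV presence mask, closes each
sample to relative abundances and draws multinomial counts at fixed depth.
Defaults: 14 environments × 60 samples, 150 ESVs, depth 10 000,
base log-abundance ~ N(0, 1.5²), within-ESV fluctuation σ = 1,
presence probability 0.9.

Placement of planted associations respects two physical constraints of
fixed-depth compositional counts: a taxon observed at well below one count
per sample carries no rank information (the association would be
undetectable by any method), and a pair dominating the composition has its
shared variation cancelled by closure.  Planted ESVs therefore receive base
abundances from the 50th–85th percentile of the base distribution, planted
partners share a base level (making the association visible to the
magnitude-sensitive Bray–Curtis measure), and planted ESVs are exempt from
the presence mask.  Hub specifications expand into planted edges
(ρ = 0.8, all environments) toward the lexicographically first free
partners.

What the generator does **not** emulate: real taxonomic composition or
phylogeny (taxonomy labels come from a dummy pool), overdispersion beyond
the log-normal/multinomial hierarchy, sample-depth variation, batch
effects, or environmental gradients within an environment.  Passing tests
therefore demonstrate statistical correctness of the machinery on
copula-generated compositional data, not performance on real surveys.

## Problem sizes and determinism

The test suite and the acceptance script run the significance machinery at
200 resampling iterations (scaled from the 1000-iteration default) and
desk-scale tables: 100 ESVs × 200 samples × 10 seeds for type-I control,
a 420-ESV table trimmed to 400 × 360 for planted recovery, 200
edge-environment queries at 1000 random removals for omission calibration,
and a 14-environment × 60-sample × 150-ESV replica for the end-to-end run.
These sizes were chosen so the whole suite completes in minutes while every
statistical claim retains adequate resolution.

All randomness flows through `numpy.random.Generator` seeded per
pair/stage via `SeedSequence` spawn keys, so results are independent of
iteration order and identical config + seed reproduces byte-identical
edge-list output (verified by test).

## Known limitations

* The Gaussian-tail ("ReBoot"-style) p-value is a parametric approximation;
  with 200–1000 iterations its extreme tails (p ≪ 10⁻¹⁰) are
  extrapolations of the fitted normal, useful for ranking but not literal
  error probabilities.
* The RMT scan needs enough distinct eigenvalues to test; very sparse
  thresholded matrices fall back to the scan start, which is conservative
  in admitting candidates (significance filtering still applies).
* Brown's covariance is a single pooled estimate per environment; pairs
  whose measure dependence differs from the pool average get slightly
  mis-calibrated merged p-values.
* The hypergeometric null ignores the degree sequence.
* Greedy modularity is a heuristic; module assignments are deterministic
  for a fixed vertex order but not globally optimal.
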