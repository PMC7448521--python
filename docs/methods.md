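# Methods

## Model and procedure

`protscan` tests the gene-level null hypothesis that no variant in a gene
is associated with a quantitative trait, and, when the null is rejected,
localises the signal in protein 3D space. All testing is driven by the
variant-level score vector `U` and its covariance `V` under a linear null
model `y = Z gamma + eps`:

    U = G' r / sigma2_hat,
    V = (G'G - G'Z (Z'Z)^{-1} Z'G) / sigma2_hat,

with `r` the null residuals and `sigma2_hat = RSS / (n - rank(Z))`. Under
the null, `U ~ MVN(0, V)` asymptotically, and `U_j / sqrt(V_jj)` is the
per-variant score Z-statistic. Summary statistics produced by external
software can be supplied directly; only the linear (quantitative-trait)
score model is implemented — binary traits would require logistic score
statistics, which are out of scope here.

### Window family

Windows are connected components of the graph joining variant pairs with
Euclidean distance `<= w`, collected as `w` sweeps the sorted *unique*
pairwise distances. This is exactly the node set of the single-linkage
merge tree: a laminar family (any two windows nested or disjoint) of at
most `2m - 1` members, with equality when every merge event is a distinct
binary merge. Implementation is a union-find sweep; equal distances are
processed in one event, so a tie can merge more than two components at
once and the family is deterministic and order-independent. The member
sets depend only on distance *ranks*, so the family is invariant to
rescaling of coordinates.

Per gene, the window set is the union of the per-structure tree nodes,
one window holding all structurally unmapped variants (if any), and one
global window over the whole gene (deduplicated if it coincides with a
structure root). A gene with no structural data therefore degrades
gracefully to the ordinary whole-gene test. When one variant maps to
several structures it is kept on one: experimental structures are
preferred over computational models (recognised by a `mod`/`model` id
prefix), then the structure mapping more variants, then the
lexicographically smallest id — a deterministic rule that keeps each
structure's family laminar.

Windows with cumulative minor allele count below `min_mac = 10` are
excluded from testing (analytic p-values are unreliable on fewer minor
alleles) but retained for display.

### Per-window tests and tail computation

The mean test uses Madsen–Browning weights `1/sqrt(MAF(1-MAF))` by
default; the variance test uses the Beta(1, 25) density of the MAF, with
`Omega = diag(weight^2)` — the SKAT kernel convention `G W W' G`. The
variance-test null is the mixture `sum lambda_k chi2_1` with `lambda_k`
eigenvalues of `V^{1/2} Omega V^{1/2}` (computed as the spectrum of
`diag(w) V diag(w)`; negative eigenvalues from roundoff are clipped, and
eigenvalues below `1e-10 * max(lambda)` are dropped).

Mixture tails are evaluated by numerical inversion of the characteristic
function: the oscillatory integral is split at a small point, the smooth
part handled adaptively and the tail integrated with QUADPACK's Fourier
weights. When all weights are equal the exact chi-square tail is used.
The inversion carries roughly 1e-10 absolute error, so p-values below
1e-9, or any failed inversion, fall back to the Liu–Tang–Zhang four-moment
match to a noncentral chi-square (fallback use is logged). Results are
clamped to (1e-300, 1].

### Gene-level combination

Genome-wide mode uses the Cauchy combination over the eligible windows'
p-values: `Q = mean_j tan((1/2 - p_j) pi)` and
`p = 1/2 - arctan(Q)/pi`; inputs are clamped to `[1e-300, 1 - 1e-16]` and
for `p_j < 1e-15` the tangent is computed by its asymptote `1/(p_j pi)`
to avoid overflow (a single input is returned exactly). The approximation
is accurate precisely where genome-wide decisions are made (combined
p < 1e-4); for larger p it can be slightly inflated, which is why
candidate-gene analyses use the minimum-p statistic instead: `B` draws of
`U* ~ MVN(0, V)` (eigenfactorisation of `V`, negative eigenvalues
clipped) rebuild the null of the minimum window p-value, and the reported
p-value is `(1 + #{min* <= min_obs}) / (B + 1)` — never zero, resolution
`1/(B+1)`, ties counted conservatively. Default `B = 5000`; eligibility
is fixed at the observed MAC filter (it depends on genotypes, not on
`U*`). The Cauchy denominator counts eligible windows only; ineligible
windows never receive p-values.

Within the Monte-Carlo machinery (minimum-p null, signal threshold), the
observed statistic and the null draws are evaluated with the *same* fast
vectorised evaluator — exact chi-square for the mean test, the moment
approximation for the variance test — so rank comparisons are internally
consistent; reported per-window p-values use the moment approximation
above p = 0.05 (where it tracks the inversion to a few percent) and the
accurate inversion below. The bulk power experiments refine small
p-values with the Lugannani–Rice saddlepoint approximation instead
(validated to within ~7% relative error of the inversion across random
tail cases, at ~1/40 the cost) — far below the Monte-Carlo noise of a
few hundred replicates.

### Signal-region search

The per-window significance threshold at level `alpha` is the empirical
lower-`alpha` quantile of the Monte-Carlo minimum-p null (order statistic
at rank `floor(alpha B)`, minimum rank 1; `alpha B >= 1` required), which
controls at ~`alpha` the family-wise probability that any window passes
under the null. Candidates below the threshold are selected greedily:
smallest p first, overlapping candidates discarded, repeat. Ties are
broken toward the smaller window, then the lexicographically smallest
member list (parsimony). The overlap-fraction variant discards a
candidate only when `|A ∩ B| / min(|A|, |B|)` exceeds `f`; with `f = 1`
every passing window is kept. The min-`|.|` denominator makes that
boundary statement literally true. The fit's Monte-Carlo null is shared
between the gene-level minimum-p test and the threshold — one `B`-draw
run per gene.

### 1D comparator

`Scan1DModel` replaces the spatial family with closed intervals
`[t, t + s]` sliding along the chromosome at a skip of `L/40`, for sizes
`s = L/2, L/4, L/8, L/12, L/16, L/20` with `L` the bp span of the gene's
variants; duplicate variant sets are deduplicated, a whole-gene window is
always included (mirroring the global window), and the same MAC filter is
applied for comparability. Everything downstream — tests, combination,
signal search — is literally the same code path, so the two methods
differ only in window definition.

### Single-variant comparator

For sensitivity/specificity comparisons, the single-variant comparator
tests each variant's score Z-statistic and declares the variants passing
a per-gene Bonferroni correction at level `alpha` as its detected
regions — the simplest defensible multiplicity rule for a per-variant
method.

## Synthetic data generator

The generator emulates a sequencing-study design at desk scale:

* **haplotype pool** — `H = 10000` haplotypes; per site the pool
  minor-allele count `k ∈ {1..H/2}` has `P(k) ∝ 1/k` (the neutral site
  frequency spectrum), carriers placed uniformly; sites independent.
  This deliberately reproduces the rare-variant-rich spectrum but **no
  linkage disequilibrium** and no demographic history — a documented
  deviation from coalescent-simulated haplotypes. Null calibration is
  insensitive to LD given a correct `V`; *absolute* power values are
  generator-specific, so only qualitative orderings between methods are
  meaningful reproduction targets.
* **genotypes** — each subject sums two pool haplotypes drawn uniformly
  with replacement (`n = 1000` by default; 5000 at full scale);
  sample-monomorphic sites are dropped and columns re-oriented to the
  sample minor allele, with MAF/MAC recomputed from the sample.
* **region** — `m ~ Uniform{20..70}` pool sites, positions drawn without
  replacement from a 3000 bp region (values chosen to mimic a
  variant-dense exonic region).
* **phenotype** — `Y = sum_j beta_j G_j + 0.3 Z + eps`, `Z, eps ~ N(0,1)`;
  causal effects `beta_j = ± c |log10 MAF_j|` so rare variants carry
  larger effects; unidirectional or bidirectional (`ceil(s/2)` positive).
  Effect scales follow the evaluation design: `c = 0.3 / 0.15` for power
  at 10%/50% causal fractions and `c = 0.25 / 0.1` for signal detection.
* **coordinates** — one pseudo-structure; neutral variants `N(0, 1)` per
  axis, causal variants `N(0, rho^2)` with dispersion
  `rho ∈ {0.1, 0.25, 1}`: at `rho = 0.1` the signal is a tight spatial
  cluster, at `rho = 1` causal and neutral variants are spatially
  indistinguishable.

All generators are deterministic given a seed; replicates use spawned
`SeedSequence` streams.

## Experiments and problem sizes

* **Signal-detection type-I error**: 1000 fresh null genes, `B = 1000`
  score draws each; a rejection is any window below the threshold.
* **Gene-level size**: per synthetic gene the genotypes and covariate are
  fixed and thousands of independent null phenotype vectors are drawn;
  `U`, `sigma2_hat` and all window tests are recomputed per draw (fully
  vectorised). The acceptance run uses 500 genes × 4000 draws = 2×10^6
  null replicates, enough to resolve the empirical size at
  `alpha = 1e-4`; the test-suite proxy calibrates at `alpha = 0.01` over
  2×10^4 replicates.
* **Power**: Cauchy gene p-values for the 3D scan (mean/variance), the 1D
  scan (mean/variance), and whole-gene burden/SKAT on the same datasets,
  at `alpha = 1e-3` (reduced from genome-wide thresholds to keep
  replicate counts small) over ~120–400 replicates per scenario.
* **Sensitivity/specificity**: per-variant definitions — sensitivity is
  the fraction of causal variants inside detected regions, specificity
  the fraction of neutral variants outside them, averaged over
  replicates.

## Known limitations

* No LD in the generator: power orderings that depend on correlated
  neutral variants hitchhiking on causal ones are not represented; the
  whole-gene burden test is likely somewhat stronger here (independent
  effects average coherently) than with real haplotypes.
* Under dense, spatially dispersed signals the scan pays its
  multiple-window combination cost without a focusing benefit; with this
  generator the whole-gene burden/SKAT tests retain a real edge in
  exactly those regimes (the scan trails burden by ~8–10 power points at
  `rho = 1`, dense unidirectional; SKAT edges the variance scan by ~5
  points under dense bidirectional effects, at alpha = 1e-3, n = 1000,
  400 replicates). With spatially clustered signals the scan's advantage
  is large (tens of points). Passing or failing these orderings therefore
  speaks to behaviour under independent variants, not to behaviour on
  LD-structured sequence data.
* In sparse strong-effect scenarios without LD, individual rare variants
  carry large standardised effects, making the Bonferroni single-variant
  comparator unusually competitive in sensitivity (within a few points of
  the 1D scans); on real LD-structured data per-variant tests are
  typically far weaker than any aggregation test.
* The variance-test tail below ~1e-9 relies on the moment approximation
  (order-of-magnitude accuracy only).
* Binary traits, meta-analysis, missing-genotype handling, and
  variant-to-structure mapping itself are out of scope; coordinates are
  consumed as given.
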