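# Methods

`ordgeom` treats ordination not as a 2-D visualization device but as an
embedding framework: community dissimilarities (or rCLR-transformed
compositions) are projected into coordinate spaces of many dimensionalities,
and the *geometry* of those spaces — trajectory directions, local
neighborhood structure, variance partitions — is analyzed as a function of
the embedding dimension. The package bundles a synthetic microcosm
generator so that every stage is testable without sequencing data.

## The synthetic microcosm generator

The generator emulates a soil bioaugmentation experiment: `soils ×
treatments × replicates × days` microcosms (default 3 × 2 × 3 × 5 = 90
samples per marker gene), each yielding a feature (OTU) count vector.

Generative model, per sample with soil *s*, treatment *t*, day *d*:

1. **Baseline.** Each soil's baseline composition is a single draw from a
   symmetric Dirichlet with concentration 0.3 per feature (default 500
   features). Small concentrations give the heavy-tailed, sparse
   compositions typical of soil amplicon tables, and independent draws per
   soil make between-soil differences dominate — the variance ordering
   (soil ≫ day > treatment, all detectable by PERMANOVA on Bray–Curtis at
   the default effect sizes) matches the whole-community structure the
   package is designed to resolve.
2. **Temporal drift.** A per-soil direction vector in log-composition
   space, entries i.i.d. normal with SD `drift_scale` (default 1.0 per
   feature), scaled by m(d) = log1p(d)/log1p(d_max): community change is
   fast early and decelerates, and both treatment arms share the same
   drift, producing the "nearly parallel trajectories" regime.
3. **Treatment shift.** For inoculated samples only, an additional log-space
   vector (SD `treatment_shift`, default 0.25/feature) orthogonalized
   against the drift direction. A per-soil **divergence angle** rotates the
   inoculated arm's drift within the drift–shift plane (default 1.25 rad
   for soil G, 0 elsewhere), so one soil *bends* its temporal trajectory in
   response to inoculation rather than merely offsetting it — the geometry
   that trajectory cosines detect and plain variance partitioning largely
   misses.
4. **Inoculant decay.** The inoculant feature's relative abundance is
   pinned: 0 in controls; in inoculated samples it interpolates
   log-linearly from `inoculant_initial_fraction` at day 0 (default 0.05;
   an inoculum of ~5×10⁸ cells against ~10¹⁰ 16S copies per microcosm
   implies a few percent, and the exact value is a free parameter) down to
   a soil-specific residual at the final day (defaults 0.33 % / 0.17 % /
   0.05 % for G / AT / ANT). Log-linear interpolation reproduces an
   order-of-magnitude decline with two parameters per soil.
5. **Counts.** Library size ~ Poisson(`library_size`, default 10⁵);
   composition jittered by a Dirichlet with precision `overdispersion`
   (default 200) times the expected composition; counts multinomial. The
   Dirichlet-multinomial gives realistic replicate-to-replicate
   overdispersion relative to pure multinomial resampling.

A random ultrametric coalescent tree (exponential internode times, rate
k(k−1)/2) supplies the phylogeny for UniFrac. All randomness flows from
one master seed through named substreams (`soil:ANT`, `counts`, `tree`,
`hopkins`, …) so each stage is reproducible in isolation.

**What the generator does not emulate:** taxonomic structure (the tree is
independent of the compositions), PCR/sequencing error, UMI artifacts,
compositional correlations between features beyond the Dirichlet's weak
negative coupling, and any fit to real deposited data. Tests passing on
synthetic data therefore establish the *machinery* (metrics, embeddings,
inference) and the qualitative phenomenology, not quantitative agreement
with any real soil community.

## Dissimilarities and transforms

- **Bray–Curtis** on raw counts (no rarefaction; the emulated workflow
  computes it on unrarefied UMI counts): BC = 1 − 2Σmin/Σ(x+y).
- **Weighted UniFrac**, normalized by default (the common `wunifrac`
  behavior); the raw form Σℓ_b|p_b − q_b| is a flag. Which variant a given
  study used is often unstated, so both are exposed and the choice is a
  config key.
- **rCLR**: log counts centered per sample over observed (nonzero) entries
  only; zeros become missing, never imputed. Features with total count
  < 8 are dropped first (the RPCA stability pre-filter); the raw-table
  analog is the ≥10-count feature filter, exposed as a plain table
  operation.

## Embeddings

All methods run at the nine-dimensionality sweep d ∈ {2, 3, 4, 7, 10, 15,
20, 30, 70}; coordinates are column-centered with a fixed sign convention
(largest-magnitude entry of each axis positive) so reruns are comparable.

- **PCoA** — classical scaling. No Cailliez/Lingoes correction: requesting
  more axes than there are positive eigenvalues is an explicit error, which
  the sweep records as a per-dimension skip. This makes the feasibility
  boundary of high-d embeddings visible instead of fabricating axes (e.g.
  weighted-UniFrac matrices of 90 samples typically support ~45 axes, so
  d = 70 is reported skipped).
- **Sammon mapping** — gradient descent on E = (Σd)⁻¹Σ(d−δ)²/d with step
  halving (step shrinks ×0.5 until stress decreases, regrows ×1.2 after
  success), so the stress trace is non-increasing by construction;
  PCoA initialization; stop at |ΔE| < 1e-9 or 500 iterations.
  Zero off-diagonal distances are an error (the 1/d weights are undefined)
  with advice to jitter or deduplicate, mirroring the classic
  implementation's behavior.
- **NMDS** — Kruskal stress-1 with monotone regression. The SMACOF
  optimizer is delegated to scikit-learn (`metric_mds=False`); restarts
  (one PCoA start + 19 random starts by default, 300 iterations) and
  best-solution selection by stress-1 (computed here via isotonic
  regression of embedded distances on dissimilarities) are package code.
  No autotransform/standardization: the input is already a distance matrix.
- **RPCA** — rCLR followed by rank-d completion of the masked matrix by
  alternating truncated SVD (missing entries refilled from the current
  reconstruction; stop when the relative Frobenius change < 1e-6).
  Coordinates are U_d·s_d. On typical 50 %-zero tables the fixed point is
  approached but not reached within the default 500 iterations; the
  `converged` flag reports this honestly and coordinates are stable to well
  below the scale of any downstream quantity. Phylogeny-aware RPCA is an
  adapter slot only. UMAP is likewise an optional external adapter, not
  re-implemented.

## Trajectory geometry

Per replicate, samples are ordered by day; vectors are endpoint differences
(global: day 0 → final; segments: successive day pairs). cos θ is computed
for every control × inoculated replicate pair within a soil and summarized
by plain arithmetic mean and population SD (no Fisher transform — means of
the raw cosines are what the summarized quantity is). Values within 1e-12
of ±1 are snapped to ±1 so the analytic anchors are exact. Smoothness is
the mean cosine between successive segments (zero-length segments are an
error, not silently skipped, because skipping would bias the mean);
linearity is net displacement over path length, in [0, 1]. Replicates
missing an endpoint day are excluded from pairwise comparisons with a
warning; surviving consecutive segments are used for smoothness.

## Dimension diagnostics

- **SNR**: mean Euclidean distance over same-soil/same-day cross-treatment
  pairs divided by the same-soil/same-day same-treatment mean. Pairs are
  pooled across soils by default (a per-soil option exists) and pooled into
  one global mean rather than per-stratum means, because the definition is
  stated in terms of pair sets.
- **kNN statistics** (k = 5): each point's mean distance to its k nearest
  neighbors, averaged over points, with the coefficient of variation
  (population SD/mean) across points. The "distance to the k-th neighbor"
  reading of the statistic is available as a mode switch, since either
  convention appears in practice.
- **Hopkins statistic** (m = 50 real + 50 probe points): probes drawn
  uniformly in the data's axis-aligned bounding box, real points sampled
  without replacement, plain (un-exponentiated) nearest-neighbor distances
  per Lawson & Jurs; H = Σu/(Σu+Σw). ≈0.5 for spatial randomness, →1 for
  clustered data; seeded.

## Inference

PERMANOVA partitions the Gower-centered squared-distance matrix with
sequential (Type I) sums of squares in the stated term order (soil, day,
treatment) via projection matrices — the convention whose R² pattern the
emulated analysis implies. Marginal SS is not offered; the sequential form
is the contract. P-values use free (unrestricted) permutation of sample
labels with the +1 correction, default 999 permutations (an `exhaustive`
mode enumerates all permutations for small n, used by the test oracles).
Day is categorical (5 unevenly spaced levels), not a linear trend.
Soil-wise models pool time points and test treatment only. Pairwise
PERMANOVA applies Benjamini–Hochberg adjustment across level pairs.
β-dispersion is distance-to-group-centroid, computed in coordinate space or
in the full positive-eigenvalue PCoA space of a distance matrix (the two
routes coincide on Euclidean input). Shannon uses natural log; Chao1 is
S_obs + F₁²/(2F₂) with the F₂ = 0 substitution F₁(F₁−1)/2.

The exclusion reanalysis removes a feature set (the inoculant OTU) and
rescales each sample's remaining counts to its original total ("rescaled to
100 %"), so abundance-based distances afterwards reflect only compositional
differences among surviving features. Without rescaling, the bulk removed
from inoculated samples would masquerade as a residual treatment effect.

## Numerical choices and degenerate inputs

- Positive-eigenvalue threshold for classical scaling: 1e-12 × the largest
  |eigenvalue|.
- cos θ snap tolerance 1e-12; Bray–Curtis of two all-zero samples is an
  error (undefined), not 0.
- PERMANOVA requires ≥ 99 permutations (or 0 to skip the test), never
  returns p = 0, and refuses constant factors and designs without residual
  degrees of freedom.
- Hopkins refuses degenerate (all-coincident) bounding boxes; kNN with all
  coincident points returns mean 0 with CV defined as 0 under a warning.
- The pipeline derives every stage's randomness from the master seed via
  named substreams and records sha256 checksums of all numeric artifacts,
  so a rerun with the same config and seed is checksum-identical.

## Problem sizes

Default analysis sizes — 90 samples × 500 features, nine dimensionalities,
999 permutations, 20 NMDS starts — run end to end in a few minutes on one
CPU. The test suite's calibration studies use reduced sizes chosen for
statistical adequacy (e.g. 500 simulations at 199 permutations for type-I
error; 100 seeds for Hopkins calibration; 40 × 60 matrices for completion
recovery).

## Known limitations

- The RPCA completion is the plain alternating-SVD scheme, without the
  regularization of specialized robust-Aitchison implementations; on very
  sparse tables its masked-entry estimates are not identifiable and only
  the leading sample-space structure should be interpreted.
- NMDS inherits SMACOF's local-minimum behavior; multi-start mitigates but
  does not eliminate it.
- The generator's features are exchangeable apart from the inoculant; no
  phylogenetic signal links the tree to compositions, so UniFrac on
  synthetic data behaves like a branch-weighted rearrangement of
  Bray–Curtis rather than capturing genuine clade structure.
- PERMANOVA uses free permutations; repeated-measures structure across days
  (the same microcosm sampled destructively over time in the emulated
  design) is not modeled as strata.
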