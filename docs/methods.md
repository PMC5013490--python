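# Methods

This note documents the models, conventions and numerical choices behind
`forestbeta`, and what the synthetic-data tests do and do not establish
about real censuses.

## Study design emulated

The analysis targets a chronosequence of nine 1-ha (100 × 100 m)
stem-mapped plots in three disturbance regimes (1 = twice-cut, 2 =
once-cut, 3 = old-growth; three plots each), censused down to dbh ≥ 1 cm
and gridded into 10 × 10 m or 20 × 20 m subplots. Turnover is analysed at
two levels: all subplot pairs **within** each plot, and all subplot pairs
**between** different plots of the same regime. Stems are optionally split
into dbh size classes [1, 5), [5, 10), [10, ∞) cm (the census threshold and
grouping are stated as ranges in the field literature without boundary
rules; half-open intervals make the partition exact, and the three
size-class community matrices sum cell-wise to the all-stems matrix).
Coordinates are half-open [0, 100) per axis; a stem at exactly 100 is
invalid rather than wrapped, so gridding is unambiguous.

## Turnover statistics

**Chao–Jaccard.** The abundance-based Chao estimator of Jaccard similarity:
with samples *x*, *y* (totals *n*, *m*) and shared species *S*,
U = Σ_{i∈S} x_i/n + ((m−1)/m)·(f₊₁/(2f₊₂))·Σ_{i∈S, y_i=1} x_i/n, where
f₊₁/f₊₂ count shared species that are singletons/doubletons in *y* (a zero
f₊₂ is replaced by 1), V symmetrically, both capped at 1; similarity
UV/(U+V−UV). Pairs with no shared species have dissimilarity 1; empty
communities are excluded from pairing rather than assigned a value, since
every index below divides by abundance sums. The implementation reproduces
R `vegan`'s `chao` index to ≥ 9 decimals (cross-checked in the test suite).

**B_st / τ_st.** Mean abundance-weighted pairwise distances use the
*species-centered* normalization — the expected distance between two
individuals drawn from communities *k* and *l* conditional on being
different species. The source equations for this statistic family exist in
both species-centered and unnormalized ("raw" Σδff) forms; species-centered
is the default and the raw variant is available behind
`variant="raw"` for sensitivity analysis. Degenerate cases: a monospecific
community has D_kk = 0 (flagged), so regime means stay computable; a pair
of identical monocultures has D_kl = 0 and B_st undefined — such pairs are
excluded with a logged count. B_st is invariant to global rescaling of the
distance matrix (so dendrogram height conventions are immaterial) and to
swapping the pair.

**Functional distances.** Traits are natural-log transformed and z-scored
across species (they are positive physical magnitudes, so the log is always
defined; a zero-variance trait column is an error). Per-trait distances are
cophenetic distances on a UPGMA (average-linkage) dendrogram of the
standardized values; the composite all-traits distance applies PCA to the
standardized table and builds the UPGMA dendrogram on Euclidean distances
over **all** retained axes. Retaining all axes removes an arbitrary
truncation threshold and makes the pre-dendrogram distance identical to the
Euclidean distance on the standardized traits (orthogonal-rotation
invariance, asserted to 1e-9). The cophenetic distance is the
average-linkage merge distance of the pair's first common cluster, the
standard convention shared by scipy and R `cophenetic`; it is ultrametric
by construction. Raw (pre-dendrogram) distances are available behind
`distance="raw"` since the per-trait figure-level analysis could plausibly
use either.

**Phylogenetic distances** are patristic distances on the supplied
ultrametric tree. Ultrametricity is checked with relative tolerance 1e-6
and violations warn rather than fail, since rate-smoothed empirical trees
carry rounding error.

## Blomberg's K

K = (observed MSE₀/MSE) / (expected MSE₀/MSE) with the GLS mean
â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x and expected ratio (tr V − n/1ᵀV⁻¹1)/(n−1), where V
is the Brownian-motion tip covariance (shared root-to-MRCA path lengths).
V⁻¹ is applied via Cholesky solves only, with jitter 1e-10·tr(V)/n added on
failure (near-duplicate tips). Significance: trait values are permuted
across tips 999 times; the 95% CI is the empirical 2.5–97.5% of null K, and
the reported significance flag is one-sided (observed above the upper
bound, i.e. more signal than chance), while the CI itself is two-sided. At
least 99 permutations are required for stable percentiles. Calibration:
mean K over 200 Brownian traits on a 64-tip Yule tree is 1.0 ± 0.1
(recomputed by `scripts/acceptance.py`); K on a star tree is exactly 1.

## Null model

One label permutation of the distance matrix per replicate, shared across
**all** pairs — the dendrogram/tree is shuffled once per random community
set, preserving the cross-pair correlation structure of the null.
Composition is never touched, so abundance, richness and Chao–Jaccard
dissimilarity are bit-identical across replicates (asserted). Envelopes
summarise the distribution of **grouping means** (regime × level by
default), matching figure-level grey bands drawn around per-regime means;
per-pair envelopes would cost 999 × pairs and are not the default reading.
SES = (obs − mean null)/sd null; rank p = (#{null ≥ obs}+1)/(n+1).
Replicates draw from per-replicate child seeds of one master seed, so any
replicate is reproducible in isolation.

Exchangeability argument: when composition is generated without reference
to the tree (neutral mode), the observed grouping mean is one more draw
from the null distribution, so ~95% of datasets fall inside the 95%
envelope. This is the pipeline's headline calibration (target ~95%,
asserted within [90, 98.5] over 200 reduced datasets).

## Mixed models

Each pair-level statistic is modelled with fixed effects: disturbance
regime (categorical, dummy-coded), log habitat distance, regime × log
habitat distance, plot mean elevation, log spatial distance; and random
intercepts for regime and for the plot (within-plot pairs) or the
unordered plot pair (between-plot pairs; a between-plot pair belongs to no
single plot, and the plot-pair convention keeps groups well defined).
Habitat distance is the 5-D Euclidean distance over z-scored mean
elevation, slope and convexity plus sin/cos of aspect, with z-scoring
statistics computed once over the analysis set per grain. Zero distances
are guarded as log(d + ε) with ε = 1e-6 × the median positive distance
(recorded in metadata). For between-plot pairs, plot mean elevation enters
as the mean of the two plots' means by default (`elev_coding="absdiff"`
switches to the absolute difference). Columns that become collinear with
earlier terms (e.g. plot mean elevation when each regime contributes a
single plot pair) are dropped greedily in term order and recorded.

Fitting is REML on the profiled criterion with the covariance handled by
the Woodbury identity (cost scales with the number of grouping levels, not
n). The optimizer works on the variance ratios λ_g = σ_g²/σ² directly with
a zero lower bound and two starts (1, 0.01); the boundary is accepted only
when it is genuinely at least as good, because a √λ parametrization was
found to absorb small positive optima into the boundary (checked against a
grid-search oracle). Estimates agree with statsmodels `MixedLM` to ~1e-6.
A fit with a variance component at 0 is returned with a boundary flag, not
an error — with regime both fixed and random on three levels, boundary
fits are expected.

**Satterthwaite tests.** For contrast c, ddf = 2(cᵀΦ̂c)²/(∇vᵀA∇v) with
v(θ) = cᵀΦ(θ)c, θ the variance parameters (σ_g², σ²), ∇v a central-
difference gradient and A = 2H⁻¹ from the numerical Hessian of the REML
deviance; boundary components are excluded from θ. Multi-df terms use the
eigen-decomposition of CΦ̂Cᵀ with the Fai–Cornelius pooling
ddf = 2E/(E−q), E = Σ ν_i/(ν_i−2). The implementation matches R
`lmerTest`'s Satterthwaite ANOVA to four decimals on a mixed
between/within design, and reduces to the residual df in the no-random-
effect limit. Backward pruning refits after dropping the least significant
term with p > 0.05, interactions before their main effects, each step
recorded.

**LRT of random structures** uses 2Δ logLik against the boundary mixture
0.5·χ²₀ + 0.5·χ²₁ (one variance component tested at zero). At reduced
sizes the finite-sample mass at zero of the null statistic is ~0.6 (above
the asymptotic 0.5, verified against a grid-search oracle), which the test
bands accommodate.

**Single-step contrasts.** All pairwise regime differences — evaluated at
the mean log habitat distance when the interaction is present — are
adjusted by P(max|T| ≥ |t|) under the joint multivariate t (correlation
from Φ̂, df = mean Satterthwaite df), integrated by seeded Monte Carlo
(2¹⁴ draws); adjusted p is floored at the unadjusted p. Compact letters
group regimes not significantly different at α = 0.05.

**Residual correlograms.** Pairs are located at the midpoint of their two
subplot centroids in the shared reserve frame; Moran's I is computed per
equal-frequency distance class with two-sided permutation p (499
permutations), Bonferroni-adjusted over classes. Tables above 1500 pair
midpoints are thinned by seeded subsampling to bound the O(n²) weight
matrices.

Pseudoreplication caveat: pairwise records sharing a subplot are not
independent; this is addressed only through the random-effect structure
(the design of the original analysis), and reports carry the caveat rather
than a Mantel-type correction.

## Synthetic chronosequence generator

The generator's defaults encode the study conditions: 180 species,
3 regimes × 3 plots, ~6,500 stems per plot (Poisson), dbh ≥ 1 cm. Where
the emulated design is qualitative, the encoding is a construct of this
package (and labelled as such in the dataset manifest):

- **Phylogeny**: pure-birth (Yule) tree, depth scaled to 1, with a final
  exponential extension so no terminal branch is zero.
- **Traits**: z = √w·b + √(1−w)·e with b a standardized Brownian
  realization and e standardized white noise, mapped to positive scales as
  exp(z·s + m) with per-trait lognormal defaults chosen for realistic
  magnitudes (SLA ≈ 15 mm²/mg, WD ≈ 0.55 g/cm³, MH ≈ 12 m, ...). w = 1
  recovers K ≈ 1; the default w = 0.5 mirrors weak-but-present signal.
- **Habitat**: squared-exponential Gaussian random fields (range 30 m) on
  a 5 m base grid, aggregated to any multiple of 5 m dividing 100 (25 m is
  used for reduced 4 × 4-subplot test datasets); plot base elevations are
  uniform on 372.6–772.9 m. The disturbance gradient is encoded as
  per-regime multipliers on within-plot habitat amplitude
  (default 0.5/0.75/1.0 — heterogeneity recovering after disturbance) plus
  per-regime truncation of the regional species pool
  (default 0.6/0.8/1.0 — disturbed plots start from a homogenized subset).
- **Census**: a Thomas cluster process (parents uniform, offsets at the
  dispersal scale, default 20 m) places stems; modes differ only in species
  choice. *Neutral*: parents carry species drawn from a lognormal regional
  SAD (sd 1.2 on the log scale). *Filtering*: per-stem species probability
  ∝ regional abundance × exp(−(t_s − h)²/2σ²), with t_s the standardized
  first PCA axis of the traits and h the within-plot standardized elevation
  anomaly at the stem's location (filtering acts on local topographic
  position; between-plot elevation differences are controlled for in the
  models and would otherwise swamp the within-plot signal). *Priority*:
  a neutral first cohort, then a fraction of stems cloned from random
  earlier stems nearby (resprouting). dbh is a truncated exponential on
  [1, 80] cm (scale 8 cm) — a convenience, not a fitted stand structure.

A dataset is a pure function of its scenario (seed included); sub-streams
for tree, traits, habitat, layout and census are spawned from the scenario
seed.

**What the generator does not emulate**: demographic dynamics through time
(a census is drawn in one pass), species-specific dispersal kernels,
realistic spatial covariance of soil nutrients, trait–trait covariance
structure, or measurement error in traits and topography. Passing tests
establish that the chain detects the encoded processes at the encoded
strengths; they do not establish power for weaker real-world effects.

## Problem sizes used in tests

Test and calibration runs use reduced sizes chosen to exercise every code
path at desk scale: 20–40 species, 2–6 plots, 300–800 stems per plot,
16–25 subplots per plot, 99–999 permutation replicates; the mixed-model
calibration uses 100 recovery fits at n = 2700 pairs and 500 null fits at
n = 270. One test grids a full-scale census (9 plots, ~58k stems, 183
species) to confirm count conservation at the real design's size.

## Known limitations

- The regime factor is simultaneously fixed and random (three levels), as
  the emulated analysis specifies; its variance component frequently sits
  on the boundary and its practical effect is absorbed by the fixed
  dummies. The LRT utility lets users compare against the plot-only
  structure.
- Satterthwaite ddf relies on numerical derivatives of the REML criterion;
  components estimated exactly at zero are excluded from the variance-
  parameter covariance rather than handled by a boundary-aware expansion.
- The Chao–Jaccard index is undefined for empty samples and the B_st family
  for identical monocultures; both are excluded (with counts logged) rather
  than imputed.
- Between-plot spatial distances require plot origins in a shared frame;
  synthetic layouts place plots on a jittered grid, which is not a model of
  any real reserve geometry.
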