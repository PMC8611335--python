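# Methods

This note documents the models, numerical conventions and design
choices behind `myxomorph`, and what the synthetic-data generators do
and do not emulate.

## Image processing and trait measurement

**8-bit conversion.** 16-bit grey images are rescaled linearly from
their observed [min, max] range to [0, 255] with half-up rounding; a
constant image maps to all zeros. This matches the common display-range
conversion while staying deterministic. 8-bit input passes through
unchanged; multi-channel input is rejected.

**Triangle threshold.** The Zack–Gruber–Spinelli rule: draw the chord
from the histogram's maximum-count bin to the farthest non-empty bin
and take the bin whose histogram point lies at maximal perpendicular
distance from that chord, ties broken toward the peak. The geometry is
computed directly for either tail orientation, which is algebraically
identical to the classical "reflect the histogram, apply the rule, map
the index back" formulation. When the two tails are exactly equidistant
from the peak the dark tail is preferred (deterministic). No histogram
smoothing is applied.

**Object-side guard.** For dark objects the threshold must fall on the
dark side of the histogram mode: a threshold at or above the mode would
place the background itself in the foreground. That situation arises
only when the histogram has no object class — e.g. a blank spot whose
slightly longer noise tail happens to lie on the bright side — and the
plate is then reported as object-free. The symmetric rule applies to
bright objects.

**Segmentation.** The histogram is computed only over ROI pixels not
under the dust mask. Foreground pixels (≤ threshold for dark objects)
are labelled into connected components (8-connectivity by default,
4 selectable) within the ROI; components smaller than 20 px² are
excluded, those of exactly 20 px² retained ("smaller than" is strict).
No maximum-size or shape filtering is applied. Per-region density and
heterogeneity are measured on the original 8-bit grey values
(population SD, ddof = 0). Pixels under the dust mask never enter a
region; a region touching dust keeps only its unmasked pixels.

**Density convention.** Density is the raw mean grey value. With dark
objects on a bright background, *lower* values mean denser bodies.
`measure_plate(..., invert_density=True)` reports 255 − mean instead;
it is off by default.

**ROI.** Either a user-supplied circle (reproducible) or automatic
detection (Gaussian blur, Otsu split, largest connected component,
convex hull) — a convenience for unannotated images.

**Plate summaries and aggregation.** Each plate yields the body count
plus the medians of area, density and heterogeneity (median of an
even-length list = mean of the central pair). A plate with zero bodies
keeps count 0 but missing medians. Aggregation is a two-stage mean:
within each assay replicate, average across the populations of a group;
then average the per-assay means across assays, reporting the s.e.m.
across assays. Missing medians are omitted pairwise with the effective
number of assays recorded; a group with no surviving populations is
absent, never zero.

## Morphospace

Observations (one population per assay replicate) are z-scored per
trait with the sample SD (ddof = 1) of the fitted reference set —
ancestor subclones and all evolved populations of the analysed cycle
together, so all groups share one morphospace. Zero-variance traits are
dropped with a warning. PCA is the eigendecomposition of the sample
covariance of the standardized matrix (z-scoring makes this the
correlation PCA of the raw traits); each component's sign is fixed so
its largest-magnitude loading is positive, making runs reproducible.
Observations with missing traits are excluded from fitting and flagged;
their counts still feed univariate summaries.

**Centroids and confidence regions.** A group's three per-assay mean
positions in the PC1–PC2 plane give the centroid (their mean) and a
small-sample Hotelling-type 95 % region for it:
{μ : n (x̄−μ)ᵀ S⁻¹ (x̄−μ) ≤ p(n−1)/(n−p) · F_{p,n−p}(0.95)} with p = 2.
Coverage is exact for Gaussian replicates at any n ≥ p + 1 (verified by
simulation). Collinear or identical replicates give a degenerate
(zero-area) region, flagged rather than drawn.

**Clustering.** Treatment-level mean trait vectors (standardized) are
clustered agglomeratively with Euclidean distance and Ward linkage; the
dendrogram is exported as Newick with ultrametric branch lengths
derived from merge heights. Linkage and the flat-cut k are exposed as
parameters; Ward/Euclidean is the package's default choice for compact
morphological clusters, isolated behind one function.

**Diversification.** Within-group dispersion for one assay is the mean
pairwise Euclidean distance among the replicate populations' trait
vectors in standardized space — the canonical dispersion statistic: it
is zero iff all populations coincide, invariant to relabeling and to
orthogonal rotations of trait space, and scales linearly when
deviations from the group mean are scaled. Cross-assay aggregation is
mean ± s.e.m. (n = 3). Groups with fewer than two populations in every
assay (heavy early extinction) are flagged not-analysable.

## Mixing effects and extinction

For focal strain *i* mixed 1:1 with partner *j* at initial frequency
f_i: C_i(j) = log₁₀[(s_mix,i/f_i)/s_pure,i] compares the focal strain's
frequency-adjusted per-input spore output in the mix to its monoculture
output; B_ij = log₁₀[(s_mix,i+s_mix,j)/(f_i·s_pure,i+f_j·s_pure,j)]
compares total mix output to the frequency-weighted monoculture
expectation. Both are 0 when mixing has no effect, strictly increasing
in the mix counts, and invariant to rescaling all counts by a common
factor. The expectation in B is the frequency-weighted sum (at
f = 0.5 an unweighted-mean convention differs only by the weighting of
unequal monocultures); both formulas live in single functions so a
variant convention is a one-line change. A mix plating with zero spores
is below the detection limit: its C is −∞, excluded from tests with the
count reported, rather than averaged.

One-sample t-tests against 0 are classical two-sided tests; zero sample
variance is degenerate (p = 0 for a nonzero mean, p = 1 at the null).
The extinction analysis builds per-treatment surviving-count series
from a ledger of extinction cycles (extinction strikes at the
development step, so an extinct population has no record at that cycle)
and tests extinction vs partner category with the standard two-sided
Fisher exact rule (sum of hypergeometric probabilities not exceeding
the observed table's). Contrasts use per-assay group means as units:
two-sample t-tests for evolved-vs-ancestor, one-way ANOVA with Tukey
HSD (adjusted within each ANOVA family; no cross-trait correction) for
category comparisons.

## Synthetic data

**Plate renderer.** A bright circular spot (default 200 grey units) on
a darker plate surface, with dark blobs (default interior 120) placed
fully inside the ROI without overlap by rejection sampling (error after
10⁴ attempts). Each blob is a flat-core disk with a Gaussian edge
rolloff of fixed width (default σ = 0.5 px, emulating the fixed optical
blur of the imaging system; σ = 0 gives hard disks), optional interior
Gaussian texture, optional bright dust specks recorded into the dust
mask, and global Gaussian pixel noise (default SD 2). A
radius-proportional rolloff was rejected: the Triangle threshold sits
at the foot of the background peak, so segmentation recovers a blob's
full detectable footprint, and an edge band that grows with the radius
makes that footprint diverge from any fixed geometric truth.

Ground truth per body: center, radius, true area = the counted
darker-than-background pixel footprint of the quantized noiseless
render (so truth and render are consistent by construction), and the
interior mean/SD over the flat core. With default settings the
segmentation recovers body counts exactly and areas to ≈ 11 % mean
relative error per plate; individual small regions can deviate more
because a ±1 grey-level shift of the threshold moves the boundary by
a pixel ring. Exactness (density equal to the planted interior mean,
zero heterogeneity) holds for hard-edged, noise-free renders, where the
segmented region is exactly the uniform core.

**Evolution simulator.** The default design mirrors the experiment:
8 treatments (no-partner control, a benign cooperator, three cheaters,
three antagonists) × 8 replicate populations × 10 cycles × 3 assay
replicates. A population's trait vector at cycle c is ancestor +
(c/10)·treatment effect + random walk (per-cycle SD) + per-assay
measurement noise; per-cycle extinction hazards remove populations
before that cycle's record. Defaults: ancestor (400 bodies, 120 px²,
110 grey, 12 grey); cheater effects are large count/area decreases,
antagonist effects small with 0.05 hazards, and one lethal antagonist
(hazard 0.35) whose populations are lost early — emulating the
qualitative structure of the real outcome (moderate overall extinction
concentrated in antagonist treatments). Trait values are floored at 0
and counts rounded to integers.

**Mix-assay simulator.** Monoculture counts are drawn log-normally
around stated means; mix counts are back-computed from target C values
(B follows from C_i, C_j and the pure means) with independent
log-normal noise, so zero-noise recovery is exact and noisy recovery is
unbiased in log₁₀ units.

**What the generators do not emulate.** No cell motility or
aggregation mechanics; no uneven illumination, vignetting or focus
gradients; no spatial correlation in pixel noise; blobs never overlap
or touch the spot edge; trait trajectories are Gaussian with linear
deterministic trends, without mutation-driven jumps or
frequency-dependent interactions. Passing the recovery tests therefore
demonstrates correctness of the measurement and inference chain under
controlled image statistics, not robustness to every artefact of real
plate photography.

## Problem sizes and numerical choices

Recovery suites use 100 seeded 640 × 640 renders with 5–150 bodies for
segmentation, 100 simulated-design runs for centroid separation (with
planted effects of 2 assay-noise SDs, the boundary of the stated
condition), 200 runs for Tukey detection of a 5-SD planted shift, 2 000
simulations for ellipse coverage, and 1 000 replicates for mixing-effect
recovery. Tolerances: orthonormality and variance-fraction identities
at 1e−9; oracle agreement for PCA at 1e−8; exact integer equality for
the Triangle threshold. All generators and analyses are pure functions
of their inputs plus a single seed.

## Known limitations

- The automatic ROI detector assumes one bright spot on a darker
  plate; partial spots or multiple spots need a manual ROI.
- Density uses raw grey values; comparing across imaging sessions
  assumes identical acquisition settings.
- The diversification statistic and the clustering configuration are
  the package's documented choices of canonical methods; alternative
  dispersion or linkage conventions are single-function changes.
- Fisher's exact test, Tukey HSD, ANOVA and t-tests come from
  scipy.stats; PCA from scikit-learn; tests cross-check them against
  independent enumeration/eigendecomposition oracles.
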