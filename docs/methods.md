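# Methods

## Statistical model and procedure

The pipeline treats each mutant genotype as one observation in a
cross-genotype screen.  Within a genotype, sepal shape parameters are
summarized by their mean and squared coefficient of variation
CV² = (sd/mean)², with sd the sample (n−1) standard deviation throughout
(the n−1 convention is applied identically to phenotype CV², expression
CV², and the reference-band sd; CV² is invariant to measurement units, so
calibrated and uncalibrated tables give identical screens).  Each mutant's
effect size is the relative difference of its mean from the wild-type mean
of its *own* control batch — every mutant is grown and measured alongside
one batch of Col-0 controls, and batch-matching absorbs environmental
batch effects that would otherwise inflate apparent mutant effects.

The screens are two-sided Pearson tests across mutants: each response
(|relative effect| or CV², per parameter) against each expression
covariate (wild-type expression CV², or log₁₀ mean expression).  The p
value comes from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom, which is
what `scipy.stats.pearsonr` computes; the unit tests re-derive it through
the t formula independently.  Log base is a display convention only:
logarithms of different bases differ by an affine map, and Pearson r and p
are affine-invariant (asserted by a test comparing log₁₀ and ln runs).  No
multiple-testing correction is applied across the screen grid — the
screens report raw per-test p values, and the resilience experiments,
rather than a correction, carry the burden of showing the headline result
is not a selection artifact.  Mutants whose gene has zero mean expression
are excluded from log-scale screens with a warning (the logarithm is
undefined there; no such gene arises at the default conditions).

The wild-type reference band per parameter is the mean ± sd (n−1) of the
per-batch control CV² values.  Under a no-effect model with matched sample
sizes this 1-sd band contains a mutant's estimated CV² roughly 68% of the
time, which the null-simulation test checks as a pooled fraction in
[0.55, 0.80].

## Resilience experiments

**Subsampling.** Each of 1000 replicates draws 30 sepals per mutant
without replacement, recomputes every mutant's CV², and re-tests the
correlation against the (fixed) covariate.  The report keeps all (r, p)
pairs and the fraction significant at α = 0.05.  Randomness is structured
as one independent substream per (mutant, replicate), seeded by
`SeedSequence((master_seed, blake2s(label), replicate))`, and the
per-mutant value vectors are sorted before drawing — together this makes
the report bit-reproducible and invariant to the row order of the input
table.  A mutant with fewer sepals than requested triggers a policy:
`fail` (default) or `all` (use every sepal).  The covariate is not
recomputed per replicate; it does not depend on the subsample.

**Leave-x-out.** After optionally removing fixed exclusions (the pmr6+x
variants remove the *pmr6* mutant first), every selection of x distinct
remaining mutants is dropped in turn and the test recomputed.  The default
enumeration is *ordered* selections (x-permutations), giving n!/(n−x)!
tests — 16/240/3360 for 16 mutants and 15/210/2730 for 15 — which matches
the original analysis's reported counts; `ordered=False` gives the
non-redundant C(n, x) enumeration, and a test asserts the ordered result
multiset equals the unordered one with each entry repeated x! times.

**P-value densities.** Reports are summarized as Gaussian KDE densities of
log₁₀ p, renormalized on their evaluation grid to integrate to exactly 1,
so densities from experiments with different combination counts are
directly comparable by area.  A report with zero spread is returned as a
flagged point mass rather than a degenerate KDE.

## Morphometrics

Images are assumed to be top-view photographs of flattened sepals on a
black background, so global Otsu thresholding plus connected-component
labeling is an adequate segmentation; components below `min_object_px`
(default 100) are discarded and an all-background image yields an empty
result rather than an error.  The outer contour of a mask is extracted by
marching squares at level 0.5 on a zero-padded copy: the boundary then
runs half a pixel outside the outermost foreground pixel centers, which
makes the polygon area track the pixel count to well under 1% for blobs of
a few thousand pixels.  Raster coordinates (origin top-left, y down) are
converted to math convention (y up) at contour extraction; vertices are
deduplicated and oriented counter-clockwise.

Alignment translates the polygon's area centroid (shoelace moments) to
the origin and rotates the principal axis — the largest-variance direction
of the vertex cloud weighted by local arc length, so vertex density cannot
bias the axis — onto the vertical.  A near-tie between eigenvalues
(relative gap ≤ 1e−9, e.g. a circle or square) is broken in favour of the
axis with the larger extent.  Length is then the vertical extent, width
the horizontal extent, area the shoelace polygon area, and aspect ratio
length/width; a calibration factor (mm/px) converts units when supplied,
and parameters default to pixel units otherwise.  For exotic shapes whose
variance axis is not their longest extent the two extents are swapped so
that length ≥ width always holds.  These definitions (principal-axis
extents, not Feret diameters) match the flattened top-view imaging
convention.  Measured parameters are rigid-motion invariant to 1e−6
relative tolerance and exactly scale-equivariant, both asserted as
property tests.

## Synthetic data generator

The generator emulates the study design: 11 wild-type control batches and
16 mutants (carrying the real mutant labels, *bglu42* … *galt29a*, and AGI
gene ids) with 39–90 sepals each, mutants assigned round-robin to batches,
and a genes × 27-sepal wild-type expression matrix.

Per-sepal measurements are gamma draws parameterized by (mean, CV²) — a
strictly positive family matching exactly the two moments the analysis
uses; the gamma choice is a stand-in, not an inference about the real
measurement distribution.  Length and width are drawn independently with a
common per-genotype CV² c; per sepal, area = (π/4)·length·width and aspect
ratio = length/width are then deterministic, preserving the relations the
morphometrics stage produces.  For a target area CV² t the generator
solves (1+c)² − 1 = t, so the *true* area CV² equals t exactly; the true
aspect-ratio CV² has the closed form c(2−c)/(1−2c) (ratio moments of
independent gammas), recorded in the ground-truth object along with all
true means, for parameter-recovery tests.

Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| control_mean_area | 2.3 mm² | typical stage-13 Arabidopsis sepal (≈2.4 × 1.2 mm, aspect ratio 2) |
| control_cv2 | 0.012 | wild-type area CV² of order 1% (CV ≈ 11%) |
| effect_scale | 0.10 | sd of the mutants' relative mean-area shift; batch means vary at half that |
| planted_slope | 0.02 /decade | area CV² gain per decade of expression; with gene means spanning 10¹–10⁴ this separates mutant CV² well above estimation noise at n = 39–90 |
| noise_sd | 0.004 | scatter of true CV² around the planted line |
| expression trend | log₁₀CV² = −0.3 − 0.5·log₁₀mean ± 0.35, 5% outliers ×10^U(0.7,1.5) | qualitative decreasing mean–CV² cloud with highly variable genes |

The planted relation is linear in log₁₀ mean expression, anchored at the
low-expression end to the control CV², and is recovered exactly by
regression on the true values when noise_sd = 0 (a construction identity
asserted in tests).  Mutant gene means, CV² levels and mean shifts are
drawn from a dedicated seed stream shared by the measurement-table and
expression-matrix generators, so the two are individually callable yet
mutually consistent; all outputs are bit-reproducible from the config
seed.

What the generator does *not* emulate: batch-specific environmental
trends, measurement error from segmentation, correlations between length
and width beyond the shared genotype (they are conditionally independent),
parameter-specific expression coupling (one slope drives all parameters
through c), and any realistic RNA-seq count structure.  Consequently,
passing tests demonstrate that the *pipeline* is correct and well
calibrated — not that the biological result holds; in particular the
real data's intermediate width signal (significance in about half the
subsampling replicates) has no synthetic counterpart, because under the
single-slope design width carries the same planted signal as length.

Sepal outline fixtures are superellipses (exponent = `tip_sharpness`; 2
gives an exact ellipse, used for analytic-area oracles) with optional
multiplicative radial noise, rasterized by center-in-polygon filling into
8-bit grayscale white-on-black images.

## Numerical and design choices

* Pearson tests require n ≥ 3 and nonzero variance in both variables;
  zero variance raises a dedicated error (e.g. the sample-size confound
  check on a table with all-equal n).
* CV² levels are floored at 1e−4 inside the generator to keep gamma shape
  parameters finite; the floor is unreachable at the default conditions.
* Genotype/batch labels are normalized to lower case at ingestion;
  readers reject rather than coerce, writing each bad row exactly once to
  a rejects table with a reason code.
* The end-to-end runner writes no timestamps, so identical config + seed
  produces byte-identical CSVs; the manifest records inputs, seed and
  outputs.
* Null calibration is checked over 250 seeds at 16 screens each: the
  per-screen rejection band is the 99.9% binomial interval around 0.05
  (wide enough that 16 simultaneous checks have a small family error),
  and the pooled rate is held in [0.03, 0.07].
* Simulation-heavy tests use reduced problem sizes chosen for statistical
  sufficiency: 250 seeds (null), 100 seeds (power), 1000 × 3 subsampling
  replicates, 20–100 expression genes where the background cloud does not
  enter the statistic.

## Known limitations

* The segmentation/alignment stage is a deliberately simple re-creation
  of black-background sepal imaging practice; equivalence with any
  specific published extraction script is not claimed, and touching or
  overlapping sepals are not separated (they merge into one component).
* The xlsx supplementary-workbook layout is not ingested; the pipeline's
  canonical interchange format is CSV.
* Aspect-ratio truth formulas assume per-genotype CV² < 0.5 (always true
  at realistic settings).
* The subsampling report's covariate is treated as fixed; uncertainty in
  the expression summaries themselves is not propagated.
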