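# Methods

This note documents the models, conventions and numerical choices behind
`caryomorph`, and what the synthetic-data generator does and does not
emulate.

## Outline representation and conventions

An outline is a closed polygon of (x, y) points for one view of one
grain — *lateral* (grain seen in its thickness) or *ventral* (furrow
up). Units are pixels after mask tracing and millimetres after
calibration against two scale landmarks a known 1 cm apart; a unit flag
guarantees calibration is applied exactly once. Orientation is stored
counter-clockwise.

**Mask tracing.** The boundary of the largest 8-connected foreground
component is followed with the Moore-neighbour algorithm, yielding the
ordered loop of boundary *pixel centres* (a 10×10 square therefore
traces 36 pixels enclosing 81 px²). Holes are ignored. A second
component larger than 10% of the first aborts with an error: that is a
segmentation problem, not a grain.

**Resampling and the start point.** All analysis happens on outlines
resampled to k = 360 points equally spaced by arc length (ample for
≤ 10 harmonics and divisible for symmetry checks). The parameterization
origin is the point where the outline crosses its positive principal
major axis (the apex-end crossing, computed on a lightly smoothed probe
of the curve). This anchor is a continuous function of the geometry:
unlike a max-coordinate vertex, it does not jump by a whole sample under
small outline noise, which would otherwise bias mean-shape estimates
through phase smearing. The convention presumes an elongated outline
with a well-defined major axis, which grain silhouettes have; for
near-circular shapes the anchor (like any geometric start convention) is
unstable.

**Size indices.** Length and width are the extents of the ventral
outline along its principal major/minor axes; thickness is the lateral
minor-axis extent. Principal-axis extents rather than image-frame
extents make the indices rotation-proof, since file-borne outlines
cannot be assumed oriented. Centroid size (√Σ‖pᵢ−centroid‖²) is computed
per view on the k-point resampled outline so values are comparable
across grains. Whether "thickness" in the field's tables means the
lateral minor extent or a caliper measure is ambiguous; the
principal-axis reading is our operationalization and is stated here so
results are unambiguous.

## Elliptic Fourier analysis

Outlines are centred and scaled to centroid size 1 (no rotation: grains
are photographed in controlled orientation, and the start-point
convention fixes the parameter origin). The coefficients

aₙ, bₙ (for x) and cₙ, dₙ (for y) are computed as the discrete Fourier
cosine/sine coefficients of the k sampled coordinates, with the sample
index as the expansion parameter. Because every analysed outline is
first resampled equally by arc length, the parameter *is* normalized arc
length — the standard convention of outline morphometrics. The discrete
form is exact at the sample points: a circle of radius r sampled this
way gives (a₁, b₁, c₁, d₁) = (r, 0, 0, r) to machine precision, an
ellipse gives (A, 0, 0, B), and the forward transform agrees with
composite-trapezoid quadrature of the Fourier integrals identically.
(A chord-length-weighted chain-code form was considered and rejected:
under it even a perfect ellipse carries ≈ 0.7% of its power at harmonic
3, which breaks the analytic reference values used for verification.)

Truncation error of the inverse transform decreases monotonically in H;
on the package's grain templates the mean round-trip deviation at H = 20
is below 10⁻⁴ of the perimeter.

**Harmonic count.** The smallest H whose cumulative power fraction
(over H_max = 32) reaches a threshold, default 0.99. On clean synthetic
templates this rank is ~3; on noisy generated grains 4–8. The analysis
defaults are fixed at 5 (lateral) and 7 (ventral) harmonics — the
counts appropriate for real photographed material, whose mid-frequency
outline detail clean templates do not fully reproduce — and automatic
selection is available in the pipeline (`harmonics: null`).

An optional first-ellipse alignment (rotation/phase normalization
against harmonic 1) is provided but off by default; all defaults operate
on unrotated coefficients.

## Statistics

- **Rank tests** for size indices: tie-corrected Kruskal–Wallis H with
  χ² p-values (scipy); pairwise two-sided rank-sum tests (Mann–Whitney
  U reported as W, the convention of common statistical software), with
  Bonferroni adjustment by default (Holm and Benjamini–Hochberg
  selectable). An all-identical sample returns H = 0, p = 1, flagged.
- **MANOVA**: Pillai's trace with its standard F approximation, chosen
  for robustness among the four classical statistics. When the
  coefficient matrix is rank-deficient for the available degrees of
  freedom, features are first reduced to principal components capturing
  ≥ 99% of variance (never more than n − groups). With one feature the
  statistic reduces exactly to the one-way ANOVA F (verified against
  scipy and statsmodels).
- **Pairwise PERMANOVA**: pseudo-F on Euclidean distances per group
  pair, p = (1 + #{F* ≥ F}) / (1 + B), B = 999 by default, seeded, then
  multiplicity-adjusted. Type-I error is calibrated in the acceptance
  suite (rejection rate at α = 0.05 within the binomial band over 200
  null simulations).
- **Rarefaction**: for each subsample size n, the mean over B seeded
  subsamples of (total ML variance in subsample)/(total ML variance in
  the accession). Maximum-likelihood (ddof = 0) variances make the curve
  rise towards 1 — it measures the share of the population's variation
  a sample of n grains records — with recommended n the smallest whose
  mean ratio reaches 0.95.

## Classification

Classic linear discriminant analysis: pooled within-class covariance,
priors proportional to training counts, implemented directly (the
per-fold refits are verified assignment-for-assignment against an
independent implementation). A ridge term λ·mean(diag S), λ = 10⁻⁸, is
added only if the pooled covariance is singular, with a logged warning.
Class imbalance is handled by the priors, not by subsampling. All grains
of 6-row varieties enter classification — twisted lateral and untwisted
central grains alike — because archaeological grains cannot be sorted by
twist.

CVP is the leave-one-out accuracy in percent. Note that LOOCV with
proportional priors is slightly *anti*-conservative at chance level: the
held-out grain's own class has one fewer training member, biasing
assignment away from it (measured: ≈ 49% for 2 balanced classes, ≈ 23%
for 4, at n = 200). The 95% CI is the 2.5–97.5 percentile of CVP over
B = 100 stratified bootstrap resamples (classes resampled to their own
sizes, full LOOCV re-run per replicate), widened if needed to bracket
the observed CVP; a Wilson binomial interval is available
(`method="wilson"`) and labelled in output, since resampling and
binomial intervals answer slightly different questions.

## Distances, networks, genetics

- **Mahalanobis distances** between group mean feature vectors under the
  pooled within-group covariance, computed on PCA scores retaining
  ≥ 99% variance whenever the coefficient matrix is rank-deficient
  (consistent with the MANOVA guard). Whether the original analyses
  operated on raw coefficients or discriminant axes is not documented
  anywhere authoritative; we operate on the PCA-reduced coefficient
  space and say so.
- **Neighbor joining** (Saitou–Nei, rate-corrected criterion Q). Ties in
  Q are broken by the smallest index pair for determinism. Negative
  branch lengths are clamped to zero with the deficit transferred to the
  sibling edge, preserving path lengths through the joined pair; raw
  values are retained on the result object. On tree-additive input the
  output's path metric reproduces the input exactly (property-tested
  over random trees with 4–12 leaves).
- **Sokal–Michener distance**: 1 − simple-matching coefficient over
  markers non-missing in both varieties (pairwise deletion). A metric on
  complete data (property-tested).
- **Mantel test**: Pearson r of strictly-lower-triangle entries;
  permutation p with the label order of the second matrix shuffled,
  seeded. One-tailed "greater" by default, since the working hypothesis
  is positive association between morphometric and genetic distance;
  two-sided available by flag.

## The synthetic-data generator

The generator emulates a varietal collection: four taxonomic categories
(2-row/6-row × hulled/naked), varieties nested in categories, accessions
(variety × year), ~30 grains per accession, two views per grain. Grain
shape lives in normalized coefficient space:

    template(view) + category + sowing + variety + year + grain noise

with all effects Gaussian per coefficient and damped by 1/n per harmonic
(smooth, low-frequency biological variation; flat-spectrum effects of
comparable magnitude produce self-intersecting outlines and are not
grain-like). The templates are fixed coefficient vectors of a pointed
egg with a smoothly flattened furrow side (lateral) and a milder taper
(ventral), shipped as package data.

Deliberate structure:

- the **row-type** effect loads on the ventral view (weight 1.0 vs 0.3
  lateral) and the **hull-type** effect on the lateral view (1.0 vs 0.3
  ventral), mirroring the spike-architecture and husk-adherence biology;
  classification on generated data therefore reproduces the
  ventral-dominant row signal and lateral-dominant hull signal;
- sowing has a small shape offset plus a multiplicative **size** effect:
  spring accessions are 6% larger on all three axes; "alternative"
  varieties sit midway between the spring and winter shape effects (a
  modelling choice; no authoritative description exists);
- per-grain sizes are lognormal (CV 5%) around base dimensions 8.5 ×
  3.4 × 2.8 mm, with one size factor shared by both views — this
  coupling is what makes centroid sizes and length highly correlated;
- grain noise is correlated between the two views of one grain
  (`view_noise_correlation`, default 0.3, variance share). Within-grain
  view covariance of real material is undocumented; this is an explicit
  knob, not an estimate.

Default effect scales (category 1.3·10⁻³, sowing 4.5·10⁻⁴, variety
4.5·10⁻⁴, year 3·10⁻⁴, grain noise 1.8·10⁻³, per normalized coefficient)
were chosen once so that combined-shape LOOCV discriminability on a
study-sized collection sits at the levels reported for real barley
collections (four groups ≈ 77%, row type ≈ 88%, hull type ≈ 87%,
variety ≈ 48%, sowing within category ≈ 70%), and frozen.

Randomness is hierarchical: every accession has its own RNG stream
derived from (seed, variety index, year), so enlarging a collection
never perturbs accessions already generated; global effect vectors come
from a stream derived from the seed alone. Identical config + seed gives
bitwise-identical outlines.

SNP genotypes are binary variety × marker matrices. With
`genetic_morpho_coupling = 0` (the default) each marker is an
independent Bernoulli draw with its own allele frequency ~ U(0.1, 0.9) —
the regime in which morphometric and genetic distances are unrelated and
a Mantel test should stay null. With coupling 1, each marker is a
thresholded random projection of the variety's true mean shape vector,
so genotype clusters follow shape clusters; intermediate coupling mixes
marker types in proportion.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: photographic artefacts and
segmentation error; husk texture and surface ripples; the twisted
lateral grains of 6-row ears as a distinct within-variety mixture;
charring deformation; realistic linkage structure among SNPs; and the
study-specific imbalance of categories over sowing periods (the
generator assigns sowing levels round-robin within every category).

## Problem sizes

Tests and the acceptance script run at desk scale — hundreds to ~2000
grains, 100–200 simulation replicates for calibration checks, B = 99
permutations inside replicated simulations and B = 999 for single tests
— sizes at which every statistical check has adequate resolution while
the full suite completes in a few minutes on one CPU.

## Known limitations

- The mean of per-grain normalized coefficients is a consistent but
  nonlinearly biased estimator of a group's true mean shape at large
  outline-noise levels (bias O(σ²) from the centroid-size division and
  arc-length reparameterization). Parameter-recovery behaviour is
  verified in the near-linear regime.
- Start-point anchoring is undefined for near-circular outlines.
- MANOVA assumes homogeneous within-group covariance; only Pillai's
  trace is exposed.
- The mask tracer assumes one grain per image; multi-grain segmentation
  is out of scope.
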