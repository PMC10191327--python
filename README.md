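# caryomorph

Elliptic Fourier morphometrics of cereal caryopses (grains): from
two-view grain outlines to shape statistics, discriminant classification
of barley categories, dissimilarity networks between varieties, and the
comparison of morphometric with SNP-based genetic distances.

The package is written for quantitative archaeobotanists and crop
scientists who identify barley types — 2-row vs 6-row subspecies, hulled
vs naked types, winter vs spring sowing — from the size and shape of the
grain alone, the only evidence that survives in charred archaeological
material. It implements the full analysis pipeline such studies use and
ships a synthetic-data generator with the hierarchical structure of a
real varietal collection (categories ⊃ varieties ⊃ accessions ⊃ grains,
two correlated views per grain), so that every stage is testable without
access to photograph archives.

## The model

Each grain is photographed in two views: **lateral** (showing its
thickness) and **ventral** (furrow up, showing its width). A closed
outline with *k* points, centred and scaled to centroid size 1, is
expanded in elliptic Fourier harmonics

    x(t) = Σₙ aₙ cos(2πnt) + bₙ sin(2πnt)
    y(t) = Σₙ cₙ cos(2πnt) + dₙ sin(2πnt),      t ∈ [0, 1),

where *t* is normalized arc length. The per-harmonic quadruples
(aₙ, bₙ, cₙ, dₙ) are the shape variables; the harmonic count is chosen
so that the cumulative harmonic power Pₙ = (aₙ²+bₙ²+cₙ²+dₙ²)/2 reaches
99% (defaults: 5 lateral, 7 ventral harmonics). Downstream:

- **size**: length, width (ventral principal-axis extents), thickness
  (lateral minor extent), per-view centroid sizes; Kruskal–Wallis and
  pairwise Wilcoxon rank tests between groups;
- **shape/form**: PCA, one-way MANOVA (Pillai's trace), pairwise
  permutational MANOVA; *form* = shape + log centroid size;
- **classification**: linear discriminant analysis (pooled within-class
  covariance, proportional priors) with leave-one-out cross-validation;
  accuracy is the CVP (cross-validation percentage) with a stratified
  bootstrap confidence interval;
- **networks**: Mahalanobis distances between group mean shapes,
  summarized as neighbor-joining trees (Newick export);
- **genetics**: Sokal–Michener distances on binary SNP genotypes and a
  permutation Mantel test against the morphometric distance matrix;
- **sample size**: rarefaction curves of captured variance per
  accession, justifying ~30 grains per accession.

## A worked example

`examples/04_classification.py` simulates 360 grains (4 categories × 3
varieties × 30 grains) and classifies them by leave-one-out LDA:

```
  contrast    feature_set  cvp  ci_low  ci_high   n
four_group         length 22.5    10.8     26.8 360
four_group  lateral_shape 64.4    64.2     74.5 360
four_group  ventral_shape 68.3    66.2     76.0 360
four_group combined_shape 85.3    85.2     92.0 360
  row_type         length 54.4    48.1     60.3 360
  row_type  lateral_shape 68.1    64.1     73.6 360
  row_type  ventral_shape 91.7    90.0     95.8 360
  row_type combined_shape 93.1    92.2     97.2 360
 hull_type         length 47.5     0.0     57.2 360
 hull_type  lateral_shape 89.4    87.0     94.3 360
 hull_type  ventral_shape 70.6    70.1     79.1 360
 hull_type combined_shape 90.3    88.0     94.4 360
```

Reading it: a single size index barely beats chance (four groups:
22.5% vs 25% chance), while outline shape identifies the category of
most grains. The 2-row/6-row contrast is carried by the **ventral**
view (91.7% vs 68.1% lateral) — spike architecture constrains the
grain's ventral silhouette — whereas the hulled/naked contrast is
carried by the **lateral** view (89.4% vs 70.6%), where husk adherence
rounds the profile. Combining both views matches or beats the better
single view (85.3% for the four-way contrast). The other examples walk
through simulation, mask-to-outline extraction, the Fourier machinery,
mean-shape contrasts, NJ networks and the Mantel test.

A thin CLI mirrors the library (`caryomorph simulate | extract | eft |
run | mantel | report`); `caryomorph run --config cfg.yaml` executes the
whole pipeline from a YAML file and writes a manifest with seeds, row
counts and a config hash for exact reproducibility.

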