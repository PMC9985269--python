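# Methods

This note documents the models behind each pipeline layer, the synthetic
generators' assumptions, the numerical choices, and the places where the
design was genuinely open.

## Community simulator

ASV counts are drawn per sample as
`multinomial(depth, softmax(log b + c·η + e_g))` where `b` is a base
relative-abundance profile drawn once per table from a symmetric
Dirichlet(`base_concentration`), `e_g` is an optional per-group log-fold
effect on chosen taxa, and `η` is a latent-factor field: taxa are assigned
round-robin to `n_latent_factors` factors and

    η_i = sqrt(s) · z_f(i) + sqrt(1 − s) · ε_i ,   z, ε ~ N(0, 1)

so the latent correlation between two taxa on the same factor is exactly
`s = factor_strength`, `s = 0` makes taxa exchangeable given the profile,
and the pairs sharing a factor are recorded as the planted co-occurring
ground truth. `latent_scale` (c = 1.5) sets the overall log-abundance
spread. Depths are log-uniform in `depth_range`; the defaults
(31,814–577,719 reads, 204 taxa, 10 guts per diet × timepoint) mirror the
emulated feeding trial's printed design, while tests and the acceptance
script run scaled-down communities (10–40 taxa, depths 10³–10⁵) to stay
fast. What the generator does **not** emulate: compositional closure
artefacts beyond the multinomial itself, phylogenetic signal in abundances,
over-dispersion beyond the lognormal-factor field, and chimeras/ASV-calling
noise — so passing recovery tests demonstrates the statistics behave as
designed, not that real gut communities satisfy the model.

Trees for Faith's PD are random join orders with exponential branch
increments — topology and lengths are arbitrary but fixed per seed, which is
all a diversity-index oracle needs.

## Community statistics

- **Filtering** keeps taxa whose total count across all samples exceeds 2
  (the boundary total of exactly 2 is removed).
- **Rarefaction** uses `numpy`'s multivariate hypergeometric sampler —
  exact subsampling without replacement — and drops samples below the
  target depth with a warning.
- **Chao1** uses the classic `S + F1²/(2F2)` and switches to the
  bias-corrected `S + F1(F1−1)/2` only when no doubletons exist (avoiding
  the 0-division); Shannon uses the natural log; Fisher's α comes from
  scikit-bio's solver; Faith's PD sums the union of root-to-tip paths of
  observed taxa.
- **The response transform** is `log10(10,000·p + 1)`: base 10 follows the
  Canoco convention the transform originates from.
- **Ordination**: PCA is the SVD of the centred sample × variable matrix;
  RDA projects the centred response onto group means (the indicator-matrix
  hat projection) and eigen-decomposes the fitted values. Percent explained
  is per axis relative to total response variance. The permutation test
  relabels samples at random and compares the constrained sum of squares;
  the `+1`-corrected estimator keeps p strictly positive. 500 permutations
  is the default.
- **The gate test** runs Shapiro–Wilk per group at α = 0.05 (the gate's
  level is not standardised anywhere; 0.05 is the conventional choice) and
  routes to one-way ANOVA when every group passes, otherwise
  Kruskal–Wallis; a constant group routes to Kruskal–Wallis with a warning.
  No multiple-testing correction is applied, deliberately matching the
  raw-p convention of the analysis this mirrors.

## Taxa connectivity

Eligibility is prevalence ≥ ceil(0.3 · n_group) samples **and** group-mean
relative abundance ≥ 10 ppm. Whether the original abundance rule was
per-sample or per-group-mean is ambiguous; group mean is the default and a
per-sample-max variant is available (`abundance_mode`). Association is
Spearman on relative abundances by default — rank-based, hence robust for
zero-inflated compositional data; Pearson is available. P-values are
asymptotic by default; `exact_permutation` enumerates all n! orderings for
n ≤ 7 (exact, no `+1` term) and samples 10,000 permutations above
(`+1`-corrected). Pairs containing a zero-variance taxon are skipped.
No CLR/SparCC-style compositionality correction is applied — a known
limitation, kept so the procedure matches the straightforward
correlation-network convention it reimplements; spurious negative
correlations from closure are therefore possible at low richness.

Edges are exactly the pairs with p ≤ 0.1 (boundary included), signed by the
correlation. Edge classes are computed from the exact diet-set membership
of each unordered pair. The significant-pair summary counts p ≤ 0.05 and
reports the normalized cumulative frequency of −log10 p (reference 1.3010).

## Transcriptome layer

tpm is `1e6 · (c_g/L_g)/Σ(c_h/L_h)`. The built-in gene scorer is a Welch
t-test on `log2(tpm + 1)` with score = −log10 p — a deliberate, transparent
stand-in; externally computed differential tables (e.g. negative-binomial
model output) can be supplied instead wherever a `GeneScoreTable` is
accepted. GSR aggregates by the **mean** gene score per term and resamples
same-size gene sets without replacement (10,000 by default; null
distributions cached per term size). Collapsing **sums** member-gene tpm —
sum preserves the tpm scale used downstream for node colouring; mean is
available. Genes in several terms contribute to each (no double-count
correction, no GO-graph ancestor propagation). Fold changes use pseudocount
1 tpm to guard zero-expression terms; the sign convention is positive = up
in treatment. Bray–Curtis dissimilarities are computed on tpm and compared
across groups with the gate test.

The expression simulator draws lognormal values around per-gene baselines
(log-scale sd 0.5 — moderate enough that a term's collapsed sum is not
dominated by one extreme gene) with per-sample dispersion 0.35, and shifts
genes of affected terms multiplicatively by the planted log2 effect. A gene
shared by several affected terms takes the strongest single effect rather
than the sum, so the per-term ground truth stays exact under annotation
overlap. Columns are not re-closed to 10⁶: closure would dilute every
planted effect by an amount depending on how many terms are affected,
falsifying the recorded truth. With these defaults a +1 log2 effect on 50
terms is recovered at n = 20/group with the correct sign throughout and
magnitude error well under 0.25.

## GO network

Node gate: |log2FC| ≥ 0.5 and GSR p ≤ 0.1 in **at least one** contrast
(boundaries kept). Edge gate: both terms ≥ 10 genes, overlap ≥ half of the
**smaller** term — the symmetric reading of an ambiguous criterion; "half
of either" is available (`share_reference`) — and both endpoints at
|log2FC| ≥ 0.2, p ≤ 0.05 in at least one **common** contrast. FC gates are
absolute-valued for consistency. Exports carry fill/border fold changes
per contrast and round-trip exactly through GraphML.

## Histomorphometry

Interface lengths are marching-squares contours at the 0.5 iso-level.
Binary indicators give contours with a scale-free staircase wiggle that
overestimates smooth boundaries by ~5%, so the indicator is first smoothed
with a Gaussian whose σ = max(1, 0.02·√min(area_a, area_b)) — the window
grows sub-linearly with feature size, which removes the wiggle while the
corner/curvature bias shrinks with resolution, making the estimate converge
to the analytic length (circle fixture: 0.50% error at 128², 0.04% at
512²). Contour segments are attributed to an interface only where adjacent
to the partner region, so a ring's inner and outer boundaries are measured
separately. Absorptive capacity is the tissue–lumen length over the
tissue–exterior length; any serosa label is merged into tissue. Cells are
8-connected components with a 3-px minimum area (suppresses single-pixel
noise; configurable); total tissue area includes cell pixels; distance is
the Euclidean distance transform from the tissue–exterior boundary sampled
at the cell centroid — the centroid is the anchor choice, as "distance of a
cell" is otherwise underspecified. All outputs carry explicit units
(%, cells/mm², µm², µm). An optional ROI mask restricts analysis to
manually selected tissue.

The section generator uses the fold boundary
`r(θ) = lumen_radius + fold_amplitude·sin(n_folds·θ)`; its analytic arc
length (20,001-point trapezoid quadrature) is stored as truth, and cells
are planted with guaranteed separation so counts, sizes (πr²) and
centre distances are exact ground truth. It does not emulate staining
variability, segmentation errors or touching cells — recovered counts being
exact says the measurement arithmetic is right, not that segmentation is
solved.

## Fluorescence counting

Pixels inside the polygon (even-odd rule at pixel centres) above an Otsu or
absolute threshold form 8-connected components; components ≥ min_area
(5 px) are counted. Touching cells are not split — no watershed — matching
manual-count granularity. Otsu is the default for real images; on
sparse-signal synthetic fields (foreground ≪ 1% of pixels) Otsu splits the
noise histogram instead, so reproducibility-critical runs use the absolute
threshold at half the blob amplitude. The generator keeps blob centres
2 radii clear of the ROI boundary so no blob's super-threshold core
straddles it, and enforces 2-radius separation between blobs, bounded at
10,000 placement retries.

## Integration

Per-layer group summaries (genus mean relative abundance, significant-pair
counts, group-mean collapsed GO tpm — the mean of per-sample sums, chosen
where sum-vs-mean was unstated — and group means of 0–1 scaled histology)
are stacked with a (layer, feature) index and min-max scaled per row across
the diet × timepoint columns; constant rows become zeros, absent
layer-group cells stay NaN. Scaling across groups (not individual fish)
matches the per-group heatmap design; the same operation applied to
fish-level columns gives per-fish heatmaps. `run_pipeline` derives one
sub-seed per stage from the global seed (SHA-256 of `seed:stage`, < 2³¹),
so any stage subset reproduces in isolation; the manifest records
parameters and SHA-256 checksums of every output.

## Known limitations

- No compositionality-aware association (documented above) and no
  multiple-testing correction anywhere p-values are thresholded — both are
  faithful to the reimplemented procedure, not statistical recommendations.
- The built-in gene scorer is not a negative-binomial model; import real
  differential tables for count data with biological replicates.
- GO annotations are taken as given (no ancestor closure), so term-level
  results depend on the annotation file's propagation state.
- The histology layer measures masks; it does not segment.
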