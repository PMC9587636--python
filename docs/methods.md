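# Methods

This note documents the statistical model behind the package, the defaults
and why they were chosen, what the synthetic-screen generator does and does
not emulate, and the numerical conventions.

## Profile construction

The unit of analysis is the *normalized frequency-distribution profile*: for
one (plate, replicate, well, feature), the per-object values are reduced to
`n` bin-wise log2 ratios against the neutral controls.

**Plate-wise normalization.** Each object's value is divided by the median
value of all neutral-control objects on the same plate pass. A "plate pass"
is one physical plate in one replicate — each replicate is stained and
imaged separately and carries its own multiplicative bias, so both the
object-level normalization and the control reference (below) are scoped to
(plate, replicate). A screen-wide reference scope is available as an option.
Plate passes without usable control objects (none present, or a zero
median) are excluded and reported, not silently imputed.

**Shared bin axis.** One equal-width axis per feature is computed from the
pooled normalized values of the entire screen, so every well's profile lives
on the same grid: width `L = (upper − lower)/n`, split points
`s_k = lower + L·k`. Bins are half-open `[s_{k−1}, s_k)` with the last bin
closed; ties at a split point go to the upper bin; values outside the limits
are clamped into the edge bins, so no object is dropped. The default number
of bins is 7 — enough support for a quadratic trend with comfortable
residual degrees of freedom once replicates are stacked, and few enough that
ordinary wells (hundreds of objects) populate the bins densely.

**Axis limits.** `compute_bin_axis` defaults to the min and max of the
pooled data. The *pipeline* default, however, is the 0.5th/99.5th
percentiles. Min/max limits hand control of the entire binning grid to the
single most extreme object in the screen; in particular, one plate pass with
a low control median stretches the normalized maximum for every well,
compressing the informative part of each distribution into one or two bins
and destroying regression power. Percentile limits are robust to this,
cost nothing (the outer 0.5% of objects are clamped into the edge bins, not
discarded), and directly serve the axis's stated purpose of avoiding
strong relative differences at the distribution tails. Both percentiles
are configurable; 0/100 restores strict min/max behaviour.

**Histogram, pseudocount, control normalization.** Objects are counted per
bin and a pseudocount of 1 is added to every bin (so every bin of every
well has positive mass and ratios are always defined); relative frequencies
divide by the population size (sum over bins, pseudocounts included). The
reference profile is the bin-wise *median* over the control wells in scope,
and each well's relative frequencies are divided by it bin by bin. On the
default log2 scale, a well distributed exactly like the reference is
identically zero — the null the downstream test is built around. The ratio
scale is kept as an option. Replicates are never pooled before
histogramming.

## Significance testing

Each profile's stacked replicate observations `y` (length `n_bins ×
n_replicates`) are regressed on centered integer bin positions:
`y = β₀ + β₁c + … + β_d c^d`, `c = b − mean(b)`. Centering keeps the
polynomial columns well conditioned; integer positions (rather than
physical bin midpoints) make profiles unit-free and screens comparable.

- **Global test:** ordinary least squares; F-statistic of the full model
  against the intercept-only null with `(d, N − d − 1)` degrees of freedom.
  Zero-variance profiles (e.g. empty wells, pure pseudocounts) are defined
  to have `p = 1`, `R² = 0` and flow through the pipeline.
- **Multiplicity:** Benjamini–Hochberg step-up adjustment applied per
  feature across all profiles of the screen, at FDR level `Q` (default
  0.05).
- **Variable selection:** backward elimination — refit and drop the
  non-intercept term with the largest t-test p-value above `alfa` (default
  0.05) until all remaining terms are significant; the intercept is never
  dropped. The reported R² is the selected model's, against the
  intercept-only null; if everything drops, the model is intercept-only
  with R² = 0.
- **Call:** significant ⇔ `p_adj < Q` and `R² > rsq_threshold` (default
  0.7, the conventional cut for this style of profile regression; the
  value is configurable and all summaries expose the underlying numbers).

Degree defaults to 2 (quadratic). The stacked-replicate fit (one regression
per well across all replicates) is used rather than one fit per replicate:
it uses all observations in a single test, gives the F-test more residual
degrees of freedom, and tolerates missing replicates.

## Clustering, membership vectors, hits

Significant profiles of each feature (replicate means) are partitioned with
k-means (defaults 4/3/2 clusters for Area / Mean Intensity DAPI / Total
Intensity DAPI, 10 seeded initializations, best inertia kept). Cluster
labels are arbitrary in k-means, so they are canonicalized — renumbered by
descending cluster size, ties by centroid norm — making runs reproducible
and comparable. An empty cluster is re-seeded by scikit-learn's standard
mechanism, keeping k fixed.

Per-feature assignments are one-hot encoded and concatenated into a
membership vector (`0001-010-10` = cluster 4 of 4, 2 of 3, 1 of 2), with an
all-zero block for features where the well was not significant. Vectors are
clustered hierarchically (complete linkage, Euclidean metric) and the
dendrogram is cut at height 1.8. With this metric, vectors differing in one
feature block differ in two bit positions (distance √2 ≈ 1.414 < 1.8) and
merge, while vectors differing in two blocks (distance 2 > 1.8) split — the
cut therefore groups wells that agree on all but at most one feature's
cluster. Linkage, metric and cut height are configurable.

A well is a hit when at least `min_features` (default 2) of its features
are significant; requiring two independent features removes essentially all
neutral-control false positives. Gene classes: **strong** = every siRNA of
the gene is a hit and all hit wells share vector and heatmap group;
**medium** = hit siRNAs agree on the group but not the exact vector, *or*
agreement is perfect but some siRNAs are not hits (partial coverage caps
the class at medium; the coverage fraction is always reported); **weak** =
hit siRNAs in different heatmap groups; **none** = no hit siRNA.

## Synthetic screens

The generator emulates a DNA-stain cell-cycle assay read out per nucleus,
at desk scale by default (2 plates × 96 wells × 3 replicates, negative
binomially distributed ~500 nuclei/well; an 8 × 384 × 3 preset exists).

- DNA content `C` is a two-mode mixture (2N and 4N at exactly twice the 2N
  center, log-normal within mode, σ = 0.18); cycling controls put weight
  0.65 on 2N. `Total Intensity DAPI ∝ C`; `Area ∝ C^0.7` with σ = 0.25;
  `Mean Intensity DAPI = Total/Area` with σ = 0.12 — the three features are
  coupled as in a real nucleus, not independent.
- **Instrument model.** Intensities saturate: values are clamped to a
  detector range calibrated at the 0.5/99.5 quantiles of a pilot control
  population, emulating exposure set up so the control population fills the
  dynamic range. Segmentation gates on Area are generous (pilot 0.1/99.9
  quantiles widened by ×0.7/×1.5): they reject debris and clumps, not
  phenotypically swollen or condensed nuclei. Without bounded measurements
  the shared bin axis is governed by the most extreme object in the screen,
  which no real imaging assay permits.
- **Effects.** A G1/S-arrest class swells nuclei (Area ×(1 + 1.8·m) at
  effect magnitude m) and lowers Mean Intensity, but shifts DNA-content
  weight by only 0.1·m — cells arrest before replicating, so the Total
  Intensity profile barely changes, which is exactly the behaviour of an
  early-S blocker. A G2/M-arrest class shifts weight m onto 4N and shrinks
  Area ×(1 − 1.2·m) (condensed mitotic nuclei), brightening Mean and Total.
  Effect genes (default 30%) draw a penetrance from {0.25, 0.45}, shared by
  both of their siRNAs; a configurable fraction of siRNAs is off-target with
  an independent phenotype. Positive-control wells carry the chemical
  arrest classes at magnitude 0.45.
- **Nuisance.** Multiplicative log-normal plate gains per plate pass (10%
  CV on intensities, 5% on area) — exactly the distortion plate-wise median
  normalization corrects — plus 3% per-well replicate jitter.

Everything is reproducible from the seed, and the emitted files are exactly
the formats the reader consumes, plus a ground-truth table.

**What the generator does not emulate** — and hence what passing tests do
not certify about real screens: spatial plate artifacts (edge effects,
gradients), cell-density-dependent phenotypes, segmentation errors
correlated with phenotype, heavy-tailed debris populations, partial
penetrance *within* a well, and transfection-efficiency variation between
replicates. The object count per well (~500) matters: at substantially
lower densities the per-well sampling noise makes borderline R² calls — and
with them twin-siRNA concordance — noticeably less stable.

## Evaluation harnesses

The ROC benchmark scores every well three ways — the regression score
(wells ranked by adjusted p, R² breaking ties), the two-sample KS D, and
the absolute Welch t, the latter two computed on plate-normalized object
values against the pooled control objects of the same plate — against
ground-truth labels. The benchmark screen uses effects that are strong in
the benchmarked feature (G2/M class, magnitude 0.45, for Total Intensity
DAPI), because a G1/S arrest is nearly invisible in that feature by
construction and would measure the assay's biology rather than the scorer.

Replicate reproducibility follows the leave-one-replicate-out design: with
four replicates, four groups R1…R4 each omit one; the pipeline is re-run per
group with all filters off (`alfa = 1`, `Q = 1`, `rsq_threshold = 0`) and
the Pearson correlation matrix of per-well R² values over sample wells is
reported. The harness uses mild replicate noise (5% plate gain CV, 2%
jitter), since the quantity under study is the reproducibility of the
statistic, not the size of the staining variation.

## Numerical conventions and edge cases

- Bin assignment is `floor((x − lower)/L)` clipped to `[0, n−1]`: ties at
  split points go up, the last bin is closed, out-of-range values land in
  edge bins.
- AllDataTable round trips exactly: floats are written with `%.17g` and
  parsed with round-trip precision.
- BH adjustment restores input order and is permutation-equivariant; caps
  at 1.
- `fit_global` raises on fewer than `degree + 2` observations; rank
  deficiency (too few distinct bin positions) is an error rather than a
  silent pseudo-inverse fit.
- k-means requires at least k profiles; the pipeline lowers k (with a
  warning) when a feature has fewer significant profiles, keeping block
  lengths consistent screen-wide.
- A single membership vector forms its own heatmap group without invoking
  the linkage machinery.
- Welch t with two zero-variance samples is defined by the limit (t = 0,
  p = 1 when means agree; p = 0 otherwise).
- All randomness (simulation, k-means initialization) flows from explicit
  seeds; identical configuration and seed give byte-identical artifacts.

## Known limitations

- The polynomial degree (default 2) bounds the profile shapes the test can
  reward with high R²: strongly asymmetric or spiky profiles fit worse than
  smooth U/monotone shapes, so the R² threshold interacts with bin
  geometry. Raising the degree or the bin count is supported but changes
  the meaning of the defaults.
- The medium/weak gene distinction depends on the heatmap cut height; 1.8
  is calibrated to the one-block/two-block geometry of one-hot vectors and
  should be revisited if the number of clusters per feature changes
  substantially.
- Per-feature FDR control does not correct across features; the ≥2-feature
  hit rule is the (deliberately simple) guard against multiplicity across
  features.
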