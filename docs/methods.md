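# Methods

## The gating model

citegate treats cell-population classification in CITE-Seq data as iterative
filtration, the way a flow cytometrist works: plot cells on two surface
markers, draw a boundary (a *gate*), keep the cells inside, and repeat on the
kept cells with a new marker pair until the population of interest remains.
Each filtration event is recorded as an immutable `Gate` — axes, geometry,
input and output barcode sets, counts, value source and timestamp — and
events compose into a `GateChain` whose invariant is barcode passing: gate
*k* draws exactly from gate *k−1*'s output. Cell barcodes, not row indices,
are the primary key throughout, so gates survive container subsetting and
reordering.

Two export forms exist on purpose. The *audit* file (JSON) is the full
provenance record, including every gate's barcode sets and the container
fingerprint. The *scheme* file (YAML) carries only what is needed to redo
the analysis — axes, geometries, labels, and the normalization record — and
is deterministic to the byte, so re-exporting an imported scheme is the
identity. Replaying a scheme on the same container reproduces every output
set exactly; replaying on another container is a first-class operation and
is where the normalization record is checked (mismatch warns, because the
gates still apply — they just may no longer mean what the author intended).

### Membership rules

Gating reduces to one geometric predicate, shared by forward gates and
back-gates:

* rectangles: `x_min ≤ x ≤ x_max` and `y_min ≤ y ≤ y_max`;
* polygons: even-odd ray casting over the implicitly closed vertex list;
* boundary points are **inside** for both geometries (flow-cytometry
  convention; a cell sitting on the drawn line was intentionally included);
* comparisons are exact floating point. Membership is a predicate on
  coordinates, and an epsilon would only move the ambiguity elsewhere.

Self-intersecting polygons are accepted with a warning and interpreted by
the even-odd rule, which matches what lasso selections in plotting tools do.
The signed-area (shoelace) degeneracy check is skipped for self-intersecting
polygons, whose lobes cancel in signed area.

## CLR normalization

Antibody-tag counts are compositional, so gating operates on centered
log-ratio values. For a margin vector x (one cell across features, or one
feature across cells):

* `log1p_centered` (default): `y_i = ln(1 + x_i) − mean_j ln(1 + x_j)`
* `pure_log_ratio`: `y_i = ln(x_i + c) − mean_j ln(x_j + c)`, pseudocount
  c > 0 (default 1)

The default margin is `across_cells` (per-feature centering), the common
practice for antibody panels; `within_cell` gives the textbook
compositional transform. Both are exposed because ADT practice is not
settled, and the choice is recorded in the normalization record that
accompanies every exported scheme. All-zero margin vectors map to zeros by
construction (never NaN). Centering is exact to ~1e-15; the transform is
strictly monotone within a margin vector, so single-marker thresholds are
equivalent on count and CLR scales.

RNA log-normalization (`ln(1 + s·x/total)`) is provided for downstream
convenience; QC metrics never use it.

## Back-gating and the density layer

A back-gate selects cells in embedding space (geometry on the first two
embedding dimensions, a metadata category such as an annotated cluster, or
an explicit barcode list) and projects the selection onto a marker pair,
reporting per-cell values with a highlighted flag and within/outside
medians. Embeddings are inputs — this package never computes dimension
reduction. The density layer under the scatter is a plain 2-D histogram
(default 64×64) over the data bounding box: deterministic, exactly
count-conserving, and cheap. Kernel density was rejected because the layer
is purely visual and a bandwidth would be one more unrecorded parameter.

## QC metrics and group comparison

Per-cell metrics are computed from raw counts and only raw counts: total
RNA counts, genes detected (raw > 0), total ADT counts, antibodies detected
(raw > 0). "Detected = raw count > 0" is the only threshold-free definition
of an antibody being present. Metrics for absent assays are omitted rather
than zero-filled.

Group comparison is one-way fixed-effects ANOVA followed by all-pairs Tukey
HSD. The ANOVA is computed from closed-form sums of squares so the
degenerate cases have defined answers (zero between-group variance → F = 0,
p = 1; zero within-group variance with distinct means → F = ∞, p = 0).
Tukey adjusted p-values come from the studentized-range distribution
(`scipy.stats.studentized_range`) with the pooled within-group degrees of
freedom and the Tukey–Kramer standard error for unequal group sizes. Using
the exact distribution rather than a lookup-table approximation makes the
two-group identity (Tukey padj = ANOVA p) hold to 1e-6, which the test
suite checks, alongside a cross-check against statsmodels'
`pairwise_tukeyhsd` at that implementation's table precision. Groups with
fewer than two cells are dropped with a warning.

Co-expression quadrant tables default their positivity thresholds to the
per-feature upper quartile of the values in use — overridable, because
positivity is a manual-gating judgement, not a statistic.

## The synthetic generator

The generator plants ground truth instead of downloading it. Per cell:
population ~ multinomial; ADT counts negative binomial with population
log-means and dispersion r (variance = μ + μ²/r, sampled gamma–Poisson);
RNA negative binomial over per-gene lognormal mean factors with Bernoulli
dropout; embedding = population center + isotropic Gaussian noise; donor
uniform over 8 donors. One `numpy.random.default_rng(seed)` (PCG64) drives
everything, so containers are bit-reproducible.

The PBMC preset uses a 9-antibody panel (CD3, CD4, CD8, CD11b, CD14, CD16,
CD19, CD56, CD41) and 8 populations: CD4 T (30%, CD3+CD4+), CD8 T (15%,
CD3+CD8+), classical CD14 monocytes (20%, CD14+CD11b+), non-classical CD16
monocytes (5%, CD16+CD11b+), intermediate CD14+CD16+ monocytes (4%), NK
(10%, CD56+CD16+), B (12%, CD19+), platelets (4%, CD41+, RNA-poor at 0.15×
depth; CD41 chosen as the canonical platelet marker). Positive modes sit at
mean 120 counts, negative (ambient) at 2, dispersion 15 — a separation of
well over 3 NB-scale SDs, so each marker's CLR distribution is cleanly
bimodal. Canonical schemes (CD3+/CD4+; CD14+/CD16−; CD19−/CD3+ then
CD8+/CD4−) place every boundary at the midpoint between the two CLR modes,
found by deterministic 1-D two-means on the data itself — no ground-truth
access. Embedding cluster centers sit on a circle of radius 6 with SD 0.5,
far enough apart that a ±3 SD box isolates one population.

### Donor-block scenario

`pbmc_preset(..., donor_shift=s)` with s > 0 zeroes each ADT count of
donors 5–8 with probability s, lowering their detected-antibodies-per-cell —
the synthetic analog of two patient blocks differing in antibody detection.
The default is s = 0: thinning corrupts ADT values, so a nonzero default
would degrade the preset's primary role as a gating benchmark.

The scenario value used by the test suite and the acceptance script is
s = 0.15, calibrated once against the scenario's own requirements: the
between-block difference must be unambiguous (pairwise t ≈ 10, adjusted
p ≈ 0) while keeping the variance distortion of thinning small. Bernoulli
thinning is intrinsically heteroscedastic — thinned donors' detected-count
variance is inflated — and pooled-variance Tukey HSD is mildly
anticonservative for the thinned donors' within-block pairs; at s = 0.15
the distortion is small enough that within-block false flags stay near the
nominal family-wise rate. Under the null (s = 0) the family-wise error rate
of the full 28-pair comparison is ~0.05, which the acceptance suite
verifies by simulation.

## What the generator does and does not emulate

It emulates: bimodal ADT marker logic with ambient background, NB
overdispersion, sparse RNA with dropout, cluster-shaped embeddings, donor
structure in antibody detection. It does not emulate: ambient-antibody
background correlated across cells (dsb's territory), RNA co-expression
structure, doublets, batch effects beyond donor thinning, or embeddings
with neighborhood structure inherited from expression. Passing tests
therefore demonstrate that the gating/back-gating/QC machinery is correct
and recoverable under its stated model — not that any particular real
dataset separates as cleanly.

## Numerical and design choices

* Thresholding (two-means) initializes at the 5th/95th percentiles and is
  deterministic; ties in membership cannot occur off the gate boundary.
* Downsampling and all simulation use explicit seeded generators; nothing
  touches global random state.
* Serialized containers store raw counts sparse and bit-exact; normalized
  matrices as a dense float64 layer (NaN where an assay has none).
* Problem sizes in the test and acceptance suites: the scheme-recovery
  benchmark uses n = 10,000 cells (the demonstration scale); donor-block
  simulations use n = 1,600 (effect, 100 seeds) and n = 1,200 (null, 400
  seeds) with a 20-gene RNA assay, sizes at which the compared group means
  are estimated to ~0.08 antibodies — ample for the planted effect of ~1.1.
* Gates on RNA or other assays are allowed (`value_source="auto"` uses the
  normalized slot when present); ADT gating refuses to fall back to raw
  silently — raw gating must be requested explicitly and is recorded.

## Known limitations

* No HDF5 10x (`.h5`) or loom ingestion; no R RDS/Seurat parsing.
* No boolean gate algebra (AND/OR/NOT of sibling gates) or 1-D interval
  gates; no GatingML import/export.
* `read_container` loads the full matrix into memory; containers far beyond
  the ~10⁵-cell scale have not been profiled.
* Tukey HSD assumes homoscedastic groups; strongly heteroscedastic
  metadata splits (as the donor-thinning analysis above shows) will be
  mildly anticonservative within the high-variance groups.
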