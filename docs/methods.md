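# Methods

This note records the models, parameter choices and numerical conventions
behind `pulmoplex`, and what the synthetic benchmarks do and do not
demonstrate about real imaging data.

## Coordinate and intensity conventions

Physical coordinates are micrometres with the origin at the image's top-left
corner, x along columns and y along rows. Pixels are 0-based and convert
through the pixel size (default 0.51 µm/px, the ×20 acquisition scale common
for this class of instrument); a pixel with index (r, c) is centred at
((c + 0.5)·px, (r + 0.5)·px). Intensities are arbitrary fluorescence units;
nothing downstream assumes a particular bit depth, and readers preserve the
stored dtype.

## Segmentation

Channel preprocessing subtracts the lower 0.01 percentile of the raw values
(a robust dark-offset estimate), clips at zero, rescales to [0, 1], and
computes the two cut points of a three-class multi-Otsu on the result. The
lower cut separates background from signal, the upper cut separates high
signal; the upper cut doubles as the per-channel binarization threshold for
the positivity calls in the cell table, a rule we fix here because mean
intensity alone does not define a call. When a raster has only two distinct
values (synthetic binary fixtures), the cuts are placed at thirds of the
single gap.

Nuclei are detected classically: foreground = normalized DAPI above the
lower Otsu cut; the Euclidean distance transform is smoothed (σ = 1 px) so
its plateaus inside round nuclei do not seed spurious maxima; regional
maxima at least 5 px apart seed a watershed that splits touching nuclei.
No trained model is involved — the fusion logic below, not the detector, is
the step the rest of the pipeline depends on, and a classical detector keeps
the package self-contained and deterministic. Each nucleus is then expanded
by 3 µm with nearest-nucleus assignment (`expand_labels`), a typical
cytoplasmic rim for dense embryonic tissue; the radius is a parameter.

Membrane compartments come from the EPCAM channel: membrane pixels are those
above the lower Otsu cut, enclosed regions are filled, interior chambers
(enclosed minus membrane) are labelled, and a watershed over EPCAM intensity
within the enclosed region grows each chamber out to the ridge crest.
Internal walls therefore split a figure into separate compartments, and a
chamber with no nucleus still becomes a compartment.

Fusion: each expanded nucleus is cut to the compartment containing the
majority of its pure nucleus (ties to the lower compartment label);
compartments without any nucleus are kept as cells as-is; nuclei outside all
compartments keep their expanded shape. Cells are forced to single connected
components (largest piece kept), filtered to areas in [20, 5000] px and — when
the normalized channels are available — to mean DAPI or mean EPCAM above the
lower Otsu cut of the respective channel, then relabelled 1..N. The area
bounds and the intensity floor are parameters; the published description of
this sanity filter names the criteria but not the constants, so the defaults
here are ours. Quantification takes per-cell means of the *original*
(unnormalized) intensities.

On the default benchmark (≈3000 non-touching cells, Gaussian noise with
s.d. 5% of the DAPI signal), matched recall and precision against the true
mask are ≥ 0.95 at IoU ≥ 0.5; the acceptance script recomputes this.

## Table preprocessing

Background is a per-(marker, week) constant subtracted with clipping at
zero, mirroring ROI-measured background tables; the shipped configuration
uses placeholders because those constants are dataset-specific.
Normalization is arcsinh with cofactor 5 (the flow/mass-cytometry
convention; the choice only rescales the axis and is configurable).
Artifact regions are polygon files in µm; a centroid on a polygon boundary
counts as inside (even-odd rule via `shapely.covers`), which makes
grid-aligned synthetic fixtures deterministic. The canonical order is
subtract → exclude → normalize.

## Phenotyping

Clustering is the standard single-cell recipe: PCA to min(20, markers − 1)
components, k-nearest-neighbour graph (k = 10, Euclidean in PC space,
symmetrized), Leiden at resolution 1 with a fixed seed
(`RBConfigurationVertexPartition`). Determinism comes from the seed; note
that Leiden cannot merge disconnected graph components, so the
"resolution → 0 gives one cluster" limit holds only on connected graphs.

Annotation reads clusters the way one reads a dot plot: cluster means are
z-scored per marker *across clusters*, and an ordered rulebook assigns the
first label whose "high" markers all satisfy z ≥ 0.25 **and** lie above the
two-class Otsu split of that marker's cluster means ("low" is the mirror
image). The Otsu term makes the call robust when many clusters share a
profile and the z-scores flatten; the z term protects against markers whose
cluster means are nearly constant. Unmatched clusters are `unassigned` and
reported with their top-3 markers. Analyses are per developmental week;
merged-week clustering is deliberately not provided — per-week annotation is
the more accurate route for data of this kind, and the cross-week statistics
below are designed around it.

Rare immune types (B, NK) enter through conjunctive gates (default: both
markers above their 90th percentile), and gate labels take precedence over
subcluster labels.

## Neighborhood enrichment

The spatial graph joins cells whose centroids are within 50 µm — physical
micrometres, since the vasculature analysis states its radius in µm; if a
pixel-unit reading of the radius were intended instead, the radius parameter
absorbs it. Enrichment counts each unordered neighbouring label pair once
(the homotypic diagonal counts pairs, not cells) and compares to a null of
1000 label permutations over the fixed graph:
Z = (obs − μ_perm)/σ_perm. Pairs with a degenerate permutation distribution
(σ = 0, e.g. a single label) get Z = 0 plus a flag rather than an infinity.
Cross-week comparison scales each week's Z matrix column-wise (mean 0,
sample s.d. 1), then subsets to the common labels — scaling before
subsetting, so the scaling context is the full week. On a 2000-cell field
with uniformly random labels, max |Z| stays ≤ 4 in ≥ 95% of seeds, the
calibration the acceptance script verifies.

## Spatial domains

Domain features mix a cell's own expression with its neighbourhood mean:
`[√(1−λ)·x_i , √λ·mean_{j∈N(i)} x_j]`, λ = 0.8, neighbours from a spatial
k-NN (k = 18) or the 50 µm graph; isolated cells fall back to their own
expression and are flagged. Only the mean block is used — no gradient /
azimuthal terms — because the mean carries the domain signal in this regime;
this is a documented simplification of the full published family of
neighbourhood-augmented clustering methods.

For clustering, features are standardized: markers are z-scored before
augmentation and each block is rescaled to unit total variance before the
√-weights, so λ is the fraction of total feature variance contributed by the
neighbourhood (the variance-partitioning reading of the mixing parameter).
Without this, the own-expression block numerically dominates and clustering
returns cell types regardless of λ. Leiden on the augmented space then
typically refines true domains into (domain × dominant-type) pieces;
mirroring the practice of annotating domains by cellular composition, the
pieces are merged automatically: ward linkage over the cluster centroids of
the neighbourhood block, cut at the largest ratio gap between successive
merge heights. The merge is skipped at λ = 0, so domain clustering at λ = 0
is *exactly* the phenotyping clustering at the same parameters and seed. On
the planted three-domain benchmark (shared cell types, different
proportions, n = 10⁴) this recovers the domains with ARI ≈ 0.94 versus
≈ 0.4 at λ = 0.

## Proliferation

A cell is proliferating iff its background-subtracted Ki67 exceeds the
week's percentile of the analysed (post-exclusion) week population — 70th at
weeks 6 and 8.5, 85th at 11 and 12, 86th at 13 — with linear interpolation
between order statistics and a strict inequality (an all-equal column yields
no positives). By construction the called fraction equals (100 − p)% on
tie-free data; a reported 36% at a 70th-percentile week is therefore only
attainable if the percentile was taken over a larger population than the
analysed one, an ambiguity we resolve in favour of the analysed population.
Homotypic-adjacency contrasts between proliferating and non-proliferating
cells of a type use the diagonal scaled-Z values across weeks and an
equal-variance two-sided Student t (the default of the t routine named in
this literature); the per-week ratio non-proliferating/proliferating guards
near-zero denominators with NaN. Region comparisons (small SOX2 / large
SOX2 / SOX9 airway groups) use the two-sided Fisher's exact test with the
point-probability convention (sum over tables with fixed margins whose
probability does not exceed the observed); the implementation delegates to
`scipy.stats.fisher_exact`, which the test suite verifies against exact
integer-arithmetic enumeration over all tables with total ≤ 30 to 1e-12.

## Vasculature

Instance route: neighbourhood composition of artery-close immune cells in
5 µm bins to 50 µm (focal cells excluded from their own neighbourhoods),
size-matched random controls (artery-distant immune, or any type), and
per-marker differential expression with a two-sided Wilcoxon rank-sum test —
tie-corrected normal approximation without continuity correction, the
convention of the single-cell toolkit this mirrors — and Benjamini–Hochberg
adjustment; significant ⇔ adjusted p < 0.05 and |log2FC| > 1 with
log2FC = log2((mean_A + ε)/(mean_B + ε)), ε = 1e-9 guarding zero means.

Semantic route, in order: CD45 rolling-ball background subtraction
(implemented as grayscale opening with a radius-50 px disk,
sequence-decomposed for speed — the functional equivalent of the named
filter); Gaussian blur σ = 4 px (ACTA2, CD144) / 2 px (CD45); Triangle
threshold per channel (256-bin histogram); artery core = ACTA2 ∧ CD144 with
connected components < 2000 px removed; optional add/remove correction masks
replacing the interactive validation of the original workflow; expansion =
union of ACTA2 components overlapping the core by ≥ 1 px; proximity zone =
maximum filter with an 80 px disk, computed exactly as a Euclidean-disk
dilation via the distance transform (the two are identical on binary input,
and the test suite asserts the identity); artery-close/-distant immune
regions = CD45 mask split by the zone; per-channel mean and median contrasts
ordered by mean difference. The 80 px (≈40 µm) semantic zone and the 50 µm
instance radius are different constants for "artery-close"; both are
exposed, neither harmonized.

## The synthetic generator

The generator is the package's test bed and defines its study conditions.
Cells are non-overlapping disks (nucleus + 3 µm cytoplasmic rim) placed by
grid-hashed rejection sampling with a minimum spacing; structure cells
(airway rings, SOX9 tip disks, vessel rings) are laid out on exact
geometry and registered, so geometric tags (artery-close, airway rings) can
be recomputed independently from the registry. Marker intensities are
log-normal per (type, marker) with a mean-preserving parameterization
(dispersion 0 returns the mean exactly) plus per-channel constant
background; Ki67 is continuous and bimodal (baseline mean 5, proliferating
mean 80). Cell-type fractions follow the composition reported for this
tissue (mesenchymal 33.9%, endothelial 24.6%, SOX2-high epithelial 13.1%,
SOX9-high epithelial 9.7%, airway smooth muscle 9.2%, immune 4.8%,
lymphatic endothelial 2.1%, neuronal 1.1%, vascular smooth muscle 0.8%,
chondroblasts 0.7%), and the per-type proliferation rates follow the
reported week-resolved extremes (73% SOX9-high vs 15% airway smooth muscle
at week 6; overall 14% at week 13), with the week-6 mixture chosen so the
composition-weighted overall rate matches the 70th-percentile threshold.
Artery-close immune cells have their CD90/HLA-DR draws multiplied by 2.5
and CD163/MRC1 by 0.35, a strong but realistic planted contrast.

Problem sizes used by the default benchmarks — 10⁴ cells for composition
and domain scenes, ≈3000 cells for the segmentation image, 2000 cells for
the permutation-null calibration — were chosen as the smallest fields on
which the statistics of interest are stable.

What the generator does *not* emulate: optics (no PSF, no chromatic or
illumination fields), autofluorescence spectra, 3D structure, segmentation
errors correlated with cell density, batch effects between weeks, or the
continuum of intermediate cell states in real tissue. Passing the
benchmarks therefore shows the *algorithms* are implemented correctly and
recover planted structure under realistic noise; it does not certify
performance on any particular real acquisition.

## Known limitations

* The nuclei detector is classical; heavily overlapping nuclei that a
  trained model would separate will be merged or split imperfectly.
* The "incorrect nucleus" branch of mask fusion is not implemented — only
  compartments with *no* nucleus become cells on their own — because no
  operational criterion for "incorrect" exists; artifact clusters can
  instead be excluded by id after the first clustering round.
* The domain-merge heuristic (largest ratio gap in ward merge heights) is
  parameter-free but can under- or over-merge when true domains form a
  similarity continuum.
* Annotation rules operate on cluster means; types that only differ in
  co-expression patterns within a cluster need gates instead.
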