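# Methods

This note documents the models, conventions and numerical choices behind
`cementum`. The package characterizes hypercementosis — cementum apposition
beyond its physiological extent — on single-rooted human teeth, from three
kinds of input: micro-CT-derived surface meshes (a dentine core and its
cementum envelope), confocal-profilometry height maps of the root surface,
and per-tooth visual score records. Its reference dataset is a table of 35
hypercementotic teeth from 23 medieval-to-early-modern individuals
(Sains-en-Gohelle, France), shipped as a machine-readable fixture.

## Anatomical frame and partition

Every root carries an apex landmark, a cemento-enamel-junction (CEJ) height,
a unit axis (apex → cervix) and a buccal reference direction. Root *thirds*
are equal axial-length intervals between apex and CEJ, numbered 1 (apical),
2 (middle), 3 (cervical); for crownless roots the preserved length is used.
*Sides* are the four 90° angular quadrants about the axis centered on the
anatomical directions, coded as in the dental literature: `<` buccal, `>`
lingual, `m` mesial, `d` distal. The partition rule (equal axial thirds) is
a package convention: the source scoring practice identifies thirds visually
and never states a geometric rule.

## Thickness mapping

Cementum thickness at each cementum-envelope vertex is the unsigned
Euclidean distance to the nearest point of the dentine surface — true
point-to-triangle distance, not vertex-to-vertex. For nested surfaces this
matches a directional inner-to-outer pointwise distance. The implementation
computes exact barycentric-region closest points over candidate triangles
selected by a KD-tree on triangle centroids; pruning is provably safe (a
radius re-check covers every triangle whose centroid lies within
best-distance + the mesh's largest centroid-to-vertex reach). Intersecting
or touching inputs yield zero thickness and a warning, never a failure.

Summaries follow the field's vocabulary:

* **MAX THI** — maximal thickness (µm).
* **LOC MAX** — the (third, side) cell of the maximal vertex, plus any cell
  whose mean reaches 85% (configurable) of the best cell mean.
* **PREF** — apposition is *preferential* when, within some third, the ratio
  of the thickest to the thinnest side exceeds `pref_ratio` (default 1.5).
  Two choices matter here. First, the ratio is evaluated per third: an
  apically concentrated lingual gradient — the hyperfunctional archetype —
  is diluted below any sensible threshold when side means are pooled over
  the whole root. Second, sides are compared on *medians*, not means, so a
  single focal node does not fake a preferential distribution; the criterion
  concerns the apposition as a whole. The 1.5 default was chosen so that
  rotationally uniform synthetic roots with surface texture up to 200 µm
  score non-preferential while gradients of 600–800 µm score preferential.
* **LOC MIN** — the side with the lowest median thickness, reported only
  when the same inhomogeneity ratio reaches `min_ratio` (default 1.5),
  otherwise "No".

## Atypical apposition shapes

Five shape classes describe focal cementum masses: node (NOD, single, > 2 mm),
nodules (Nds, clustered, each < 2 mm, roughly hemispherical), atypical
overgrowth (OG, bulky, > 3 mm, covering ≥ 2 sides), ridges (RID, ≥ 3
elongated oblique crests, each width < 1 mm, length > 2 mm, height > 0.5 mm)
and localized spike-like projection (LSP, < 2 mm, spiky).

Detection separates focal masses from the smooth background apposition by a
robust parametric fit: the background is modeled as angular harmonics up to
order 2 (which represent a one-sided gradient exactly) times a cubic axial
polynomial, fit by iteratively reweighted least squares with positive
outliers (the shapes themselves) excluded. Vertices whose residual exceeds
`prominence_um` (default 300 µm) form seed components on the mesh graph;
each component is then grown to its half-maximum contour so measured extents
approximate the footprint rather than the slice cut at the threshold.
Plain smoothing cannot play the background role here: a root-scale gradient
and a 4 mm overgrowth live at overlapping spatial scales.

Components are measured in unrolled surface coordinates (axial position,
arc length at the local base radius): largest extent ("diameter"), extent
across the principal axis ("width"), elongation, obliquity to the root axis,
sides spanned (≥ 15% vertex share), and a spike score (the maximal positive
deviation from a graph-smoothed copy of the field — narrow spikes survive
neighborhood averaging, broad domes do not; LSP threshold 75 µm).
Rules apply in order: OG (≥ 2 sides, > 3 mm, elongation < 2.5), RID, Nds,
NOD, LSP, none.

## Composite hypercementosis score

The `type.stage.form` triple is derived from the thickness map: stage is the
longest apically anchored contiguous run of thirds whose mean exceeds
`baseline_um` (default 500 µm), or 4 when the CEJ is absent and the whole
preserved root is affected; type is 1 (diffuse) or 3 (mixed) depending on
whether a focal shape component is present — type 2 (purely focal) exists in
the source scoring system but is never produced by this derivation; form is
M (marked) when MAX THI reaches `marked_um` (default 1500 µm). The source
system's exact thresholds are unpublished; both defaults are config keys and
were chosen to reproduce the study table's printed scores on synthetic
analogs.

## Confocal topography

Height maps are regular elevation grids in µm at 0.65 µm/pixel with an
optional non-measured (NM) mask. Processing is fixed as: NM fill (linear
interpolation from valid neighbors, exact on planes; nearest-neighbor
outside the convex hull) → least-squares plane leveling → optional crop →
least-squares bivariate degree-2 form removal (the curvature of the
underlying root). Form removal is idempotent and annihilates degree-≤2
inputs exactly, so the whole chain is invariant to any degree-≤2
contamination of the input.

**MAX VE** is the peak-to-valley amplitude max(z) − min(z) of the
form-removed surface; the published elevation cut (≥ 200 µm ⇒ `+`) is
applied to it. Whether the source's "amplitude" is peak-to-valley or a
percentile-based robust range is unstated; peak-to-valley is used.

The texture (S/R) and relief-frequency (1/2) scores are qualitative visual
judgments in the source guidelines; quantitative proxies stand in:

* **S/R** — RMS of a Gaussian high-pass residual against `rough_rms_um`
  (default 5 µm). The cutoff (default 4 µm) sits at instrument scale, a few
  pixels. This is deliberate: tall-but-smooth relief is common on cementum
  (nodular mounds of several hundred µm), and at any cutoff much above the
  pixel scale its leakage alone exceeds 5 µm RMS whenever MAX VE ≥ 200 µm —
  the Gaussian transfer function makes a 50 µm-scale cutoff mathematically
  unable to call any high-relief surface smooth. Roughness here therefore
  means grain-scale jaggedness, not steep relief.
* **1/2** — density of prominent local maxima of a 12 µm-smoothed copy of
  the surface: a maximum within a 35 µm-radius neighborhood, rising above
  the median by ≥ 25% of the smoothed amplitude, with an 8% border trim
  (polynomial form removal lifts corners). More than 0.5 peaks per
  100 µm × 100 µm scores 1 (frequent).

All thresholds are configuration keys; the defaults were calibrated once on
the synthetic archetypes below.

## Synthetic data

The generator stands in for the study's raw scans and defines the conditions
under which the pipeline is validated.

**Roots.** Tapered superellipse tubes (exponent 2.5) capped by a
hemispherical apex and a rim-to-center cervical cap with bounded triangle
size; defaults: length 12 mm, base radius 2.2 mm, taper 0.35 — the scale of
premolar/canine roots. The cementum envelope displaces each dentine vertex
outward along its normal by an analytic field: base thickness (default
500 µm, the order of a marked physiological layer) + an angular × axial
gradient (cos²-shaped around a direction, Gaussian along the axis, default
amplitudes 600–800 µm for preferential archetypes) + shape primitives with
exact peak heights + correlated per-vertex texture (default 100 µm
peak-to-valley). The truth field equals the displacement, so recovery is
measured against an analytic ground truth. Displacements approaching the
tube radius raise an error (fold-over risk at the apex).

**Height maps.** Degree-2 form + smooth-edged relief mounds (sparse broad
domes for low-frequency surfaces, dense small mounds for high-frequency
ones) + correlated Gaussian noise; the relief is scaled so the detrended
relief+noise peak-to-valley matches the requested amplitude, with the noise
share measured, not assumed. Eight archetype parameter sets span the
(+/−, S/R, 1/2) octants: amplitudes 430 µm / 150 µm; noise 1.2 µm RMS at
30 µm correlation (smooth) versus 16 µm or 8 µm RMS at 2 µm correlation
(rough); mound densities 110 /mm² versus 18 /mm². On the default 512×512
grid the scored aspect matched the archetype label in 199 of 200 draws.

**What the generator does not emulate.** Real micro-CT surfaces carry
segmentation noise, resorption lacunae, and partial-volume artifacts;
real confocal maps have anisotropic instrument noise, outlier spikes, and
NM regions correlated with slope. Roots are idealized tubes without apical
foramina, curvature, or two-rooted anomalies. Passing recovery tests
therefore demonstrates correctness of the geometry and scoring logic under
controlled conditions, not robustness to every artifact of real scans.

## Etiology classification

Five groups: IMP (impacted), INF (infected), HYPO (hypofunctional), HYPER
(hyperfunctional), MIX (mixed condition).

**Published tree.** A fixed seven-leaf tree: preferential apposition at the
root; on the preferential branch the antagonist code (ANT = 1 versus
0/2/3), then MAX THI at 1295 µm, then wear degree ≤ 2; on the
non-preferential branch wear degree ≤ 1 (INF), then MAX VE at 190 µm
(HYPO below, MIX above). The wear cut-points encode "0, 1 or 2" and
"0 or 1" as inclusive integer comparisons. A missing MAX VE on the worn
non-preferential path yields an explicit unroutable result rather than an
imputation. On the 33-tooth study sample the tree reproduces six pure
leaves of seven and exactly one misclassification (a mixed-condition
premolar labeled hyperfunctional).

**Criteria rule set.** One decisive-criteria list per group (preferential
status, antagonist, wear, caries/pulp, stage, the 1295/190 µm cuts). A
unique full match wins; multiple full matches — or two or more half
matches — return MIX, because the mixed condition is defined by overlapping
profiles rather than criteria of its own; anything else is indeterminate.
Partial match scores are always returned for inspection.

**CART.** A from-scratch greedy learner maximizing Gini-impurity decrease:
numeric splits at midpoints between sorted distinct values, categorical
splits over exhaustive level subsets (≤ 8 levels, mirrored duplicates
skipped), stopping at purity, `min_leaf` (default 2) or `max_depth`
(default 5); no cost-complexity pruning — the published tree is treated as
a final structure, and refits on new data may legitimately differ from it.
Ties break toward the first column and the lowest threshold, so fits are
deterministic.

## FAMD

Factor Analysis of Mixed Data embeds continuous and categorical variables
jointly: continuous columns standardized to unit variance (population
denominator), each categorical level's indicator divided by √(level
proportion) and centered, followed by an SVD of the combined matrix divided
by √n. Eigenvalues sum to the total inertia p_cont + Σ(levels − 1); the
all-continuous limit is standardized PCA and the all-categorical limit is
multiple correspondence analysis (FAMD eigenvalues = Q × MCA eigenvalues
for Q variables). Row coordinates are ZV; column coordinates are loadings
scaled by singular values (correlations for continuous variables).

Variables with no or almost no variability (fewer than two observed levels,
or a level carried by exactly one record) are dropped before analysis.
Missing cells are filled by unregularized iterative FAMD: initialize at
mean/mode, refit, reconstruct at rank `n_components` (default 2), rewrite
the missing cells, repeat to stationarity (tolerance 1e-8, cap 500 sweeps
with a warning). Regularization is omitted for determinism; with the
fixture's near-complete table the iteration converges in a handful of
sweeps. Convex-hull group overlays on chosen axis pairs are display-only,
as are the cos² display cutoffs.

The study's printed axis percentages depend on an exact variable subset and
encoding that are not published; the package therefore validates the
decomposition against its algebraic identities and limiting cases, not
against those percentages. Ordinal wear scores can be passed either as
categorical levels or as numeric columns via the variable-role argument.

## Problem sizes

Validation runs use: synthetic roots at 64 × 80 surface resolution
(~5,400 vertices) with 50 recovery replicates; concentric icospheres at
2,562 vertices for the geometric benchmark; 512×512 height maps with 25
seeded draws per archetype. These sizes keep the full validation suite in
the minutes range while leaving every recovery margin wide.

## Known limitations

* The composite-score thresholds (500/1500 µm) reconstruct an unpublished
  scoring system parameterically; absolute stages on real teeth depend on
  those defaults.
* Shape classification assumes a roughly tubular root; the unrolled-surface
  measurements degrade on strongly curved or two-rooted forms (the study
  itself excluded two such teeth).
* The S/R and 1/2 proxies are calibrated on the synthetic archetypes; on
  real confocal data the thresholds may need re-calibration against a
  trained observer.
* `fit_cart` handles complete tables only; impute or drop missing cells
  first.
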