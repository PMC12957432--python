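# Methods

## The quantification model

The pipeline operates on the post-cell-detection representation of a
multiplex-immunohistochemistry section: a table of cell centroids with one
intensity per marker. Everything upstream — staining, scanning, spectral
unmixing, nuclear detection — is out of scope; everything downstream of
the cell table is implemented and tested here.

**Gating.** A cell is positive for a marker iff its intensity ≥ the
donor's threshold for that marker. The closed comparison is a convention
(either choice is defensible; exact tests need one fixed rule). Composite
phenotypes are pure conjunctions; the pMSC gate is
CD73⁺CD90⁺CD105⁺CD31⁻CD34⁻CD45⁻, and the reduced 3-plex gate
CD90⁺CD105⁺CD31⁻ is a strict relaxation, so 3-plex counts are provably ≥
6-plex counts on any input. Thresholds are per-donor configuration, never
learned. Upstream platforms may score cytoplasmic and nuclear compartments
separately and it is not documented which compartment drives positivity per
marker; this implementation collapses to one intensity per marker and, if a
second-compartment column is supplied, gates the two with OR.

**Islet annotation.** Hormone-positive cells are clustered with DBSCAN
(neighbour distance `cluster_radius`, minimum `cluster_min_cells`); each
cluster is closed into a polygon (buffer by `cluster_radius`, union, erode
by `cluster_radius/2`) and polygons under `min_islet_area` = 170 µm² (one
cell-equivalent) are discarded. This replaces the pixel-classifier islet
detection of commercial platforms with a defined, testable procedure on the
cell-table representation; externally produced annotations can be ingested
from GeoJSON instead, bypassing segmentation entirely. Survivors get
sequential ids in (min-y, min-x) bounding-box order.

**Periphery bands.** The band of islet *i* is the set of points outside
every islet, within `expansion_distance` = 10 µm of islet *i*'s boundary,
and strictly nearer islet *i* than any other islet — the result of growing
all annotations simultaneously until they meet. Distance is Euclidean
point-to-boundary distance (whether pixel dilation in imaging platforms is
exactly Euclidean is unstated; the raster oracle below mimics simultaneous
dilation and the agreement of the two constructions is itself a test).
Implementation: each islet's 10 µm buffer ring is clipped by the region
provably nearer each competing islet, built as the union of
`buffer_j(t) − buffer_i(t)` over a 100-step ladder of distances t. This
locates the bisector to within 0.1 µm; the unclassified strip between the
two one-sided constructions — and any exactly equidistant point — goes to
the lower islet id, a measure-zero tie rule needed only for determinism.
Bands are exactly pairwise disjoint by sequential subtraction. Bands are
not clipped to a tissue mask by default (synthetic sections are entirely
tissue); a clip polygon can be supplied.

**Region assignment.** Each cell gets exactly one label: intraislet if it
is inside or on the boundary of an islet (matching the "expanded islet
minus islet" subtraction semantics), else periphery if inside a band, else
exocrine; islets and bands are scanned in ascending id order, so residual
boundary ties also resolve to the lower id.

**Per-islet metrics.** Composition uses the ≥1-positive-cell rule per
hormone on intraislet cells ((0, 0) is an error — islets are defined by
endocrine staining). Size bin = floor(log2(area / 170 µm²)). Densities
divide integer counts by the islet polygon area (intraislet) or the
collision-limited band area (periphery) — not the unconstrained ring — with
the µm²→mm² factor 1e6. An islet is inflamed iff intraislet + periphery
CD45⁺ cells exceed 5; it has an associated pMSC iff that pooled pMSC count
is ≥ 1.

**Statistics.** Descriptives use sample SD and SEM = SD/√n. t tests are
unpaired, two-sided, pooled-variance (Student) — chosen because the
degrees of freedom this convention implies (nA+nB−2) are the ones
consistent with the study-scale group sizes — with t = 0, p = 1 for two
identical constant groups and an error for zero variance with unequal
means. One-way ANOVA reports F with (k−1, N−k) df; post hoc families are
declared per analysis (not hard-coded) and Bonferroni-adjusted with
m = comparisons performed, adjusted p = min(1, m·p). Two-way ANOVA fits
the factorial OLS model with marginal (Type II) sums of squares, which
equal the sequential decomposition for balanced designs — islet-level
designs are heavily unbalanced and the convention of point-and-click
packages is not documented, so the choice is made explicit and tested on
the balanced identity. Size-bin categories with <5 islets in any group are
excluded from binned analyses for all groups. 2^−ΔΔCt normalises the
target Ct against the arithmetic mean of the four reference-gene Cts
(equal to geometric-mean normalisation in linear space) and references the
control condition's mean ΔCt. Both islet-level and donor-level summaries
are supported and labelled; cohort-level percentages are reported both as
pooled cell fractions and as unweighted donor means, since a published
cohort figure can be either statistic.

## The synthetic section generator

The generator emulates what the analysis assumes about real sections:

* **Islets**: lognormal radii (median 40 µm ≈ 5,000 µm², log-SD 0.35, so
  size bins span ~2–7), outlines are circles with 2nd–4th-order sinusoidal
  radial perturbation capped at 20% of the radius — simple,
  area-controllable and convex-ish like real islets. Placement is
  rejection sampling with non-overlap, capped at 10,000 attempts with an
  explicit failure naming the constraint.
* **Endocrine cells**: uniform inside islets at 1/170 µm⁻²
  (5,882 cells/mm²); each islet's composition category is drawn from
  `composition_props`, and the category's required hormone(s) are
  guaranteed ≥1 cell while the forbidden hormone has exactly zero.
* **pMSCs**: a piecewise-constant Poisson process — 14 cells/mm² over
  exocrine tissue (the study-scale whole-pancreas density), ×
  `periphery_enrichment` within 10 µm of insulin-containing islets, and a
  separate intraislet rate. The enrichment multiplier is a phenomenological
  stand-in for chemokine-gradient homing, not a mechanism claim.
* **Sub-phenotypes**: pMSCs are independently ANXA1⁺ with probability
  0.332 and IDO1⁺ with probability 0.01.
* **Inflammation**: each insulin-containing islet is infiltrated with
  probability `inflamed_fraction`; infiltrates are Poisson-distributed
  CD45⁺ cells placed uniformly in the islet plus its 10 µm ring.
* **Confounders**: CD31⁺CD34⁺ endothelial (50/mm²), CD45⁺ haematopoietic
  (60/mm²) and CD90⁺CD105⁺-only fibroblast-like cells (109/mm², sized so
  that the default section reproduces the ~123 vs ~14 cells/mm² 3-plex vs
  6-plex overcount scenario) scattered uniformly.
* **Intensities**: per marker, lognormal positive and negative components
  (log-means ln 100 and 0, log-SD 0.4); the default thresholds at the
  geometric midpoint (10) mis-call a marker with probability ~4e-9, so
  gating recovers ≥99% of true labels — and tests can shrink the
  separation to create hard gating cases.

One seeded NumPy generator drives the section and sub-processes draw in a
fixed documented order, so identical config + seed is bit-identical.

What the generator does **not** emulate: cell shapes and segmentation
errors, intensity spatial autocorrelation and bleed-through, tissue masks
(ducts, vessels, glass), donor-to-donor threshold drift, and serial-section
registration error. Passing tests therefore demonstrate the correctness of
the quantification given a cell table, not robustness to upstream imaging
artefacts.

## Donor-group presets

`reference_config` provides four presets (<13y / ≥13y at diagnosis × type 1
diabetes / no diabetes). Composition proportions are the cohort group means
(e.g. ≥13y T1D ∝ 7.15 / 22.93 / 69.92%), inflamed fractions 0.536 (<13y
T1D), 0.136 (≥13y T1D), ~0 otherwise, and infiltrate means 27.48 / 15.84
CD45⁺ cells per inflamed islet. Periphery enrichment (1.5 / 2.5 / 4 / 8 for
<13y ND / ≥13y ND / <13y T1D / ≥13y T1D) and intraislet pMSC densities are
phenomenological: the source observations are qualitative orderings
(diabetes > age-matched no-diabetes; later onset > earlier onset; loss at
insulin-deficient islets), so the presets fix magnitudes once that
reproduce those orderings, and tests assert the orderings, not the
magnitudes.

## Validation experiment design

Parameter-recovery and preset experiments quantify against the generator's
ground-truth polygons via the annotation-ingestion path. Cluster-based
segmentation places the islet boundary near the outermost detected cell
plus `cluster_radius/2` — an outward offset of a few µm that would dilute a
10 µm band with baseline-rate area and bias any band-density estimate
downward by design, independent of the quantification being tested.
Segmentation accuracy is assessed separately (≥95% of truth islets matched
one-to-one with centroid error <10 µm, pooled over 10 sections).

The enrichment-recovery experiment uses 10 seeds × 50 islets pooled into
one 500-islet estimate per enrichment value, with the exocrine pMSC density
raised to 400 cells/mm² for that experiment only: a pre-hoc power
calculation shows the study-scale 14 cells/mm² leaves ~35 band counts at
enrichment 2 (Poisson SE ~17%), far too noisy for a 10% recovery check,
while 400/mm² yields ~1,000 counts (SE ~3%).

Type-I-error calibration estimates the rejection rate over 5,000 null
simulations and checks it against the binomial band for 1,000 draws
([0.036, 0.064]); at 5,000 reps the band is ~4.5 SE wide, so the check is
stable for a calibrated test yet still fails a mis-calibrated one.

## Numerical choices and limitations

* Polygon overlap tolerance 1e-6 µm²; circles approximated with ≥64
  segments; the single-circle band area matches the 500π annulus to ~4e-5
  relative (polygon approximation, not method error).
* The raster oracle samples cell centres on a grid of pitch
  `raster_resolution` (≤ expansion_distance/10) over the union of expanded
  islet bounding boxes; boundary distance uses the outline densified at
  the grid pitch (including interior rings, so islets with holes are
  handled), and disjointness is structural.
* Segmentation is the weakest stage by construction: very close islets
  (< cluster radius apart) merge, and islets whose endocrine sampling
  leaves gaps larger than the cluster radius split; the 30 µm default is
  ~4.5× the mean endocrine nearest-neighbour spacing at the default
  density. Size bins computed from segmented polygons inherit the
  closing's ~`cluster_radius/2` dilation.
* Degenerate inputs have defined behaviour: empty endocrine tables give an
  empty islet list; (0, 0) hormone counts, zero-area denominators with
  nonzero counts, zero variance with unequal means, empty factorial cells
  and missing reference Cts all raise named errors rather than propagate
  NaNs.
* No mixed-effects modelling of islets nested within donors, no 3-D or
  across-section islet matching, and no whole-slide image formats.
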