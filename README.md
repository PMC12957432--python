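# isletquant

Per-islet spatial phenotyping of pancreatic mesenchymal stromal cells
(pMSCs) from multiplex-immunohistochemistry cell tables.

In type 1 diabetes, stromal cells with islet-protective properties
accumulate around islets that still contain beta cells. Quantifying that
association from whole-slide multiplex imaging requires several
non-standard steps that this package implements as a tested, reusable
pipeline for histopathology groups working with detected-cell exports
(HALO/QuPath-style tables):

* **Phenotype gating** — per-donor intensity thresholds turn marker
  intensities into boolean calls; a pMSC is
  CD73⁺ CD90⁺ CD105⁺ CD31⁻ CD34⁻ CD45⁻ (the full 6-plex definition), and
  the reduced 3-plex gate (CD90⁺ CD105⁺ CD31⁻) is provided to expose how
  badly it overcounts.
* **Islet annotation** — islets are built from insulin⁺/glucagon⁺ cells by
  density clustering plus morphological closing (or ingested as GeoJSON),
  and filtered at the single-cell reference area of 170 µm².
* **Collision-limited periphery bands** — each islet annotation is expanded
  outwards by 10 µm *or until it meets another expanding annotation*.
  Formally, the band of islet *i* is

  ```
  band(i) = { p : p outside every islet,
                  dist(p, ∂islet_i) ≤ 10 µm,
                  dist(p, islet_i) < dist(p, islet_j)  ∀ j ≠ i }
  ```

  a nearest-boundary (boundary-Voronoi) partition of the 10 µm buffer zone.
  Bands never overlap each other or an islet, so no cell is counted twice.
  A brute-force raster oracle validates the polygon construction in tests.
* **Per-islet metrics** — endocrine composition (INS⁺GLU⁻ / INS⁺GLU⁺ /
  INS⁻GLU⁺ by the ≥1-positive-cell rule), logarithmic size bin
  `floor(log2(area / 170 µm²))`, phenotype counts and densities per region,
  an inflammation flag (>5 associated CD45⁺ cells) and a pMSC-association
  flag.
* **Group statistics** — descriptives (mean/SD/SEM/n), pooled-variance t
  tests, one-/two-way ANOVA with Bonferroni-corrected post hocs, the
  <5-islet bin-exclusion rule, and 2^−ΔΔCt relative expression with
  geometric-mean reference normalisation.
* **Synthetic sections** — a seeded generator emits virtual sections
  (cells + ground-truth islet polygons) with lognormal islet sizes,
  configurable endocrine compositions, pMSC enrichment near
  insulin-containing islets, ANXA1⁺/IDO1⁺ sub-fractions and immune
  infiltrates, so the whole pipeline is testable end to end without any
  slide data.

## Worked example

Simulate a default 4×4 mm section (50 islets, healthy young-donor
composition), gate, annotate, quantify and summarise in one command:

```sh
isletquant run --seed 1 --out results/demo
```

which logs the stage funnel

```
simulate: 5494 cells, 50 truth islets
gate: 233 pMSC (6-plex), 1988 MSC (3-plex)
annotate: 50 islets, 50 bands
```

and prints the section summary (abridged):

```json
{
  "section_area_mm2": 16.0,
  "n_islets": 50,
  "whole_density": {"pMSC_6plex": 14.56, "immune": 63.81, "...": "..."},
  "n_pmsc": 233,
  "n_pmsc_intraislet": 6,
  "n_pmsc_periphery": 6,
  "n_pmsc_islet_associated": 12,
  "pct_pmsc_islet_associated": 5.15,
  "pct_pmsc_anxa1_pos_pooled": 30.04
}
```

Reading this: the section carries 233 six-plex pMSCs (14.6 cells/mm² over
16 mm², near the configured 14/mm²), of which 12 (5.2%) are
islet-associated — 6 inside islets and 6 within the 10 µm periphery bands —
and 30% are ANXA1⁺ (configured fraction 33.2%). Note the 3-plex gate calls
1,988 "MSCs" on the same section: an ~8.5-fold overcount driven by
CD73⁻ fibroblast-like confounders, which is why the full panel matters.
Per-islet rows (composition, size bin, counts and densities per region,
inflamed flag) land in `results/demo/profiles.csv`, geometry in
`islets.geojson`/`bands.geojson`, and every run writes a `provenance.json`
(seed, config hash, stage counts); re-running with the same seed reproduces
byte-identical tables.

The same stages are available separately (`isletquant simulate | gate |
annotate | quantify`), and as library functions (`generate_section`,
`gate_cells`, `segment_islets`, `expand_islets`, `assign_cells`,
`profile_islets`, `profile_section`, plus the statistics in
`isletquant.stats`).

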