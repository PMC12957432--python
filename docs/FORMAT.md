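# File formats and conventions

All coordinates are micrometres on the section frame: origin at the
lower-left corner of the section, x to the right, y up. Areas are µm² in
per-islet outputs and mm² in section summaries; densities are cells/mm²
(µm² → mm² conversion factor 1e6).

## Cell tables (CSV)

One row per detected cell. Required columns:

    cell_id, x_um, y_um, CD90, CD73, CD105, CD31, CD34, CD45,
    ANXA1, IDO1, insulin, glucagon

Marker columns hold one intensity per cell. An optional second-compartment
column `<marker>_nuc` is gated with OR against the same threshold.
Synthetic tables add `true_label` (beta | alpha | pmsc | endothelial |
immune | fibroblast) and `true_anxa1` / `true_ido1` flags. Gating appends
boolean `<marker>_pos` and composite phenotype columns; assignment appends
`region` (intraislet | periphery | exocrine) and `region_islet_id`
(0 = exocrine).

## Annotations (GeoJSON)

A FeatureCollection of (Multi)Polygon features with properties:

    islet_id   integer, unique per section
    area_um2   polygon area
    kind       "islet" or "periphery"

Coordinates are micrometres (not a geographic CRS; the non-standard
`crs_note` member records this). Ground-truth islets from the simulator
carry `true_composition` and `true_inflamed` instead of `kind`.

## Summaries (JSON/CSV)

`section.json` holds the section profile (totals, whole-section densities,
percentages); `profiles.csv` one row per islet; `group_summaries.csv` and
`comparisons.csv` the descriptive and inferential statistics;
`provenance.json` the seed, config hash, package version and per-stage
counts of every run.
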