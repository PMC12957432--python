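"""Seeded virtual pancreas sections.

The generator emits the post-cell-detection representation the analysis
consumes: a table of detected cells (coordinates + per-marker intensities)
and ground-truth islet polygons.  It does not render images.

Statistical structure:

* islet radii are lognormal and islet outlines are circles with a low-order
  sinusoidal radial perturbation (≤20% of the radius), placed by rejection
  sampling so that no two islets overlap;
* each islet is assigned one of the three endocrine compositions
  (INS+GLU-, INS+GLU+, INS-GLU+) and filled with endocrine cells at a
  uniform density, with at least one cell of every hormone the category
  requires and none of a hormone the category forbids;
* pMSCs are a piecewise-constant Poisson point process: a baseline rate over
  exocrine tissue, the baseline rate times ``periphery_enrichment`` within
  ``periphery_band_width`` µm of insulin-containing islets, and a separate
  intraislet rate inside islets;
* a Bernoulli subset of insulin-containing islets carries a CD45+ immune
  infiltrate (Poisson-distributed count, placed in the islet and its ring);
* confounder populations (CD31+CD34+ endothelial, CD45+ haematopoietic,
  CD90+CD105+-only fibroblast-like cells) are scattered uniformly;
* every cell draws one lognormal intensity per marker from its true
  phenotype's positive or negative component.

Determinism: one ``numpy.random.Generator`` seeded from the config drives
the whole section, and draws happen in a fixed order (compositions, islet
shapes/placement, endocrine cells per islet, inflammation flags and
infiltrates, pMSCs, confounders, ANXA1/IDO1 sub-flags, then intensities one
marker at a time in panel order).  Identical config + seed therefore gives a
bit-identical dataset.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box, mapping

from .config import COMPOSITIONS, MARKERS, SimulationConfig

#: true phenotype labels a generated cell can carry (exactly one each).
TRUE_LABELS = ("beta", "alpha", "pmsc", "endothelial", "immune", "fibroblast")

#: markers truly expressed by each phenotype; every other marker draws from
#: the negative intensity component.  ANXA1/IDO1 positivity of pMSCs is a
#: per-cell Bernoulli sub-flag handled separately.
_POSITIVE_MARKERS = {
    "beta": {"insulin"},
    "alpha": {"glucagon"},
    "pmsc": {"CD90", "CD73", "CD105"},
    "endothelial": {"CD31", "CD34"},
    "immune": {"CD45"},
    "fibroblast": {"CD90", "CD105"},
}

_MAX_PLACEMENT_ATTEMPTS = 10_000
_SHAPE_VERTICES = 64


class SectionTooCrowdedError(RuntimeError):
    """Raised when rejection sampling cannot place all islets."""


@dataclass
class TruthIslet:
    islet_id: int
    polygon: Polygon
    composition: str
    inflamed: bool

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class SectionDataset:
    """A generated section: cell table + ground-truth islets + config echo."""

    cells: pd.DataFrame
    islets_truth: list[TruthIslet]
    config: SimulationConfig
    seed: int

    @property
    def section_area_um2(self) -> float:
        return self.config.section_width * self.config.section_height

    def write(self, out_dir) -> None:
        """Write ``cells.csv`` and ``islets_truth.geojson`` under *out_dir*."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        features = []
        for isl in self.islets_truth:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(isl.polygon),
                    "properties": {
                        "islet_id": isl.islet_id,
                        "true_composition": isl.composition,
                        "true_inflamed": bool(isl.inflamed),
                        "area_um2": isl.area,
                    },
                }
            )
        collection = {
            "type": "FeatureCollection",
            # coordinates are micrometres on the section frame, not geographic
            "crs_note": "coordinates in µm, origin lower-left",
            "features": features,
        }
        with open(out / "islets_truth.geojson", "w") as fh:
            json.dump(collection, fh)
        with open(out / "simulation_config.json", "w") as fh:
            json.dump({"seed": self.seed, "config": self.config.to_dict()}, fh, indent=2)


def _islet_shape(rng: np.random.Generator, radius: float) -> np.ndarray:
    """Vertices of a perturbed circle centred at the origin.

    Radial perturbation is a sum of 2nd–4th order sinusoids with total
    amplitude at most 20% of the radius, keeping the outline convex-ish.
    """
    amps = rng.uniform(-0.2 / 3.0, 0.2 / 3.0, size=3)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    theta = np.linspace(0.0, 2.0 * math.pi, _SHAPE_VERTICES, endpoint=False)
    r = radius * (
        1.0
        + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _place_islets(rng: np.random.Generator, config: SimulationConfig) -> list[Polygon]:
    """Rejection-sample non-overlapping islet polygons inside the section."""
    placed: list[Polygon] = []
    bounds = np.empty((config.n_islets, 4))
    attempts = 0
    margin_pad = config.periphery_band_width + 2.0
    for i in range(config.n_islets):
        while True:
            attempts += 1
            if attempts > _MAX_PLACEMENT_ATTEMPTS:
                raise SectionTooCrowdedError(
                    f"could not place {config.n_islets} non-overlapping islets in a "
                    f"{config.section_width:g} x {config.section_height:g} µm section "
                    f"within {_MAX_PLACEMENT_ATTEMPTS} attempts"
                )
            radius = rng.lognormal(config.islet_radius_log_mean, config.islet_radius_log_sd)
            verts = _islet_shape(rng, radius)
            margin = 1.2 * radius + margin_pad
            if 2 * margin >= min(config.section_width, config.section_height):
                continue  # islet too large for the section; redraw
            cx = rng.uniform(margin, config.section_width - margin)
            cy = rng.uniform(margin, config.section_height - margin)
            poly = Polygon(verts + [cx, cy])
            if poly.area < 170.0:  # below one cell's area; redraw the shape
                continue
            b = poly.bounds
            if placed:
                prior = bounds[: len(placed)]
                close = ~(
                    (prior[:, 2] < b[0])
                    | (prior[:, 0] > b[2])
                    | (prior[:, 3] < b[1])
                    | (prior[:, 1] > b[3])
                )
                if any(poly.intersects(placed[j]) for j in np.flatnonzero(close)):
                    continue
            bounds[len(placed)] = b
            placed.append(poly)
            break
    return placed


def _sample_points_in(rng: np.random.Generator, geom, n: int) -> np.ndarray:
    """Uniform points inside a (multi)polygon, by per-component rejection."""
    if n == 0 or geom.is_empty:
        return np.empty((0, 2))
    parts = list(geom.geoms) if hasattr(geom, "geoms") else [geom]
    areas = np.array([p.area for p in parts])
    counts = rng.multinomial(n, areas / areas.sum())
    out = []
    for part, k in zip(parts, counts):
        if k == 0:
            continue
        minx, miny, maxx, maxy = part.bounds
        pts = np.empty((k, 2))
        got = 0
        while got < k:
            m = max(2 * (k - got), 16)
            xs = rng.uniform(minx, maxx, size=m)
            ys = rng.uniform(miny, maxy, size=m)
            inside = shapely.contains_xy(part, xs, ys)
            take = min(int(inside.sum()), k - got)
            idx = np.flatnonzero(inside)[:take]
            pts[got : got + take, 0] = xs[idx]
            pts[got : got + take, 1] = ys[idx]
            got += take
        out.append(pts)
    return np.vstack(out) if out else np.empty((0, 2))


def _poisson_count(rng: np.random.Generator, density_per_mm2: float, area_um2: float) -> int:
    return int(rng.poisson(density_per_mm2 * area_um2 * 1e-6))


def generate_section(config: SimulationConfig) -> SectionDataset:
    """Generate one virtual section from *config* (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    width, height = config.section_width, config.section_height
    section = box(0.0, 0.0, width, height)

    # 1. compositions, 2. shapes + placement
    comp_idx = (
        rng.choice(3, size=config.n_islets, p=list(config.composition_props))
        if config.n_islets
        else np.empty(0, dtype=int)
    )
    polygons = _place_islets(rng, config)

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    labels: list[str] = []

    def add(points: np.ndarray, label: str) -> None:
        xs.append(points[:, 0])
        ys.append(points[:, 1])
        labels.extend([label] * len(points))

    # 3. endocrine cells per islet (fixed islet order)
    for i, poly in enumerate(polygons):
        comp = COMPOSITIONS[comp_idx[i]]
        n = _poisson_count(rng, config.endocrine_cell_density, poly.area)
        if comp == "INS+GLU-":
            n_beta, n_alpha = max(n, 1), 0
        elif comp == "INS-GLU+":
            n_beta, n_alpha = 0, max(n, 1)
        else:
            n = max(n, 2)
            n_beta = int(rng.binomial(n, config.mixed_islet_beta_fraction))
            n_beta = min(max(n_beta, 1), n - 1)  # ≥1 cell of each hormone
            n_alpha = n - n_beta
        pts = _sample_points_in(rng, poly, n_beta + n_alpha)
        add(pts[:n_beta], "beta")
        add(pts[n_beta:], "alpha")

    # 4. immune infiltration of insulin-containing islets
    inflamed = np.zeros(config.n_islets, dtype=bool)
    for i, poly in enumerate(polygons):
        if COMPOSITIONS[comp_idx[i]] == "INS-GLU+":
            continue
        if rng.random() >= config.inflamed_fraction:
            continue
        inflamed[i] = True
        n = int(rng.poisson(config.infiltrate_mean))
        zone = poly.buffer(config.periphery_band_width, quad_segs=16).intersection(section)
        add(_sample_points_in(rng, zone, n), "immune")

    # 5. pMSCs: exocrine baseline, enriched ring, intraislet
    islet_union = shapely.unary_union(polygons) if polygons else Polygon()
    ins_polys = [
        p for i, p in enumerate(polygons) if COMPOSITIONS[comp_idx[i]] != "INS-GLU+"
    ]
    if ins_polys:
        ring = (
            shapely.unary_union([p.buffer(config.periphery_band_width, quad_segs=16) for p in ins_polys])
            .intersection(section)
            .difference(islet_union)
        )
    else:
        ring = Polygon()
    exocrine = section.difference(islet_union).difference(ring)

    n_exo = _poisson_count(rng, config.exocrine_pmsc_density, exocrine.area)
    add(_sample_points_in(rng, exocrine, n_exo), "pmsc")
    n_ring = _poisson_count(
        rng, config.exocrine_pmsc_density * config.periphery_enrichment, ring.area
    )
    add(_sample_points_in(rng, ring, n_ring), "pmsc")
    if not islet_union.is_empty:
        n_intra = _poisson_count(rng, config.intraislet_pmsc_density, islet_union.area)
        add(_sample_points_in(rng, islet_union, n_intra), "pmsc")

    # 6. confounders, uniform over the whole section
    for density, label in (
        (config.endothelial_density, "endothelial"),
        (config.immune_density, "immune"),
        (config.fibroblast_density, "fibroblast"),
    ):
        n = _poisson_count(rng, density, section.area)
        add(_sample_points_in(rng, section, n), label)

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    label_arr = np.array(labels, dtype=object)
    n_cells = len(label_arr)

    # 7. ANXA1 / IDO1 sub-flags for pMSCs
    is_pmsc = label_arr == "pmsc"
    true_anxa1 = np.zeros(n_cells, dtype=bool)
    true_ido1 = np.zeros(n_cells, dtype=bool)
    n_pmsc = int(is_pmsc.sum())
    true_anxa1[is_pmsc] = rng.random(n_pmsc) < config.anxa1_pos_fraction
    true_ido1[is_pmsc] = rng.random(n_pmsc) < config.ido1_pos_fraction

    # 8. marker intensities, one lognormal draw per cell per marker
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells, dtype=int),
            "x_um": x,
            "y_um": y,
            "true_label": label_arr,
            "true_anxa1": true_anxa1,
            "true_ido1": true_ido1,
        }
    )
    for marker in MARKERS:
        positive = np.fromiter(
            (marker in _POSITIVE_MARKERS[lab] for lab in label_arr),
            dtype=bool,
            count=n_cells,
        )
        if marker == "ANXA1":
            positive |= true_anxa1
        elif marker == "IDO1":
            positive |= true_ido1
        mu_p, sd_p = config.marker_pos_params[marker]
        mu_n, sd_n = config.marker_neg_params[marker]
        mu = np.where(positive, mu_p, mu_n)
        sd = np.where(positive, sd_p, sd_n)
        cells[marker] = np.exp(mu + sd * rng.standard_normal(n_cells))

    islets_truth = [
        TruthIslet(
            islet_id=i + 1,
            polygon=polygons[i],
            composition=COMPOSITIONS[comp_idx[i]],
            inflamed=bool(inflamed[i]),
        )
        for i in range(config.n_islets)
    ]
    return SectionDataset(cells=cells, islets_truth=islets_truth, config=config, seed=config.seed)


#: donor-group presets.  Composition percentages are group means of the study
#: cohort; inflamed fractions (53.6% / 13.6%) and infiltrate means
#: (27.5 / 15.8 CD45+ cells per inflamed islet) are the reported values for
#: the two diabetes groups.  Periphery enrichment and intraislet pMSC density
#: are phenomenological choices reproducing the reported qualitative ordering
#: (T1D > age-matched no-diabetes; later onset > earlier onset).
_GROUP_PRESETS: dict[str, dict] = {
    "<13y_T1D": dict(
        composition_props=(0.0347, 0.1054, 0.8599),
        inflamed_fraction=0.536,
        infiltrate_mean=27.48,
        periphery_enrichment=4.0,
        intraislet_pmsc_density=30.0,
    ),
    "<13y_ND": dict(
        composition_props=(0.4270, 0.5176, 0.0554),
        inflamed_fraction=0.0015,
        infiltrate_mean=10.0,
        periphery_enrichment=1.5,
        intraislet_pmsc_density=12.0,
    ),
    ">=13y_T1D": dict(
        composition_props=(0.0715, 0.2293, 0.6992),
        inflamed_fraction=0.136,
        infiltrate_mean=15.84,
        periphery_enrichment=8.0,
        intraislet_pmsc_density=40.0,
    ),
    ">=13y_ND": dict(
        composition_props=(0.4643, 0.4395, 0.0962),
        inflamed_fraction=0.0015,
        infiltrate_mean=10.0,
        periphery_enrichment=2.5,
        intraislet_pmsc_density=16.0,
    ),
}

GROUP_TAGS = tuple(_GROUP_PRESETS)


def reference_config(group: str, **overrides) -> SimulationConfig:
    """A fully populated :class:`SimulationConfig` for one donor group.

    *group* is one of ``<13y_T1D``, ``<13y_ND``, ``>=13y_T1D``, ``>=13y_ND``
    (age at type 1 diabetes diagnosis under/over 13 years, or age-matched
    donors without diabetes).  Keyword *overrides* replace any config field.
    """
    if group not in _GROUP_PRESETS:
        raise ValueError(f"unknown group {group!r}; valid tags: {', '.join(GROUP_TAGS)}")
    preset = dict(_GROUP_PRESETS[group])
    # renormalise the printed percentages exactly to 1
    props = np.asarray(preset["composition_props"], dtype=float)
    preset["composition_props"] = tuple(props / props.sum())
    preset.update(overrides)
    cfg = dataclasses.replace(SimulationConfig(), **preset)
    cfg.validate()
    return cfg
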