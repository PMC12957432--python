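"""Configuration types shared across the pipeline.

All coordinates are micrometres, origin at the section's lower-left corner,
x to the right and y upwards.  Densities are cells/mm²; areas are µm² unless
a name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

#: Marker panel, in the fixed order used everywhere (CSV columns, intensity
#: draws, threshold blocks).
MARKERS: tuple[str, ...] = (
    "CD90",
    "CD73",
    "CD105",
    "CD31",
    "CD34",
    "CD45",
    "ANXA1",
    "IDO1",
    "insulin",
    "glucagon",
)

#: Endocrine composition categories (insulin/glucagon, ≥1-positive-cell rule).
COMPOSITIONS: tuple[str, ...] = ("INS+GLU-", "INS+GLU+", "INS-GLU+")

#: Approximate area of a single cell, µm².  Used as the minimum islet area
#: and as the reference for the logarithmic islet size bins.
REFERENCE_CELL_AREA: float = 170.0


def _default_marker_params(mu: float, sigma: float) -> dict[str, tuple[float, float]]:
    return {m: (mu, sigma) for m in MARKERS}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tissue-section generator.

    The defaults describe a healthy young-donor section: islet endocrine
    compositions in the proportions observed for donors under 13 without
    diabetes (42.7 / 51.8 / 5.5% for INS+GLU-, INS+GLU+, INS-GLU+), a whole
    pancreas pMSC density of 14 cells/mm², a third of pMSCs ANXA1-positive,
    ~1% IDO1-positive, and essentially no islet immune infiltration.
    """

    section_width: float = 4000.0
    section_height: float = 4000.0
    n_islets: int = 50
    #: lognormal islet radius, log-µm: median radius 40 µm ≈ 5,000 µm² area.
    islet_radius_log_mean: float = math.log(40.0)
    islet_radius_log_sd: float = 0.35
    #: P(INS+GLU-), P(INS+GLU+), P(INS-GLU+); must sum to 1.
    composition_props: tuple[float, float, float] = (0.4270, 0.5176, 0.0554)
    #: one endocrine cell per 170 µm² of islet.
    endocrine_cell_density: float = 1e6 / REFERENCE_CELL_AREA
    exocrine_pmsc_density: float = 14.0
    #: pMSC rate multiplier within 10 µm of insulin-containing islets.
    periphery_enrichment: float = 5.0
    intraislet_pmsc_density: float = 16.0
    #: fraction of beta cells among endocrine cells of a mixed INS+GLU+ islet.
    mixed_islet_beta_fraction: float = 0.7
    anxa1_pos_fraction: float = 0.332
    ido1_pos_fraction: float = 0.01
    #: probability an insulin-containing islet carries an immune infiltrate.
    inflamed_fraction: float = 0.0015
    #: mean CD45+ cells per inflamed islet (Poisson).
    infiltrate_mean: float = 10.0
    periphery_band_width: float = 10.0
    # Confounder cell densities, cells/mm², scattered over the whole section.
    endothelial_density: float = 50.0  # CD31+CD34+
    immune_density: float = 60.0  # CD45+ background (non-infiltrate)
    fibroblast_density: float = 109.0  # CD90+CD105+ only (CD73-)
    #: per-marker (mu, sigma) of log-intensity for truly positive cells.
    marker_pos_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: _default_marker_params(math.log(100.0), 0.4)
    )
    #: per-marker (mu, sigma) of log-intensity for truly negative cells.
    marker_neg_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: _default_marker_params(0.0, 0.4)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.section_width <= 0 or self.section_height <= 0:
            raise ValueError("section dimensions must be > 0")
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        props = tuple(self.composition_props)
        if len(props) != 3 or any(p < 0 for p in props):
            raise ValueError("composition_props must be three probabilities >= 0")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("composition_props must sum to 1 (within 1e-9)")
        for name in (
            "endocrine_cell_density",
            "exocrine_pmsc_density",
            "intraislet_pmsc_density",
            "endothelial_density",
            "immune_density",
            "fibroblast_density",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("anxa1_pos_fraction", "ido1_pos_fraction", "inflamed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.periphery_enrichment < 0:
            raise ValueError("periphery_enrichment must be >= 0")
        if self.periphery_band_width <= 0:
            raise ValueError("periphery_band_width must be > 0")
        for params in (self.marker_pos_params, self.marker_neg_params):
            for m in MARKERS:
                if m not in params:
                    raise ValueError(f"marker intensity parameters missing for {m!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["composition_props"] = list(self.composition_props)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "composition_props" in d:
            d["composition_props"] = tuple(d["composition_props"])
        for key in ("marker_pos_params", "marker_neg_params"):
            if key in d:
                d[key] = {m: tuple(v) for m, v in d[key].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class AnalysisParams:
    """Geometry parameters for islet annotation and periphery expansion."""

    #: islets smaller than one cell's area are discarded.
    min_islet_area: float = REFERENCE_CELL_AREA
    #: outward expansion defining the islet periphery band, µm.
    expansion_distance: float = 10.0
    #: neighbour distance for density clustering of endocrine cells, µm.
    #: About 4-5x the mean endocrine nearest-neighbour spacing, so sampling
    #: gaps inside one islet do not split it into several clusters.
    cluster_radius: float = 30.0
    #: minimum endocrine cells per cluster.
    cluster_min_cells: int = 3
    #: grid pitch of the brute-force raster oracle, µm.
    raster_resolution: float = 0.5

    def validate(self) -> None:
        if self.min_islet_area <= 0:
            raise ValueError("min_islet_area must be > 0")
        if self.expansion_distance <= 0:
            raise ValueError("expansion_distance must be > 0")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be > 0")
        if self.cluster_min_cells < 1:
            raise ValueError("cluster_min_cells must be >= 1")
        if self.raster_resolution > self.expansion_distance / 10.0:
            raise ValueError(
                "raster_resolution must be <= expansion_distance / 10 "
                f"({self.expansion_distance / 10.0:g} µm)"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisParams":
        params = cls(**dict(d))
        params.validate()
        return params


class GateThresholds(dict):
    """Per-marker positive-call thresholds (intensity units) for one donor.

    A mapping ``marker -> threshold``; a cell is called positive for a marker
    iff its intensity is >= the threshold (closed comparison).
    """

    def validate(self, required: tuple[str, ...] = MARKERS) -> None:
        for m in required:
            if m not in self:
                raise ValueError(f"gating threshold missing for marker {m!r}")
            if self[m] < 0:
                raise ValueError(f"gating threshold for {m!r} must be >= 0")

    @classmethod
    def default(cls, threshold: float = 10.0) -> "GateThresholds":
        # geometric midpoint of the default negative (~1) and positive (~100)
        # intensity components.
        return cls({m: threshold for m in MARKERS})


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
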