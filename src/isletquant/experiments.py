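"""Validation experiments on synthetic sections.

These experiments generate sections with known ground truth, quantify them
with the pipeline, and measure how well the analysis recovers the generating
parameters.  Quantification ingests the generator's ground-truth islet
polygons through the same path used for externally provided annotations:
cluster-based segmentation places the islet boundary near the outermost
detected endocrine cell plus half the cluster radius, a small outward offset
that would dilute a 10 µm periphery band with baseline-rate area, so
parameter-recovery experiments must not confound segmentation error with
quantification error.  Segmentation accuracy is assessed separately.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import AnalysisParams, GateThresholds, SimulationConfig
from .gating import gate_cells
from .geometry import IsletAnnotation, assign_cells, expand_islets
from .metrics import profile_islets
from .synthetic import SectionDataset, generate_section, reference_config

#: exocrine pMSC density used by the enrichment-recovery experiment,
#: cells/mm².  Chosen by a power calculation: with 500 islets the pooled
#: band area is ~1.25 mm², and resolving a 2x enrichment to within 10%
#: needs the Poisson error of the band count (1/sqrt(density x 2 x 1.25))
#: below ~3%, i.e. a density of a few hundred cells/mm²; the study-scale
#: 14 cells/mm² would leave only ~35 band cells.
RECOVERY_PMSC_DENSITY = 400.0


def quantify_with_truth(
    dataset: SectionDataset,
    params: AnalysisParams | None = None,
    thresholds: GateThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gate, band-expand and profile a section using its truth polygons.

    Returns ``(gated cells with region assignment, per-islet profiles)``.
    """
    params = params or AnalysisParams()
    thresholds = thresholds or GateThresholds.default()
    gated = gate_cells(dataset.cells, thresholds)
    islets = [IsletAnnotation(t.islet_id, t.polygon) for t in dataset.islets_truth]
    bands = expand_islets(islets, params)
    region, islet_id = assign_cells(gated[["x_um", "y_um"]].to_numpy(), islets, bands)
    gated = gated.assign(region=region, region_islet_id=islet_id)
    return gated, profile_islets(gated, islets, bands)


def estimate_periphery_enrichment(
    enrichment: float,
    n_islets_total: int = 500,
    n_seeds: int = 10,
    base_seed: int = 0,
    exocrine_pmsc_density: float = RECOVERY_PMSC_DENSITY,
) -> float:
    """Recover the periphery enrichment factor from simulated sections.

    Generates *n_seeds* sections of ``n_islets_total / n_seeds`` islets with
    the given enrichment, pools pMSC counts and areas across sections, and
    returns (pMSC density in bands of insulin-containing islets) /
    (exocrine pMSC density) — an estimate of the generating multiplier.
    """
    per_section = max(1, n_islets_total // n_seeds)
    band_count = band_area = 0.0
    exo_count = exo_area = 0.0
    for k in range(n_seeds):
        cfg = dataclasses.replace(
            SimulationConfig(),
            n_islets=per_section,
            periphery_enrichment=enrichment,
            exocrine_pmsc_density=exocrine_pmsc_density,
            seed=base_seed + k,
        )
        ds = generate_section(cfg)
        gated, profiles = quantify_with_truth(ds)
        ins = profiles[profiles["composition"].isin(["INS+GLU-", "INS+GLU+"])]
        band_count += ins["pMSC_6plex_periphery_count"].sum()
        band_area += ins["band_area_um2"].sum()
        exo = gated[gated["region"] == "exocrine"]
        exo_count += int(exo["pMSC_6plex"].sum())
        exo_area += (
            ds.section_area_um2
            - profiles["islet_area_um2"].sum()
            - profiles["band_area_um2"].sum()
        )
    band_density = band_count / band_area
    exo_density = exo_count / exo_area
    return float(band_density / exo_density)


def run_group_preset(
    group: str, n_islets: int, seed: int, section_side: float | None = None
) -> dict:
    """Generate and quantify one donor-group preset section.

    Returns periphery pMSC densities (cells/mm²) by endocrine composition,
    pooled over islets, and the measured inflamed fraction among
    insulin-containing islets.
    """
    if section_side is None:
        # keep islet coverage around 5% so placement stays easy
        section_side = float(np.sqrt(n_islets) * 450.0)
    cfg = reference_config(
        group,
        n_islets=n_islets,
        section_width=section_side,
        section_height=section_side,
        seed=seed,
    )
    ds = generate_section(cfg)
    _, profiles = quantify_with_truth(ds)
    out: dict = {"group": group, "n_islets": len(profiles)}
    for comp, sub in profiles.groupby("composition"):
        area = sub["band_area_um2"].sum()
        out[f"periphery_density[{comp}]"] = (
            float(sub["pMSC_6plex_periphery_count"].sum()) / area * 1e6 if area else float("nan")
        )
    ins = profiles[profiles["composition"].isin(["INS+GLU-", "INS+GLU+"])]
    pooled_ins_area = ins["band_area_um2"].sum()
    out["periphery_density[INS-containing]"] = (
        float(ins["pMSC_6plex_periphery_count"].sum()) / pooled_ins_area * 1e6
        if pooled_ins_area
        else float("nan")
    )
    out["n_insulin_islets"] = int(len(ins))
    out["inflamed_fraction"] = float(ins["inflamed"].mean()) if len(ins) else float("nan")
    return out
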