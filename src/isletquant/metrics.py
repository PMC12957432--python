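"""Per-islet and per-section quantification.

For every islet annotation this module computes the endocrine composition
category (≥1-positive-cell rule for each hormone), the logarithmic size bin
(floor(log2(area / 170 µm²)), one cell ≈ 170 µm²), phenotype counts and
densities separately for the islet interior and its periphery band, an
inflammation flag (more than five CD45+ cells inside the islet or in its
band) and a pMSC-association flag (at least one pMSC in either region).

Densities are counts divided by the region area, converted from µm² to mm²
(factor 1e6).  Counts are integers; there is no area-weighted fractional
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import REFERENCE_CELL_AREA
from .geometry import IsletAnnotation, PeripheryBand

#: phenotypes counted per region, in output column order.
COUNTED_PHENOTYPES = (
    "pMSC_6plex",
    "ANXA1_pos_pMSC",
    "IDO1_pos_pMSC",
    "immune",
    "insulin_pos",
    "glucagon_pos",
)

#: an islet is inflamed if it has more than this many associated CD45+ cells.
INFLAMED_THRESHOLD = 5


def categorize_islet(insulin_count: int, glucagon_count: int) -> str:
    """Endocrine composition from intraislet hormone-positive cell counts."""
    if insulin_count < 0 or glucagon_count < 0:
        raise ValueError("hormone-positive cell counts must be >= 0")
    if insulin_count == 0 and glucagon_count == 0:
        raise ValueError(
            "uncategorisable islet: no insulin- or glucagon-positive cells "
            "(islets are defined by endocrine staining)"
        )
    if glucagon_count == 0:
        return "INS+GLU-"
    if insulin_count == 0:
        return "INS-GLU+"
    return "INS+GLU+"


def size_bin(area: float, reference_cell_area: float = REFERENCE_CELL_AREA) -> int:
    """floor(log2(area / reference_cell_area)); bin 0 is a one-cell islet."""
    if area < reference_cell_area:
        raise ValueError(
            f"islet area {area:g} µm² is below the reference cell area "
            f"{reference_cell_area:g} µm²; such islets are filtered upstream"
        )
    return int(np.floor(np.log2(area / reference_cell_area)))


def profile_islets(
    cells: pd.DataFrame,
    islets: list[IsletAnnotation],
    bands: list[PeripheryBand],
) -> pd.DataFrame:
    """One row per islet with all per-islet quantities.

    *cells* must carry the gated phenotype columns plus the ``region`` /
    ``region_islet_id`` assignment columns.
    """
    for col in ("region", "region_islet_id"):
        if col not in cells.columns:
            raise KeyError(f"cell table is missing assignment column {col!r}")
    band_by_id = {b.islet_id: b for b in bands}
    rows = []
    for isl in islets:
        band = band_by_id.get(isl.islet_id)
        band_area = band.area if band is not None else 0.0
        mine = cells[cells["region_islet_id"] == isl.islet_id]
        intra = mine[mine["region"] == "intraislet"]
        peri = mine[mine["region"] == "periphery"]
        row: dict = {"islet_id": isl.islet_id, "islet_area_um2": isl.area, "band_area_um2": band_area}
        for ph in COUNTED_PHENOTYPES:
            n_in = int(intra[ph].sum())
            n_pe = int(peri[ph].sum())
            if band_area <= 0.0 and n_pe > 0:
                raise RuntimeError(
                    f"islet {isl.islet_id}: {n_pe} periphery cells but zero band area "
                    "(geometry inconsistency)"
                )
            row[f"{ph}_intraislet_count"] = n_in
            row[f"{ph}_periphery_count"] = n_pe
            row[f"{ph}_intraislet_density"] = n_in / isl.area * 1e6
            row[f"{ph}_periphery_density"] = n_pe / band_area * 1e6 if band_area > 0 else 0.0
        row["composition"] = categorize_islet(
            row["insulin_pos_intraislet_count"], row["glucagon_pos_intraislet_count"]
        )
        row["size_bin"] = size_bin(isl.area)
        n_immune = row["immune_intraislet_count"] + row["immune_periphery_count"]
        row["inflamed"] = n_immune > INFLAMED_THRESHOLD
        n_pmsc = row["pMSC_6plex_intraislet_count"] + row["pMSC_6plex_periphery_count"]
        row["has_associated_pmsc"] = n_pmsc >= 1
        rows.append(row)
    lead = ["islet_id", "composition", "size_bin", "islet_area_um2", "band_area_um2"]
    df = pd.DataFrame(rows)
    if len(df):
        df = df[lead + [c for c in df.columns if c not in lead]]
    return df


@dataclass
class SectionProfile:
    """Whole-section totals, densities and fractions."""

    section_area_mm2: float
    n_islets: int
    n_cells: int
    whole_density: dict[str, float]  # cells/mm² per counted phenotype
    n_pmsc: int
    n_pmsc_intraislet: int
    n_pmsc_periphery: int
    n_pmsc_islet_associated: int
    n_anxa1_pmsc: int
    n_anxa1_pmsc_intraislet: int
    n_anxa1_pmsc_periphery: int
    pct_pmsc_islet_associated: float
    pct_pmsc_anxa1_pos_pooled: float
    pct_pmsc_anxa1_pos_donor_mean: float
    pct_anxa1_pmsc_islet_associated: float
    pct_anxa1_pmsc_intraislet: float
    pct_anxa1_pmsc_periphery: float

    def to_dict(self) -> dict:
        return asdict(self)


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else 0.0


def profile_section(
    cells: pd.DataFrame,
    profiles: pd.DataFrame,
    section_area_mm2: float,
    donor: pd.Series | None = None,
) -> SectionProfile:
    """Aggregate gated cells and islet profiles into section-level numbers.

    ``pct_pmsc_anxa1_pos_pooled`` is the pooled cell fraction; if *donor*
    (a per-cell donor label) is given, ``pct_pmsc_anxa1_pos_donor_mean`` is
    the unweighted mean of per-donor fractions, otherwise it equals the
    pooled value.  Both are reported because a cohort-level figure can be
    either statistic.
    """
    if section_area_mm2 <= 0:
        raise ValueError("section_area_mm2 must be > 0")
    whole_density = {
        ph: float(cells[ph].sum()) / section_area_mm2 for ph in COUNTED_PHENOTYPES
    }
    n_pmsc = int(cells["pMSC_6plex"].sum())
    n_anxa1_pmsc = int(cells["ANXA1_pos_pMSC"].sum())
    if len(profiles):
        n_pmsc_in = int(profiles["pMSC_6plex_intraislet_count"].sum())
        n_pmsc_pe = int(profiles["pMSC_6plex_periphery_count"].sum())
        n_anx_in = int(profiles["ANXA1_pos_pMSC_intraislet_count"].sum())
        n_anx_pe = int(profiles["ANXA1_pos_pMSC_periphery_count"].sum())
    else:
        n_pmsc_in = n_pmsc_pe = n_anx_in = n_anx_pe = 0
    if donor is not None and n_pmsc:
        per_donor = cells.groupby(donor).apply(
            lambda g: _pct(g["ANXA1_pos_pMSC"].sum(), g["pMSC_6plex"].sum()),
            include_groups=False,
        )
        donor_mean = float(per_donor.mean())
    else:
        donor_mean = _pct(n_anxa1_pmsc, n_pmsc)
    return SectionProfile(
        section_area_mm2=float(section_area_mm2),
        n_islets=int(len(profiles)),
        n_cells=int(len(cells)),
        whole_density=whole_density,
        n_pmsc=n_pmsc,
        n_pmsc_intraislet=n_pmsc_in,
        n_pmsc_periphery=n_pmsc_pe,
        n_pmsc_islet_associated=n_pmsc_in + n_pmsc_pe,
        n_anxa1_pmsc=n_anxa1_pmsc,
        n_anxa1_pmsc_intraislet=n_anx_in,
        n_anxa1_pmsc_periphery=n_anx_pe,
        pct_pmsc_islet_associated=_pct(n_pmsc_in + n_pmsc_pe, n_pmsc),
        pct_pmsc_anxa1_pos_pooled=_pct(n_anxa1_pmsc, n_pmsc),
        pct_pmsc_anxa1_pos_donor_mean=donor_mean,
        pct_anxa1_pmsc_islet_associated=_pct(n_anx_in + n_anx_pe, n_anxa1_pmsc),
        pct_anxa1_pmsc_intraislet=_pct(n_anx_in, n_anxa1_pmsc),
        pct_anxa1_pmsc_periphery=_pct(n_anx_pe, n_anxa1_pmsc),
    )


def composition_totals(counts: dict[str, float]) -> float:
    """Total islet count from a per-composition breakdown (row additivity)."""
    return float(sum(counts.values()))
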