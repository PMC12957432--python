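"""Marker calls and composite phenotype labels.

A cell is positive for a marker iff its intensity is >= the donor's
threshold for that marker (closed comparison; thresholds are set per donor).
If a second-compartment column ``<marker>_nuc`` is present, the cell is
positive if either compartment clears the threshold.

Composite phenotypes are pure boolean conjunctions of marker calls:

==================  ==========================================
pMSC_6plex          CD73+ CD90+ CD105+ CD31- CD34- CD45-
MSC_3plex           CD90+ CD105+ CD31-
ANXA1_pos_pMSC      pMSC_6plex and ANXA1+
IDO1_pos_pMSC       pMSC_6plex and IDO1+
immune              CD45+
endothelial         CD31+
ANXA1_pos_any       ANXA1+
insulin_pos         insulin+
glucagon_pos        glucagon+
==================  ==========================================

Labels are not mutually exclusive except where the definitions force it
(a pMSC_6plex cell is CD45- hence never immune, and CD31- hence never
endothelial).  The reduced 3-plex definition is a superset of the 6-plex
one on every input, which is the overcounting the full panel corrects.
"""

from __future__ import annotations

import pandas as pd

from .config import GateThresholds

#: composite label -> (positive markers, negative markers)
PHENOTYPE_RULES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "pMSC_6plex": (("CD73", "CD90", "CD105"), ("CD31", "CD34", "CD45")),
    "MSC_3plex": (("CD90", "CD105"), ("CD31",)),
    "ANXA1_pos_pMSC": (("ANXA1", "CD73", "CD90", "CD105"), ("CD31", "CD34", "CD45")),
    "IDO1_pos_pMSC": (("IDO1", "CD73", "CD90", "CD105"), ("CD31", "CD34", "CD45")),
    "immune": (("CD45",), ()),
    "endothelial": (("CD31",), ()),
    "ANXA1_pos_any": (("ANXA1",), ()),
    "insulin_pos": (("insulin",), ()),
    "glucagon_pos": (("glucagon",), ()),
}

PHENOTYPE_LABELS = tuple(PHENOTYPE_RULES)


def call_markers(cells: pd.DataFrame, thresholds: GateThresholds) -> pd.DataFrame:
    """Append a boolean ``<marker>_pos`` column per thresholded marker.

    Raises ``KeyError`` naming the marker if its intensity column is absent.
    """
    thresholds.validate(tuple(thresholds))
    out = cells.copy()
    for marker, thr in thresholds.items():
        if marker not in cells.columns:
            raise KeyError(f"cell table is missing intensity column for marker {marker!r}")
        pos = cells[marker].to_numpy() >= thr
        nuc = f"{marker}_nuc"
        if nuc in cells.columns:
            pos = pos | (cells[nuc].to_numpy() >= thr)
        out[f"{marker}_pos"] = pos
    return out


def classify_phenotypes(called: pd.DataFrame) -> pd.DataFrame:
    """Append one boolean column per composite phenotype label."""
    out = called.copy()
    for label, (pos, neg) in PHENOTYPE_RULES.items():
        flag = pd.Series(True, index=called.index)
        for m in pos:
            flag &= _marker_col(called, m)
        for m in neg:
            flag &= ~_marker_col(called, m)
        out[label] = flag.to_numpy()
    return out


def _marker_col(df: pd.DataFrame, marker: str) -> pd.Series:
    col = f"{marker}_pos"
    if col not in df.columns:
        raise KeyError(f"marker call column {col!r} missing; run call_markers first")
    return df[col]


def gate_cells(cells: pd.DataFrame, thresholds: GateThresholds) -> pd.DataFrame:
    """``call_markers`` followed by ``classify_phenotypes``."""
    return classify_phenotypes(call_markers(cells, thresholds))


def panel_overcount(
    cells: pd.DataFrame, thresholds: GateThresholds, section_area_mm2: float
) -> tuple[float, float]:
    """Whole-section MSC densities (cells/mm²) under the 3-plex and 6-plex panels.

    Returns ``(density_3plex, density_6plex)``; the 3-plex density is always
    at least the 6-plex density because its gate is a relaxation.
    """
    if section_area_mm2 <= 0:
        raise ValueError("section_area_mm2 must be > 0")
    gated = gate_cells(cells, thresholds)
    return (
        float(gated["MSC_3plex"].sum() / section_area_mm2),
        float(gated["pMSC_6plex"].sum() / section_area_mm2),
    )
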