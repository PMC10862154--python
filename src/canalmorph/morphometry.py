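"""Section-level histomorphometric indices and size conversions.

Indices follow standard bone-histomorphometry nomenclature: Ct.Ar (cortical
area), N.Ca (canal count), Tt.Ca.Ar (total canal area), N.Ca/Ct.Ar (canal
numerical density) and Tt.Ca.Ar/Ct.Ar (canal area fraction, i.e. porosity).
Areas are reported in mm^2 and densities in 1/mm^2.

Two canal selections are supported:
  combined      Ca.Ar > 0.002 mm^2 (closing + cutting cones)
  cutting_only  Ca.Ar > 0.04 mm^2  (cutting cones)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SELECTIONS = ("combined", "cutting_only")

#: Index column names shared by sections tables and group summaries.
INDEX_COLUMNS = ("Ct_Ar_mm2", "N_Ca", "Tt_Ca_Ar_mm2", "N_Ca_per_Ct_Ar",
                 "Tt_Ca_Ar_per_Ct_Ar")


@dataclass
class SectionMorphometry:
    """Morphometric indices of one section for one canal selection."""

    subject_id: str | None
    site: str | None
    group: str | None
    selection: str
    Ct_Ar_mm2: float
    N_Ca: int
    Tt_Ca_Ar_mm2: float
    N_Ca_per_Ct_Ar: float
    Tt_Ca_Ar_per_Ct_Ar: float


def canal_diameter(area_mm2: float) -> float:
    """Equivalent circular diameter Ca.Dm (um) of a canal area (mm^2)."""
    if area_mm2 < 0:
        raise ValueError("area must be non-negative")
    return 2000.0 * math.sqrt(area_mm2 / math.pi)


def area_cutoff_from_diameter(diameter_um: float) -> float:
    """Area cut-off (mm^2) from a canal diameter, at one significant figure.

    This reproduces how the class cut-offs derive from nominal diameters:
    a 50 um diameter gives pi*(0.025 mm)^2 ~ 0.002 mm^2 and a 225 um diameter
    gives pi*(0.1125 mm)^2 ~ 0.04 mm^2.
    """
    if diameter_um < 0:
        raise ValueError("diameter must be non-negative")
    if diameter_um == 0:
        return 0.0
    area = math.pi * (diameter_um / 2000.0) ** 2
    exponent = math.floor(math.log10(abs(area)))
    return round(area, -exponent)


def min_resolvable_diameter(pixel_spacing_um: float) -> float:
    """Minimum resolvable canal diameter (um): one pixel's equivalent circle.

    The smallest detectable canal is a single pixel, whose equivalent
    circular diameter is 2*s/sqrt(pi); reported to 2 decimals.
    """
    if not pixel_spacing_um > 0:
        raise ValueError("pixel spacing must be positive")
    return round(2.0 * pixel_spacing_um / math.sqrt(math.pi), 2)


def _select(records, selection: str, config=None):
    from canalmorph.pore_analysis import FilterConfig

    cfg = config or FilterConfig()
    if selection == "combined":
        return [r for r in records if r.area_mm2 > cfg.area_min_mm2]
    if selection == "cutting_only":
        return [r for r in records if r.area_mm2 > cfg.cutting_min_mm2]
    raise ValueError(f"unknown selection {selection!r}; expected one of {SELECTIONS}")


def section_morphometry(records, cmask, selection: str = "combined",
                        subject_id: str | None = None, site: str | None = None,
                        group: str | None = None) -> SectionMorphometry:
    """Compute section indices from retained pore records and a cortical mask.

    ``records`` should already be filtered (only retained records are
    counted); the selection then narrows by canal size class.
    """
    if not cmask.area_mm2 > 0:
        raise ValueError("cortical mask has zero area")
    retained = [r for r in records if r.retained]
    chosen = _select(retained, selection)
    n_ca = len(chosen)
    tt = float(sum(r.area_mm2 for r in chosen))
    return SectionMorphometry(
        subject_id=subject_id, site=site, group=group, selection=selection,
        Ct_Ar_mm2=cmask.area_mm2, N_Ca=n_ca, Tt_Ca_Ar_mm2=tt,
        N_Ca_per_Ct_Ar=n_ca / cmask.area_mm2,
        Tt_Ca_Ar_per_Ct_Ar=tt / cmask.area_mm2,
    )


def sections_to_frame(sections: list[SectionMorphometry]) -> pd.DataFrame:
    """Tabulate per-section indices (sections.csv dialect)."""
    return pd.DataFrame([{
        "subject_id": s.subject_id, "site": s.site, "group": s.group,
        "selection": s.selection, "Ct_Ar_mm2": s.Ct_Ar_mm2, "N_Ca": s.N_Ca,
        "Tt_Ca_Ar_mm2": s.Tt_Ca_Ar_mm2, "N_Ca_per_Ct_Ar": s.N_Ca_per_Ct_Ar,
        "Tt_Ca_Ar_per_Ct_Ar": s.Tt_Ca_Ar_per_Ct_Ar,
    } for s in sections])


def size_histogram(records, bin_edges) -> np.ndarray:
    """Counts of retained canals per area bin, right-open convention [lo, hi).

    Counts are summable across sections; edges must be strictly increasing.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    areas = np.array([r.area_mm2 for r in records if r.retained])
    counts = np.zeros(len(edges) - 1, dtype=int)
    if len(areas) == 0:
        return counts
    idx = np.searchsorted(edges, areas, side="right") - 1
    valid = (idx >= 0) & (areas < edges[-1])
    np.add.at(counts, idx[valid], 1)
    return counts


def log_bin_edges(max_area_mm2: float, min_area_mm2: float = 0.002,
                  n_bins: int = 30) -> np.ndarray:
    """Logarithmic bin edges for canal-size distributions."""
    if not max_area_mm2 > min_area_mm2:
        raise ValueError("max area must exceed min area")
    return np.logspace(np.log10(min_area_mm2), np.log10(max_area_mm2), n_bins + 1)


def group_summary(section_table: pd.DataFrame, by=("site", "group", "selection"),
                  indices=INDEX_COLUMNS) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of each index per group cell.

    A single-section cell has undefined SD; it is reported as 0 and the cell
    flagged via the ``n`` column (n = 1).
    """
    if section_table.empty:
        raise ValueError("empty section table")
    rows = []
    for key, sub in section_table.groupby(list(by), sort=True):
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(sub)
        for col in indices:
            vals = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = vals.mean()
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
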