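"""Land-cover composition of home ranges, weighted by the utilization PDF.

For each individual and period the probability mass inside the home-range
contour is attributed to the land-cover class of each cell and
renormalized within the contour, giving weighted relative proportions
that sum to 1; multiplying by the home-range area converts them to
per-class areas (km^2).  Group summaries (mean, SE) and the removal of
classes never used by any individual mirror standard habitat-use
reporting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import LandCoverGrid, PDFGrid
from .homerange import HomeRange

USE_COLUMNS = [
    "individual_id",
    "species",
    "period",
    "fate",
    "class_code",
    "class_name",
    "weighted_proportion",
    "area_km2",
]


def weighted_proportions(
    pdf: PDFGrid, hr: HomeRange, lc: LandCoverGrid
) -> dict[int, float]:
    """PDF-weighted relative proportion of each land-cover class.

    p_c = (mass of home-range cells of class c) / (mass of all home-range
    cells); the proportions sum to 1 over the classes present in the
    contour.  All three rasters must share one grid definition.
    """
    if pdf.grid != hr.grid or pdf.grid != lc.grid:
        raise ValueError("pdf, home range and land cover must share one grid")
    if not hr.mask.any():
        raise ValueError("empty home-range mask")
    mass = pdf.cell_mass[hr.mask]
    codes = lc.class_code[hr.mask]
    total = mass.sum()
    if total <= 0:
        raise ValueError("home range carries no probability mass")
    out: dict[int, float] = {}
    for code in np.unique(codes):
        out[int(code)] = float(mass[codes == code].sum() / total)
    return out


def class_areas(proportions: dict[int, float], hr: HomeRange) -> dict[int, float]:
    """Per-class area (km^2): weighted proportion times home-range area."""
    s = sum(proportions.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1 (got {s:.6f})")
    return {code: p * hr.area_km2 for code, p in proportions.items()}


def use_rows(
    individual_id: str,
    species: str,
    period: str,
    fate: str,
    pdf: PDFGrid,
    hr: HomeRange,
    lc: LandCoverGrid,
    all_codes=None,
) -> pd.DataFrame:
    """Long-format habitat-use rows for one individual x period.

    Classes absent from the home range get explicit zero rows (so group
    summaries average over the same class set); ``all_codes`` defaults to
    every class in the land-cover legend.
    """
    props = weighted_proportions(pdf, hr, lc)
    areas = class_areas(props, hr)
    codes = sorted(all_codes) if all_codes is not None else sorted(lc.class_names)
    rows = [
        {
            "individual_id": individual_id,
            "species": species,
            "period": period,
            "fate": fate,
            "class_code": code,
            "class_name": lc.class_names.get(code, str(code)),
            "weighted_proportion": props.get(code, 0.0),
            "area_km2": areas.get(code, 0.0),
        }
        for code in codes
    ]
    return pd.DataFrame(rows, columns=USE_COLUMNS)


def drop_unused_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Remove classes with zero weighted proportion across all rows.

    Mirrors the convention of excluding land-cover classes no individual
    ever used before group comparison.
    """
    used = table.groupby("class_code")["weighted_proportion"].transform("max") > 0
    return table[used].reset_index(drop=True)


def summarize(table: pd.DataFrame, by=("species", "period")) -> pd.DataFrame:
    """Per-group mean and standard error of proportions and areas.

    SE uses the n-1 standard deviation over individuals; singleton groups
    get SE 0 with ``se_undefined`` flagged True.
    """
    by = list(by) + ["class_code", "class_name"]
    recs = []
    for key, g in table.groupby(by, sort=True):
        n = len(g)
        if n == 0:
            warnings.warn(f"empty group {key} omitted")
            continue
        rec = dict(zip(by, key))
        rec["n"] = n
        for col, label in (("weighted_proportion", "proportion"), ("area_km2", "area_km2")):
            vals = g[col].to_numpy(dtype=float)
            rec[f"mean_{label}"] = vals.mean()
            rec[f"se_{label}"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        rec["se_undefined"] = n < 2
        recs.append(rec)
    return pd.DataFrame(recs)
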