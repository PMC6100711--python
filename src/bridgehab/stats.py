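"""CV / delta-CV summaries and the chi-square independence test.

The coefficient of variation of per-class home-range area across
individuals measures how variable habitat use is within a group; the
difference post minus pre independence (delta CV) measures whether
individuals became more alike after leaving parental care (negative =
homogenization).  The chi-square test asks whether class-use counts are
independent of group membership, after removing classes whose total
count falls below a minimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


def cv(values) -> float:
    """Coefficient of variation: sd (n-1 denominator) / mean.

    Requires at least two values and a nonzero mean; NaN (flagged
    undefined) otherwise.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = vals.mean()
    if m == 0:
        return float("nan")
    return float(vals.std(ddof=1) / m)


def delta_cv(cv_pre: float, cv_post: float) -> float:
    """Post-independence CV minus pre-independence CV."""
    return cv_post - cv_pre


def cv_table(use_table: pd.DataFrame, value_col: str = "area_km2") -> pd.DataFrame:
    """Per species x class CV of area in each period, and delta CV.

    Groups with fewer than 2 individuals or zero mean get NaN CVs and the
    ``undefined`` flag; delta CV is NaN whenever either period's CV is.
    """
    recs = []
    for (species, code, name), g in use_table.groupby(
        ["species", "class_code", "class_name"], sort=True
    ):
        rec = {"species": species, "class_code": code, "class_name": name}
        for period in ("pre", "post"):
            vals = g.loc[g["period"] == period, value_col].to_numpy(dtype=float)
            if vals.size >= 2 and vals.mean() != 0:
                rec[f"cv_{period}"] = cv(vals)
            else:
                rec[f"cv_{period}"] = float("nan")
        rec["delta_cv"] = delta_cv(rec["cv_pre"], rec["cv_post"])
        rec["undefined"] = bool(np.isnan(rec["delta_cv"]))
        recs.append(rec)
    return pd.DataFrame(recs)


def modal_class_counts(use_table: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of modal-class assignments.

    Each individual x period contributes one count to the class with its
    highest weighted proportion (ties broken by lowest class code), giving
    a (species x period) by class count table — the explicit
    proportions-to-counts rule used before the chi-square test.
    """
    rows = {}
    for (ind, species, period), g in use_table.groupby(
        ["individual_id", "species", "period"], sort=True
    ):
        top = g.sort_values(["weighted_proportion", "class_code"],
                            ascending=[False, True]).iloc[0]
        key = f"{species}:{period}"
        rows.setdefault(key, {})
        rows[key][top["class_name"]] = rows[key].get(top["class_name"], 0) + 1
    return pd.DataFrame(rows).T.fillna(0).astype(int)


def chi_square_independence(
    table: pd.DataFrame | np.ndarray, min_count: float = 2
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a count table.

    Classes (columns) whose total count is below ``min_count`` are removed
    first, as are all-zero rows; no continuity correction is applied.
    Returns (statistic, degrees of freedom, p-value).
    """
    counts = np.asarray(table, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    keep_cols = counts.sum(axis=0) >= min_count
    counts = counts[:, keep_cols]
    keep_rows = counts.sum(axis=1) > 0
    counts = counts[keep_rows]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate table after removing low-count classes")
    stat, p, dof, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)
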