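"""Per-individual trajectory metrics and the pre/post-independence split.

Fledgling tracks are split at the independence day (default 20 days after
leaving the nest, fixes at exactly day 20 belonging to the pre period).
Metrics per individual and period: mean step (path) length, total
displacement (sum of step lengths), net displacement (first fix to last
fix), and home-range size computed elsewhere from that period's own PDF.
Individuals that died on their first day out of the nest are censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import Track


@dataclass
class MovementMetrics:
    individual_id: str
    species: str
    period: str  # "pre" | "post"
    fate: str
    n_fixes: int
    mean_path_length_m: float
    total_displacement_m: float
    net_displacement_m: float
    home_range_km2: float | None = None


def split_periods(track: Track, independence_day: float = 20.0) -> tuple[Track | None, Track | None]:
    """Split a track into pre- (t <= independence day) and post-periods.

    Either period may be None when it holds no fixes (bird died early or
    tracking started late).
    """
    pre = [f for f in track.fixes if f.t <= independence_day]
    post = [f for f in track.fixes if f.t > independence_day]

    def mk(fixes):
        if not fixes:
            return None
        return Track(
            individual_id=track.individual_id,
            species=track.species,
            fixes=fixes,
            fate=track.fate,
            tracking_days=track.tracking_days,
        )

    return mk(pre), mk(post)


def censor_day1_deaths(tracks: list[Track]) -> list[Track]:
    """Drop individuals that died within 1 day of leaving the nest."""
    return [tr for tr in tracks if not (tr.fate == "died" and tr.t[-1] <= 1.0)]


def _xy(fixes) -> np.ndarray:
    if hasattr(fixes, "xy"):
        return fixes.xy
    return np.array([[f.x, f.y] for f in fixes], dtype=float)


def path_length_stats(fixes) -> tuple[np.ndarray, float]:
    """Euclidean step lengths between consecutive fixes and their mean."""
    xy = _xy(fixes)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 fixes for step lengths")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return steps, float(steps.mean())


def total_displacement(fixes) -> float:
    """Sum of step lengths along the track (m)."""
    steps, _ = path_length_stats(fixes)
    return float(steps.sum())


def net_displacement(fixes) -> float:
    """Straight-line distance from the first to the last fix (m)."""
    xy = _xy(fixes)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 fixes for net displacement")
    return float(np.linalg.norm(xy[-1] - xy[0]))


def track_metrics(track: Track, period: str, home_range_km2: float | None = None) -> MovementMetrics:
    """All movement metrics for one (already period-split) track."""
    steps, mean_step = path_length_stats(track)
    return MovementMetrics(
        individual_id=track.individual_id,
        species=track.species,
        period=period,
        fate=track.fate,
        n_fixes=len(track),
        mean_path_length_m=mean_step,
        total_displacement_m=float(steps.sum()),
        net_displacement_m=net_displacement(track),
        home_range_km2=home_range_km2,
    )


METRIC_COLUMNS = [
    "home_range_km2",
    "mean_path_length_m",
    "total_displacement_m",
    "net_displacement_m",
]


def metrics_table(metrics: list[MovementMetrics]) -> pd.DataFrame:
    """Long-format metrics table, one row per individual x period."""
    return pd.DataFrame([m.__dict__ for m in metrics])


def summarize_metrics(table: pd.DataFrame, by=("species", "period")) -> pd.DataFrame:
    """Mean and SE of each movement metric by group (Table-2 style)."""
    recs = []
    for key, g in table.groupby(list(by), sort=True):
        rec = dict(zip(by, key))
        rec["n"] = len(g)
        for col in METRIC_COLUMNS:
            vals = g[col].dropna().to_numpy(dtype=float)
            rec[f"mean_{col}"] = vals.mean() if vals.size else np.nan
            rec[f"se_{col}"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            )
        recs.append(rec)
    return pd.DataFrame(recs)
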