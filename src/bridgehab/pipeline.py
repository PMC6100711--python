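"""End-to-end study pipeline.

Reads daily fixes and a land-cover raster (or takes them in memory), then
for every individual and independence period: estimates the Brownian
motion variance, builds the time-integrated bridge PDF on a grid aligned
to the land-cover lattice, extracts the 95% volume-contour home range,
computes PDF-weighted land-cover composition and movement metrics, and
finally the group summaries (mean/SE tables, CV and delta-CV, chi-square
independence test).  Periods with fewer than 3 fixes cannot support the
variance estimate and are skipped with a logged reason; a manifest
records every individual as processed or skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as bio
from .bbmm import BBParams, default_grid, estimate_motion_variance, time_integrated_pdf
from .grids import LandCoverGrid
from .habitat import drop_unused_classes, summarize, use_rows
from .homerange import volume_contour
from .metrics import (
    censor_day1_deaths,
    metrics_table,
    split_periods,
    summarize_metrics,
    track_metrics,
)
from .stats import chi_square_independence, cv_table, modal_class_counts
from .synthetic import Track

log = logging.getLogger("bridgehab")

MIN_FIXES_PER_PERIOD = 3  # leave-one-out variance MLE needs >= 3


@dataclass
class StudyConfig:
    """Paths and options driving one pipeline run."""

    fixes_csv: str
    landcover_raster: str
    roads_geojson: str | None = None
    out_dir: str = "bridgehab_out"
    delta2: float = 9.0
    quad_points_per_segment: int = 20
    margin_sds: float = 3.0
    level: float = 0.95
    independence_day: float = 20.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.independence_day <= 0:
            raise ValueError("independence_day must be positive")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class StudyResult:
    """In-memory bundle of every pipeline output."""

    use_table: pd.DataFrame
    use_summary: pd.DataFrame
    metrics: pd.DataFrame
    metrics_summary: pd.DataFrame
    cv: pd.DataFrame
    chi_square: dict
    pdfs: dict = field(default_factory=dict)  # (individual_id, period) -> PDFGrid
    home_ranges: dict = field(default_factory=dict)
    sigma_m2: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)  # (individual_id, period, reason)


def analyze_tracks(
    tracks: list[Track],
    landcover: LandCoverGrid,
    delta2: float = 9.0,
    quad_points_per_segment: int = 20,
    margin_sds: float = 3.0,
    level: float = 0.95,
    independence_day: float = 20.0,
) -> StudyResult:
    """Run the full analysis on in-memory tracks and a land-cover raster."""
    tracks = censor_day1_deaths(tracks)
    use_frames, metric_rows, skipped = [], [], []
    pdfs, hrs, sigmas = {}, {}, {}

    for track in tracks:
        for period, sub in zip(("pre", "post"), split_periods(track, independence_day)):
            if sub is None:
                skipped.append((track.individual_id, period, "no fixes in period"))
                continue
            if len(sub) < MIN_FIXES_PER_PERIOD:
                skipped.append(
                    (track.individual_id, period, f"{len(sub)} fixes < {MIN_FIXES_PER_PERIOD}")
                )
                log.info("skipping %s/%s: %d fixes", track.individual_id, period, len(sub))
                continue
            params = estimate_motion_variance(sub, delta2=delta2)
            grid = default_grid(sub, params, margin_sds=margin_sds, align_to=landcover.grid)
            pdf = time_integrated_pdf(sub, params, grid, quad_points_per_segment)
            hr = volume_contour(pdf, level)
            lc_win = landcover.crop(grid)
            use_frames.append(
                use_rows(track.individual_id, track.species, period, track.fate,
                         pdf, hr, lc_win, all_codes=landcover.class_names)
            )
            metric_rows.append(track_metrics(sub, period, home_range_km2=hr.area_km2))
            key = (track.individual_id, period)
            pdfs[key], hrs[key], sigmas[key] = pdf, hr, params.sigma_m2
            log.info("%s/%s: sigma_m2=%.1f m2/day, HR=%.3f km2",
                     track.individual_id, period, params.sigma_m2, hr.area_km2)

    if not use_frames:
        raise ValueError("no individual x period had enough fixes to analyze")
    use_table = drop_unused_classes(pd.concat(use_frames, ignore_index=True))
    mtable = metrics_table(metric_rows)

    counts = modal_class_counts(use_table)
    try:
        stat, dof, p = chi_square_independence(counts)
        chi_report = {"statistic": stat, "df": dof, "p_value": p,
                      "table": counts.to_dict()}
    except ValueError as exc:
        chi_report = {"statistic": None, "df": None, "p_value": None,
                      "reason": str(exc), "table": counts.to_dict()}

    return StudyResult(
        use_table=use_table,
        use_summary=summarize(use_table),
        metrics=mtable,
        metrics_summary=summarize_metrics(mtable),
        cv=cv_table(use_table),
        chi_square=chi_report,
        pdfs=pdfs,
        home_ranges=hrs,
        sigma_m2=sigmas,
        skipped=skipped,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig) -> StudyResult:
    """File-driven pipeline run: read inputs, analyze, write all outputs.

    Outputs under ``config.out_dir``: per individual x period PDF rasters
    (.asc), long and summary CSV tables, the CV table, the chi-square
    report, and ``manifest.json`` listing every output file with its
    SHA-256 checksum plus every skipped individual x period with reason.
    """
    logging.basicConfig(level=config.log_level)
    fixes_path = Path(config.fixes_csv)
    lc_path = Path(config.landcover_raster)
    for p in (fixes_path, lc_path):
        if not p.exists():
            raise FileNotFoundError(f"input not found: {p}")

    tracks = bio.read_fixes(fixes_path)
    landcover = bio.read_landcover(lc_path)
    if config.roads_geojson:
        from .synthetic import rasterize_roads

        roads = bio.read_roads(config.roads_geojson)
        landcover = rasterize_roads(landcover, roads)

    xy_ok = landcover.grid.contains_point(
        *(pd.concat([pd.DataFrame(t.xy, columns=["x", "y"]) for t in tracks])
          .to_numpy().T)
    )
    if not xy_ok.all():
        raise ValueError(
            "some fixes fall outside the land-cover raster: check that fixes "
            "and raster share one projected coordinate system"
        )

    result = analyze_tracks(
        tracks,
        landcover,
        delta2=config.delta2,
        quad_points_per_segment=config.quad_points_per_segment,
        margin_sds=config.margin_sds,
        level=config.level,
        independence_day=config.independence_day,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        files[name] = _sha256(p)

    save_csv(result.use_table, "habitat_use_long.csv")
    save_csv(result.use_summary, "habitat_use_summary.csv")
    save_csv(result.metrics, "movement_metrics.csv")
    save_csv(result.metrics_summary, "movement_metrics_summary.csv")
    save_csv(result.cv, "cv_delta_cv.csv")

    (out / "chi_square.json").write_text(json.dumps(result.chi_square, indent=1))
    files["chi_square.json"] = _sha256(out / "chi_square.json")

    for (ind, period), pdf in result.pdfs.items():
        name = f"pdf_{ind}_{period}.asc"
        bio.write_pdf(pdf, out / name)
        files[name] = _sha256(out / name)

    manifest = {
        "config": {k: v for k, v in config.__dict__.items()},
        "processed": sorted(f"{i}:{p}" for i, p in result.pdfs),
        "skipped": [
            {"individual_id": i, "period": p, "reason": r} for i, p, r in result.skipped
        ],
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
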