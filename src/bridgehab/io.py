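"""File formats: fixes CSV, ESRI ASCII rasters, GeoJSON road lines.

Rasters use the plain-text ESRI ASCII grid format (.asc) so categorical
land cover and float PDF surfaces share one code path; fixes travel as a
long CSV with one row per daily location; road vectors are GeoJSON
LineString/MultiLineString features in the same projected coordinate
system as the rasters.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping, shape

from .grids import GridDef, LandCoverGrid, PDFGrid
from .synthetic import NLCD_CLASS_NAMES, Fix, Track

FIXES_COLUMNS = ["individual_id", "species", "t_days", "x_m", "y_m", "loc_error_sd_m", "fate"]


# ---------------------------------------------------------------- fixes CSV

def write_fixes(tracks: list[Track], path) -> None:
    rows = [
        {
            "individual_id": tr.individual_id,
            "species": tr.species,
            "t_days": f.t,
            "x_m": f.x,
            "y_m": f.y,
            "loc_error_sd_m": f.loc_error_sd,
            "fate": tr.fate,
        }
        for tr in tracks
        for f in tr.fixes
    ]
    pd.DataFrame(rows, columns=FIXES_COLUMNS).to_csv(path, index=False)


def read_fixes(path) -> list[Track]:
    """Read a fixes CSV into per-individual Tracks.

    Validates columns, coordinates and time ordering; duplicated
    (individual, t) rows are an error naming the offending row, and
    out-of-order rows are sorted with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in FIXES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[df[["x_m", "y_m", "t_days"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: NaN coordinates/times at rows {list(bad[:5])}")
    dup = df.duplicated(subset=["individual_id", "t_days"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValueError(f"{path}: duplicated (individual_id, t_days) at row {row}")

    tracks = []
    for ind, g in df.groupby("individual_id", sort=True):
        if not g["t_days"].is_monotonic_increasing:
            warnings.warn(f"fixes for {ind} out of order; sorting by time")
            g = g.sort_values("t_days")
        fixes = [
            Fix(t=float(r.t_days), x=float(r.x_m), y=float(r.y_m),
                loc_error_sd=float(r.loc_error_sd_m))
            for r in g.itertuples()
        ]
        tracks.append(
            Track(
                individual_id=str(ind),
                species=str(g["species"].iloc[0]),
                fixes=fixes,
                fate=str(g["fate"].iloc[0]),
            )
        )
    return tracks


# ---------------------------------------------------------- ESRI ASCII grid

def write_ascii_grid(grid: GridDef, values: np.ndarray, path, nodata: float = -9999) -> None:
    values = np.asarray(values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_min!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    fmt = "%d" if np.issubdtype(values.dtype, np.integer) else "%.17g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path) -> tuple[GridDef, np.ndarray]:
    head = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_cols, n_rows = int(head["ncols"]), int(head["nrows"])
    cs = head["cellsize"]
    grid = GridDef(
        x_origin=head["xllcorner"],
        y_origin=head["yllcorner"] + n_rows * cs,
        cell_size=cs,
        n_cols=n_cols,
        n_rows=n_rows,
    )
    return grid, values.reshape(n_rows, n_cols)


def write_landcover(lc: LandCoverGrid, path) -> None:
    """Categorical raster as .asc plus a sidecar JSON class legend."""
    write_ascii_grid(lc.grid, lc.class_code.astype(np.int64), path)
    legend = Path(path).with_suffix(".classes.json")
    legend.write_text(json.dumps({str(k): v for k, v in lc.class_names.items()}, indent=1))


def read_landcover(path, class_names: dict[int, str] | None = None) -> LandCoverGrid:
    grid, values = read_ascii_grid(path)
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: categorical raster must hold integer codes")
    if class_names is None:
        legend = Path(path).with_suffix(".classes.json")
        if legend.exists():
            class_names = {int(k): v for k, v in json.loads(legend.read_text()).items()}
        else:
            class_names = dict(NLCD_CLASS_NAMES)
    return LandCoverGrid(grid, values.astype(np.int64), class_names)


def write_pdf(pdf: PDFGrid, path) -> None:
    write_ascii_grid(pdf.grid, pdf.density, path)


def read_pdf(path) -> PDFGrid:
    grid, values = read_ascii_grid(path)
    return PDFGrid(grid, values)


def pdf_to_csv(pdf: PDFGrid, path) -> None:
    """Flat (row, col, density, mass) dump for inspection and tests."""
    r, c = np.indices(pdf.density.shape)
    pd.DataFrame(
        {
            "row": r.ravel(),
            "col": c.ravel(),
            "density": pdf.density.ravel(),
            "mass": pdf.cell_mass.ravel(),
        }
    ).to_csv(path, index=False)


# -------------------------------------------------------------- roads (GeoJSON)

def write_roads(roads: list[LineString], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(line)}
            for line in roads
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_roads(path) -> list[LineString]:
    fc = json.loads(Path(path).read_text())
    lines: list[LineString] = []
    for feat in fc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "LineString":
            lines.append(geom)
        elif geom.geom_type == "MultiLineString":
            lines.extend(geom.geoms)
        else:
            raise ValueError(f"{path}: unsupported road geometry {geom.geom_type}")
    return lines
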