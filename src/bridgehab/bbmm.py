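"""Brownian bridge movement model: motion variance and utilization PDF.

Between two consecutive fixes the animal's position at an interior time is
modelled as an isotropic bivariate normal centered on the linear
interpolant of the fixes, with variance

    sigma^2(t) = T * a * (1 - a) * sigma_m^2 + (1 - a)^2 * delta^2 + a^2 * delta^2

where T is the segment duration, a the elapsed fraction, sigma_m^2 the
Brownian motion variance (m^2/day) and delta^2 the per-fix location-error
variance (m^2).  The utilization distribution is the duration-weighted
time average of these bridge densities over all segments, evaluated per
raster cell by fixed-order Gauss-Legendre quadrature in a.

The motion variance is estimated by the leave-one-out maximum-likelihood
scheme standard for Brownian bridges: every odd-indexed fix is dropped in
turn, modelled as a bridge observation between its two neighbours, and
sigma_m^2 maximizes the product of the resulting bivariate normal
densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .grids import GridDef, PDFGrid

SIGMA_M2_BOUNDS = (1e-6, 1e8)  # m^2/day


@dataclass(frozen=True)
class BBParams:
    """Brownian motion variance and location-error variance."""

    sigma_m2: float  # m^2/day
    delta2: float = 9.0  # m^2; GPS accuracy of +/- 3 m

    def __post_init__(self) -> None:
        if self.sigma_m2 <= 0:
            raise ValueError("sigma_m2 must be positive")
        if self.delta2 < 0:
            raise ValueError("delta2 must be non-negative")


def _as_txy(track_fixes) -> tuple[np.ndarray, np.ndarray]:
    """Accept a Track or an iterable of Fix; return (t, xy) arrays."""
    if hasattr(track_fixes, "fixes"):
        track_fixes = track_fixes.fixes
    t = np.array([f.t for f in track_fixes], dtype=float)
    xy = np.array([[f.x, f.y] for f in track_fixes], dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("fix times must be strictly increasing")
    return t, xy


def bridge_variance(T: float, alpha, sigma_m2: float, delta2: float):
    """Per-axis positional variance of the bridge at elapsed fraction alpha."""
    alpha = np.asarray(alpha, dtype=float)
    return T * alpha * (1 - alpha) * sigma_m2 + ((1 - alpha) ** 2 + alpha**2) * delta2


def bridge_density(z, t: float, a, b, params: BBParams) -> float:
    """Bridge PDF (m^-2) at point ``z`` and time ``t`` between fixes a, b."""
    if a.t >= b.t:
        raise ValueError("segment requires a.t < b.t")
    if not a.t <= t <= b.t:
        raise ValueError("t outside the segment [a.t, b.t]")
    T = b.t - a.t
    alpha = (t - a.t) / T
    var = float(bridge_variance(T, alpha, params.sigma_m2, params.delta2))
    if var <= 0:
        raise ValueError("degenerate bridge: zero variance (need delta2 > 0 or interior t)")
    mx = a.x + alpha * (b.x - a.x)
    my = a.y + alpha * (b.y - a.y)
    z = np.asarray(z, dtype=float)
    d2 = (z[..., 0] - mx) ** 2 + (z[..., 1] - my) ** 2
    return np.exp(-d2 / (2 * var)) / (2 * np.pi * var)


def estimate_motion_variance(track_fixes, delta2: float = 9.0) -> BBParams:
    """Leave-one-out ML estimate of the Brownian motion variance.

    Each odd-indexed fix is treated as an observation of the bridge between
    its two neighbours; the likelihood is the product of isotropic
    bivariate normal densities and is maximized over sigma_m^2 within
    ``SIGMA_M2_BOUNDS`` (search on a log scale; deterministic).
    """
    t, xy = _as_txy(track_fixes)
    if t.size < 3:
        raise ValueError("motion-variance estimation needs at least 3 fixes")

    i = np.arange(1, t.size - 1, 2)
    ta, tb, ti = t[i - 1], t[i + 1], t[i]
    T = tb - ta
    alpha = (ti - ta) / T
    mu = xy[i - 1] + alpha[:, None] * (xy[i + 1] - xy[i - 1])
    r2 = np.sum((xy[i] - mu) ** 2, axis=1)

    if np.all(r2 == 0) and delta2 == 0:
        warnings.warn("all leave-one-out residuals are zero; returning lower bound")
        return BBParams(SIGMA_M2_BOUNDS[0], delta2)

    def nll(log_s: float) -> float:
        var = bridge_variance(T, alpha, np.exp(log_s), delta2)
        return float(np.sum(np.log(2 * np.pi * var) + r2 / (2 * var)))

    lo, hi = np.log(SIGMA_M2_BOUNDS)
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    sigma_m2 = float(np.exp(res.x))
    # the bounded optimizer never lands exactly on a bound; snap if pinned
    if nll(lo) <= res.fun:
        sigma_m2 = SIGMA_M2_BOUNDS[0]
        warnings.warn("sigma_m2 pinned at lower bound (residuals ~ location error)")
    return BBParams(sigma_m2=sigma_m2, delta2=delta2)


def max_segment_sd(track_fixes, params: BBParams) -> float:
    """Largest positional sd reached along any segment of the track."""
    t, _ = _as_txy(track_fixes)
    if t.size < 2:
        return float(np.sqrt(params.delta2))
    T = np.diff(t)
    mid = T * params.sigma_m2 / 4 + params.delta2 / 2
    return float(np.sqrt(max(mid.max(), params.delta2)))


def default_grid(
    track_fixes,
    params: BBParams,
    cell_size: float = 30.0,
    margin_sds: float = 3.0,
    align_to: GridDef | None = None,
) -> GridDef:
    """Grid covering the fixes with a margin of ``margin_sds`` bridge sds.

    With ``align_to`` the grid is snapped to (and clipped within) an
    existing raster lattice so cell centers coincide, e.g. with a
    land-cover raster.
    """
    t, xy = _as_txy(track_fixes)
    margin = margin_sds * max_segment_sd(track_fixes, params) + cell_size
    x0, y1 = xy[:, 0].min() - margin, xy[:, 1].max() + margin
    x1, y0 = xy[:, 0].max() + margin, xy[:, 1].min() - margin
    if align_to is not None:
        cs = align_to.cell_size
        x0 = align_to.x_origin + np.floor((x0 - align_to.x_origin) / cs) * cs
        y1 = align_to.y_origin - np.floor((align_to.y_origin - y1) / cs) * cs
        x0 = max(x0, align_to.x_origin)
        y1 = min(y1, align_to.y_origin)
        x1 = min(x1, align_to.x_max)
        y0 = max(y0, align_to.y_min)
        cell_size = cs
    n_cols = max(1, int(np.ceil((x1 - x0) / cell_size - 1e-9)))
    n_rows = max(1, int(np.ceil((y1 - y0) / cell_size - 1e-9)))
    return GridDef(x_origin=float(x0), y_origin=float(y1), cell_size=cell_size,
                   n_cols=n_cols, n_rows=n_rows)


def time_integrated_pdf(
    track_fixes,
    params: BBParams,
    grid: GridDef,
    quad_points_per_segment: int = 20,
    mass_warn_threshold: float = 0.99,
) -> PDFGrid:
    """Time-averaged bridge density over all segments, on a raster.

    h(cell) = (1/T_total) * sum_i T_i * int_0^1 phi(center; mu_i(a), var_i(a)) da,
    with the integral evaluated by Gauss-Legendre quadrature of order
    ``quad_points_per_segment``.  Cell mass is center density times cell
    area; the result is renormalized to unit total mass, warning when the
    pre-normalization mass falls below ``mass_warn_threshold`` (grid too
    tight).
    """
    t, xy = _as_txy(track_fixes)
    if t.size < 2:
        raise ValueError("time-integrated PDF needs at least 2 fixes")
    inside = grid.contains_point(xy[:, 0], xy[:, 1])
    if not np.all(inside):
        raise ValueError("grid does not cover all fixes")

    nodes, wts = np.polynomial.legendre.leggauss(quad_points_per_segment)
    alpha = (nodes + 1) / 2  # map [-1,1] -> [0,1]
    wts = wts / 2

    xc = grid.x_centers()
    yc = grid.y_centers()
    T_total = t[-1] - t[0]
    dens = np.zeros((grid.n_rows, grid.n_cols))
    for i in range(t.size - 1):
        T = t[i + 1] - t[i]
        var = bridge_variance(T, alpha, params.sigma_m2, params.delta2)
        if np.any(var <= 0):
            raise ValueError("degenerate bridge variance; require delta2 > 0")
        mux = xy[i, 0] + alpha * (xy[i + 1, 0] - xy[i, 0])
        muy = xy[i, 1] + alpha * (xy[i + 1, 1] - xy[i, 1])
        inv2v = 1.0 / (2 * var)
        gx = np.exp(-((xc[None, :] - mux[:, None]) ** 2) * inv2v[:, None])
        gy = np.exp(-((yc[None, :] - muy[:, None]) ** 2) * inv2v[:, None])
        scale = wts * T / (2 * np.pi * var)
        dens += np.einsum("q,qr,qc->rc", scale, gy, gx)
    dens /= T_total

    pdf = PDFGrid(grid, dens)
    pre = pdf.total_mass
    if pre < mass_warn_threshold:
        warnings.warn(
            f"pre-normalization PDF mass {pre:.4f} < "
            f"{mass_warn_threshold}; grid margin may be too small"
        )
    out = pdf.normalized()
    out.prenorm_mass = pre
    return out


def sample_utilization(
    track_fixes, params: BBParams, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo positions from the time-integrated bridge process.

    Draws a segment with probability proportional to its duration, a time
    uniformly within it, then a position from the bridge normal — the
    independent sampling route used to validate the quadrature PDF.
    """
    t, xy = _as_txy(track_fixes)
    if t.size < 2:
        raise ValueError("need at least 2 fixes")
    T = np.diff(t)
    seg = rng.choice(T.size, size=n_samples, p=T / T.sum())
    alpha = rng.uniform(size=n_samples)
    var = bridge_variance(T[seg], alpha, params.sigma_m2, params.delta2)
    mu = xy[seg] + alpha[:, None] * (xy[seg + 1] - xy[seg])
    return mu + rng.normal(size=(n_samples, 2)) * np.sqrt(var)[:, None]
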