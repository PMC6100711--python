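"""Brownian bridge density, variance estimation, time-integrated PDF."""

import numpy as np
import pytest

import bridgehab as bh
from bridgehab.bbmm import SIGMA_M2_BOUNDS, bridge_variance, max_segment_sd
from bridgehab.grids import GridDef


def fix(t, x, y, sd=3.0):
    return bh.Fix(t=float(t), x=float(x), y=float(y), loc_error_sd=sd)


class TestBridgeDensity:
    def test_midpoint_closed_form(self):
        # a = b = origin, T = 1, sigma_m2 = 1, delta2 = 0:
        # var at midpoint = 0.25, peak density = 1/(2 pi 0.25)
        a, b = fix(0, 0, 0), fix(1, 0, 0)
        p = bh.BBParams(sigma_m2=1.0, delta2=0.0)
        d = bh.bridge_density(np.array([0.0, 0.0]), 0.5, a, b, p)
        assert d == pytest.approx(1 / (2 * np.pi * 0.25), rel=1e-12)

    def test_endpoint_reduces_to_location_error(self):
        a, b = fix(0, 5, -2), fix(1, 50, 40)
        p = bh.BBParams(sigma_m2=3.0, delta2=1.0)
        d = bh.bridge_density(np.array([5.0, -2.0]), 0.0, a, b, p)
        assert d == pytest.approx(1 / (2 * np.pi), rel=1e-12)

    def test_time_outside_segment_rejected(self):
        a, b = fix(0, 0, 0), fix(1, 1, 1)
        p = bh.BBParams(sigma_m2=1.0)
        with pytest.raises(ValueError, match="outside"):
            bh.bridge_density(np.zeros(2), 1.5, a, b, p)

    def test_degenerate_variance_rejected(self):
        a, b = fix(0, 0, 0), fix(1, 1, 1)
        p = bh.BBParams(sigma_m2=1.0, delta2=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            bh.bridge_density(np.zeros(2), 0.0, a, b, p)

    def test_monte_carlo_histogram_matches_density(self, rng):
        # simulate bridge positions at a fixed interior time; the binned
        # frequencies must match the bivariate normal law with the bridge
        # mean and variance (cell-integrated, so no discretization slack)
        from scipy.stats import norm

        p = bh.BBParams(sigma_m2=900.0, delta2=9.0)
        t, T = 0.7, 2.0
        alpha = t / T
        var = float(bridge_variance(T, alpha, p.sigma_m2, p.delta2))
        mu = np.array([alpha * 60, alpha * 20])
        sd = np.sqrt(var)
        z = mu + rng.normal(size=(2_000_000, 2)) * sd
        cell = 10.0
        edges_x = mu[0] + np.arange(-8, 9) * cell
        edges_y = mu[1] + np.arange(-8, 9) * cell
        hist, _, _ = np.histogram2d(z[:, 0], z[:, 1], bins=(edges_x, edges_y))
        hist /= z.shape[0]
        px = np.diff(norm.cdf(edges_x, mu[0], sd))
        py = np.diff(norm.cdf(edges_y, mu[1], sd))
        prob = np.outer(px, py)
        sel = prob > 0.1 * prob.max()
        rel = np.abs(hist[sel] - prob[sel]) / prob[sel]
        assert rel.max() < 0.05


class TestEstimateMotionVariance:
    def test_collinear_fixes_hit_lower_bound(self):
        fixes = [fix(t, 10.0 * t, 0.0, sd=0.0) for t in range(6)]
        with pytest.warns(UserWarning):
            p = bh.estimate_motion_variance(fixes, delta2=0.0)
        assert p.sigma_m2 == SIGMA_M2_BOUNDS[0]

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError, match="3 fixes"):
            bh.estimate_motion_variance([fix(0, 0, 0), fix(1, 1, 1)])

    def test_parameter_recovery(self, brownian_track_factory):
        # median over replicate Brownian tracks within +/-15% of truth,
        # every single estimate within a generous bracket
        est = []
        for rep in range(20):
            tr = brownian_track_factory(400.0, 500, seed=100 + rep, loc_error_sd=3.0)
            est.append(bh.estimate_motion_variance(tr, delta2=9.0).sigma_m2)
        est = np.array(est)
        assert np.all((est > 300) & (est < 520))
        assert abs(np.median(est) - 400) / 400 < 0.15

    def test_scale_equivariance(self, brownian_track_factory):
        tr = brownian_track_factory(200.0, 200, seed=7, loc_error_sd=0.0)
        doubled = bh.Track(
            individual_id="x2",
            species="sim",
            fixes=[bh.Fix(t=f.t, x=2 * f.x, y=2 * f.y, loc_error_sd=0.0) for f in tr.fixes],
        )
        s1 = bh.estimate_motion_variance(tr, delta2=0.0).sigma_m2
        s2 = bh.estimate_motion_variance(doubled, delta2=0.0).sigma_m2
        assert s2 == pytest.approx(4 * s1, rel=1e-4)


class TestTimeIntegratedPDF:
    def grid_for(self, track, params, cell=5.0):
        return bh.default_grid(track, params, cell_size=cell)

    def test_stationary_track_matches_analytic_mixture(self):
        # two coincident fixes with negligible motion variance: the PDF is
        # the time average of isotropic Gaussians whose variance is the
        # location-error interpolation ((1-a)^2 + a^2) * delta2; compare
        # with that mixture built directly by dense trapezoid quadrature
        fixes = [fix(0, 50, 50), fix(1, 50, 50)]
        p = bh.BBParams(sigma_m2=1e-6, delta2=9.0)
        grid = GridDef(20.0, 80.0, 1.0, 60, 60)
        pdf = bh.time_integrated_pdf(fixes, p, grid)
        xc, yc = grid.x_centers(), grid.y_centers()
        alphas = np.linspace(0, 1, 4001)
        var = (1 - alphas) ** 2 * 9.0 + alphas**2 * 9.0
        d2 = (xc[None, :] - 50) ** 2 + (yc[:, None] - 50) ** 2
        ref = np.trapezoid(
            np.exp(-d2[None] / (2 * var[:, None, None])) / (2 * np.pi * var[:, None, None]),
            alphas, axis=0,
        )
        ref = ref / (ref.sum() * grid.cell_area)
        q = pdf.cell_mass.ravel()
        r = (ref * grid.cell_area).ravel()
        sel = q > 1e-15
        kl = float(np.sum(q[sel] * np.log(q[sel] / r[sel])))
        assert kl < 1e-3

    def test_normalization_contract(self, brownian_track_factory):
        tr = brownian_track_factory(900.0, 12, seed=3, loc_error_sd=3.0)
        p = bh.estimate_motion_variance(tr)
        pdf = bh.time_integrated_pdf(tr, p, self.grid_for(tr, p))
        assert pdf.total_mass == pytest.approx(1.0, abs=1e-3)

    def test_grid_must_cover_fixes(self, brownian_track_factory):
        tr = brownian_track_factory(900.0, 10, seed=4)
        p = bh.BBParams(sigma_m2=900.0)
        tiny = GridDef(0.0, 10.0, 5.0, 2, 2)
        with pytest.raises(ValueError, match="cover"):
            bh.time_integrated_pdf(tr, p, tiny)

    def test_time_reversal_symmetry(self, brownian_track_factory):
        tr = brownian_track_factory(900.0, 8, seed=5, loc_error_sd=3.0)
        p = bh.BBParams(sigma_m2=700.0)
        grid = self.grid_for(tr, p)
        fwd = bh.time_integrated_pdf(tr, p, grid)
        t_max = tr.t[-1]
        rev = bh.Track(
            individual_id="rev",
            species="sim",
            fixes=[
                bh.Fix(t=float(t_max - f.t), x=f.x, y=f.y, loc_error_sd=f.loc_error_sd)
                for f in reversed(tr.fixes)
            ],
        )
        bwd = bh.time_integrated_pdf(rev, p, grid)
        np.testing.assert_allclose(fwd.density, bwd.density, rtol=1e-10, atol=1e-18)

    def test_translation_equivariance(self, brownian_track_factory):
        tr = brownian_track_factory(900.0, 8, seed=6, loc_error_sd=3.0)
        p = bh.BBParams(sigma_m2=700.0)
        grid = self.grid_for(tr, p)
        base = bh.time_integrated_pdf(tr, p, grid)
        dx, dy = 1234.5, -987.25
        moved = bh.Track(
            individual_id="mv",
            species="sim",
            fixes=[bh.Fix(t=f.t, x=f.x + dx, y=f.y + dy, loc_error_sd=f.loc_error_sd)
                   for f in tr.fixes],
        )
        grid2 = GridDef(grid.x_origin + dx, grid.y_origin + dy, grid.cell_size,
                        grid.n_cols, grid.n_rows)
        shifted = bh.time_integrated_pdf(moved, p, grid2)
        np.testing.assert_allclose(base.cell_mass, shifted.cell_mass, rtol=1e-9,
                                   atol=1e-18)

    def test_quadrature_convergence(self, brownian_track_factory):
        tr = brownian_track_factory(900.0, 8, seed=8, loc_error_sd=10.0)
        p = bh.BBParams(sigma_m2=900.0, delta2=100.0)
        grid = self.grid_for(tr, p)
        a = bh.time_integrated_pdf(tr, p, grid, quad_points_per_segment=20)
        b = bh.time_integrated_pdf(tr, p, grid, quad_points_per_segment=40)
        assert np.abs(a.cell_mass - b.cell_mass).max() < 1e-4

    @pytest.mark.parametrize("n_fixes", [2, 5])
    def test_monte_carlo_oracle(self, n_fixes, rng):
        # quadrature PDF vs a large utilization sample binned on the grid
        pos = np.cumsum(rng.normal(0, 30, size=(n_fixes, 2)), axis=0)
        fixes = [fix(i, pos[i, 0], pos[i, 1], sd=10.0) for i in range(n_fixes)]
        tr = bh.Track(individual_id="mc", species="sim", fixes=fixes)
        p = bh.BBParams(sigma_m2=900.0, delta2=100.0)
        grid = bh.default_grid(tr, p, cell_size=5.0, margin_sds=4.0)
        pdf = bh.time_integrated_pdf(tr, p, grid, quad_points_per_segment=40)
        n = 1_000_000
        z = bh.sample_utilization(tr, p, n, rng)
        xe = grid.x_origin + np.arange(grid.n_cols + 1) * grid.cell_size
        ye_desc = grid.y_origin - np.arange(grid.n_rows + 1) * grid.cell_size
        hist, _, _ = np.histogram2d(z[:, 1], z[:, 0], bins=(ye_desc[::-1], xe))
        mc_mass = hist[::-1, :] / n
        se = np.sqrt(mc_mass * (1 - mc_mass) / n)
        err = np.abs(pdf.cell_mass - mc_mass)
        assert np.all(err < 3 * se + 1e-4)


class TestGridHelpers:
    def test_margin_covers_bridge_spread(self, brownian_track_factory):
        tr = brownian_track_factory(2000.0, 10, seed=9)
        p = bh.BBParams(sigma_m2=2000.0)
        grid = bh.default_grid(tr, p, cell_size=30.0)
        sd = max_segment_sd(tr, p)
        assert grid.x_origin <= tr.xy[:, 0].min() - 3 * sd
        assert grid.x_max >= tr.xy[:, 0].max() + 3 * sd

    def test_aligned_grid_snaps_to_parent_lattice(self, small_landscape,
                                                  brownian_track_factory):
        parent = small_landscape.grid
        tr = brownian_track_factory(500.0, 8, seed=10, start=(1500.0, 1500.0))
        p = bh.BBParams(sigma_m2=500.0)
        grid = bh.default_grid(tr, p, align_to=parent)
        r0, c0 = parent.window_of(grid)  # raises if misaligned
        assert grid.cell_size == parent.cell_size
        assert r0 >= 0 and c0 >= 0
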