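import numpy as np
import pytest

import bridgehab as bh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return bh.LandscapeSpec(
        width_cells=100,
        height_cells=100,
        n_forest_patches=4,
        patch_area_range=(5.0, 40.0),
        road_spacing=900.0,
        seed=42,
    )


@pytest.fixture
def small_landscape(small_spec):
    return bh.generate_landscape(small_spec)


def brownian_track(
    sigma_m2: float,
    n_days: int,
    seed: int,
    loc_error_sd: float = 0.0,
    start=(0.0, 0.0),
    individual_id: str = "bm-0",
) -> bh.Track:
    """Pure Brownian-motion daily fixes (no landscape, no habitat bias)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma_m2), size=(n_days, 2))
    pos = np.asarray(start) + np.cumsum(steps, axis=0)
    if loc_error_sd > 0:
        pos = pos + rng.normal(0.0, loc_error_sd, size=pos.shape)
    fixes = [
        bh.Fix(t=float(d + 1), x=float(x), y=float(y), loc_error_sd=loc_error_sd)
        for d, (x, y) in enumerate(pos)
    ]
    return bh.Track(individual_id=individual_id, species="sim", fixes=fixes)


@pytest.fixture
def brownian_track_factory():
    return brownian_track
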