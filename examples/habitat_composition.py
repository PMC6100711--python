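"""PDF-weighted land-cover composition of one home range.

Builds a home range as in home_range_from_track.py, then overlays it on
the land-cover raster: each class's weighted proportion is the share of
utilization probability falling on cells of that class inside the 95%
contour (they sum to 1), and multiplying by the home-range area gives
km^2 per class.
"""

import numpy as np

import bridgehab as bh

landscape = bh.generate_landscape(bh.LandscapeSpec(seed=4))
_, specialist = bh.default_study_profiles()
start = tuple(np.argwhere(np.isin(landscape.class_code, list(bh.FOREST_CODES)))[200])
track = bh.simulate_track(specialist, landscape, start, n_days=30, seed=11)

params = bh.estimate_motion_variance(track)
grid = bh.default_grid(track, params, align_to=landscape.grid)
pdf = bh.time_integrated_pdf(track, params, grid)
hr = bh.volume_contour(pdf)

props = bh.weighted_proportions(pdf, hr, landscape.crop(grid))
areas = bh.class_areas(props, hr)

print(f"home range: {hr.area_km2:.4f} km^2; composition (proportion, km^2):")
for code in sorted(props, key=props.get, reverse=True):
    name = landscape.class_names.get(code, str(code))
    print(f"  {name:28s} {props[code]:6.3f}  {areas[code]:8.5f}")
print(f"  {'sum':28s} {sum(props.values()):6.3f}  {sum(areas.values()):8.5f}")
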