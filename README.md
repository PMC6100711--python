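# bridgehab

Brownian bridge home ranges and land-cover habitat use for daily-fix
wildlife telemetry.

Movement ecologists tracking juvenile songbirds (or any animal located
roughly once per day) need to turn sparse fix sequences into space-use
estimates and habitat-composition summaries. `bridgehab` implements that
pipeline end to end:

- **Brownian bridge movement model (BBMM).** Between consecutive fixes
  `(t_a, z_a)` and `(t_b, z_b)` the position at time `t` is isotropic
  bivariate normal around the linear interpolant with variance
  `σ²(t) = T α(1−α) σ_m² + ((1−α)² + α²) δ²`, where `T = t_b − t_a`,
  `α = (t − t_a)/T`, `σ_m²` is the Brownian motion variance (m²/day) and
  `δ²` the per-fix location-error variance (GPS ± 3 m ⇒ δ² = 9 m²). The
  utilization distribution (UD) is the duration-weighted time average of
  these bridge densities over all segments, evaluated on a raster by
  Gauss–Legendre quadrature. `σ_m²` is estimated per individual × period
  by leave-one-out maximum likelihood.
- **95% volume-contour home range:** the smallest cell set whose center
  densities exceed a common threshold while holding 95% of the UD volume.
- **Habitat use:** UD-weighted relative proportions of each land-cover
  class inside the home range (NLCD-style 30 m raster with rasterized
  roads embedded as an extra class), converted to km² per class.
- **Movement metrics:** mean step (path) length, total and net
  displacement, home-range size — per individual, split into
  pre-independence (≤ 20 days after fledging) and post-independence
  (> 20 days) periods.
- **Group statistics:** mean/SE tables, coefficient of variation (CV) of
  per-class area across individuals, ΔCV = CV_post − CV_pre, and a
  chi-square independence test on class-use counts.
- **Synthetic data:** a landscape generator (forest fragments of 5–163 ha
  in a developed matrix with a road grid) and a habitat-biased random
  walk (forest affinity, road avoidance, daily Bernoulli survival,
  reflecting boundaries) so the whole pipeline can be validated against
  known ground truth.

## Worked example

`examples/full_study.py` simulates a generalist and a forest-specialist
cohort (20 birds each, daily fixes for 2–88 days, GPS error ± 3 m) on one
fragmented landscape and runs every stage. It prints:

```
movement metrics (mean) by species x period:
   species period  n  mean_home_range_km2  mean_mean_path_length_m  mean_net_displacement_m
generalist   post 14                0.381                  134.550                  845.890
generalist    pre 20                0.060                   68.297                  278.187
specialist   post 11                0.302                  121.362                  542.192
specialist    pre 19                0.045                   60.015                  210.804

mean weighted forest proportion per home range:
generalist   0.474
specialist   0.874

chi-square on modal-class counts: X2=27.04, df=9, p=1.38e-03
```

Reading this: home ranges, step lengths and displacements are all several
times larger after independence (the simulated post-independence motion
variance is 4× the pre value), and the specialist — whose walk prefers
forest cells 5:1 — concentrates ~87% of its utilization in forest versus
~47% for the indifferent generalist, the contrast the habitat-use
weighting is designed to expose. The other examples show a single
individual's home range, its land-cover composition, and the CV/ΔCV
homogenization summary; the `bridgehab simulate | run | summarize` CLI
drives the same pipeline from files (fixes CSV, ESRI ASCII land-cover
raster, GeoJSON roads, YAML config).

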