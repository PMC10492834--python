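# Demo pipeline configuration for `borealcarbon run-all`.
#
# The generator block controls the synthetic catchment; thresholds below it
# control the downstream analysis. Any field omitted falls back to the
# package default (the full-survey conditions: 430 plots, 350 m spacing,
# 2 m wetness cells). This demo uses a small catchment so a complete run
# finishes in a couple of seconds.
generator:
  n_plots: 100            # survey plots on a square grid
  grid_spacing: 80.0      # m between adjacent plot centres
  plot_radius: 10.0       # m
  moisture_class_props: [0.07, 0.73, 0.11, 0.07, 0.02]  # dry..wet
  peat_target_fraction: 0.11
  soc_curve: [4.23, 8.51, 3.35]   # log(SOC) = b0 + b1*x + b2*x^2
  soc_log_sd: 0.24                # residual sd on the log scale
  tree_curve: [44.0, 170.0, -200.0]  # tree C quadratic, Mg C/ha
  tree_sd: 18.0                   # residual sd, Mg C/ha
  als_points_per_m2: 20.0
  correlation_length: 30.0        # m, wetness field smoothness
  wetness_cell_size: 2.0          # m
  seed: 7
canopy_threshold: 1.5     # m, vegetation-ratio cutoff
exclusion_limit: 5.0      # m, |Lorey - P95| plot exclusion rule
als_exponent: 1.2         # fixed exponent of the (P95*VR) term
soc_degree: 2
soc_log_scale: true
seed: 7
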