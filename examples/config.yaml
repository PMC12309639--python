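# Full pipeline configuration with every default spelled out.
# Any key may be omitted; omitted keys take the values shown here.

seed: 1
out_dir: artifacts

landscape:
  nrows: 64
  ncols: 64
  cell_size_m: 1000.0        # planning units are one cell = 1 x 1 km
  n_islands: 1
  land_fraction: 0.22
  relief_m: 700.0
  storm_precip_mm: 300.0     # extreme cyclone event rainfall depth
  n_towns: 5
  total_population: 60000
  cost_radius_cells: 10.0    # quartic kernel radius for the cost surface

musle:
  a: 11.8                    # standard metric MUSLE coefficients
  b: 0.56
  p_practice: 1.0
  storm_duration_h: 24.0

dispersion:
  alpha: -2.3                # power-law dispersion exponent
  distance_metric: euclidean # or: overwater
  min_distance_km: 0.5

surveys:
  n_sites: 72
  transects: 3
  points_per_transect: 100

coral_fit:
  n_basis: 10
  n_draws: 1000
  threshold: 0.30            # good-condition cover threshold

features:
  - {name: coral,          target_fraction: 0.30, probabilistic: true, certainty: 0.90}
  - {name: mangrove,       target_fraction: 0.30, probabilistic: false}
  - {name: seagrass,       target_fraction: 0.30, probabilistic: false}
  - {name: turtle_grounds, target_fraction: 0.10, probabilistic: false}

anneal:
  n_iterations: 300000
  n_solutions: 100
  initial_temp: auto
  cooling_factor: auto       # geometric decay spanning the whole run
  blm: 0.0                   # raise for more compact reserves

cost_floor_frac: 0.02        # area-based cost floor (fraction of mean cost)
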