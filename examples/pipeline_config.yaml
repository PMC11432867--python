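# Full-experiment configuration: synthetic detailed/generalized pair,
# both suitability models, cross-comparison. Run with:
#   pollimap pipeline examples/pipeline_config.yaml
output_dir: pollimap_out
simulate: true
seed: 42
landscape:
  n_rows: 200
  n_cols: 200
  cell_size_m: 10
  hedgerow_density: 3.0
min_patch_cells: 250      # 2.5 ha at 10 m cells
flight_distance_m: 680    # reference-species mean flight distance
forest_edge_m: 15
riparian_m: 4
estimap:
  w_f: 0.5                # floral weight in the local score
  lam: 0.5                # favorable-area influence strength
  p_road: 0.5             # road penalty depth
  beta_road_m: 100
invest:
  output_kind: supply
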