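# Default desk-scale monitoring scenario: one wet-tropics river discharging
# onto a coastal strip with an along-shore residual current, seven sites on
# a downstream transect, six sampling dates spanning wet and dry seasons.
scenario:
  grid: {nx: 45, ny: 30, dx: 4000.0, dy: 4000.0, depth: 10.0, coast_rows: 2}
  flow: {u: 0.08, v: 0.0, description: "along-shore residual coastal current (+x, downstream)"}
  rivers:
    - name: tully
      mouth: [2, 5]
      baseflow_ml_d: 300.0
      wet_flow_ml_d: 80000.0
  window: ["2011-10-01", "2012-06-30"]
  params: {K: 50.0, dt: 3600.0, boundary_mode: open-outflow}
exposure:
  threshold_fraction: 0.01
  season: ["2011-11-01", "2012-03-31"]
  map_cap: 20.0
  snapshot_interval: 7
  recent_window_days: 28
sites:
  - {id: TR,  cell: [2, 5],  distance_km: 12.0, relation: upstream}
  - {id: TT1, cell: [2, 6],  distance_km: 4.0,  relation: downstream}
  - {id: TT2, cell: [2, 7],  distance_km: 8.0,  relation: downstream}
  - {id: TT3, cell: [2, 9],  distance_km: 16.0, relation: downstream}
  - {id: TT4, cell: [2, 14], distance_km: 36.0, relation: downstream}
  - {id: RI,  cell: [2, 16], distance_km: 44.0, relation: downstream}
  - {id: FI,  cell: [2, 20], distance_km: 60.0, relation: downstream}
synthesis:
  dates: ["2011-10-10", "2011-11-20", "2011-12-15", "2012-01-20", "2012-03-10", "2012-06-15"]
  depth_range: [800, 1200]
  euk_rate: 0.05
analysis:
  rarefaction_depth: 279
  n_perm: 999
  permanova_terms: [category, season]
  rda_candidates: [rain_7d, water_qual_idx, salinity, water_temp]
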