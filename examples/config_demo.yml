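# Demo pipeline configuration: a reduced synthetic network (2 sites per
# area, 60 days) so the full chain runs in seconds.  Drop the sim_* keys
# and point loggers_csv/meta_csv/interp_csv/assays_csv at real exports to
# analyse field data instead.
outdir: thermobuffer_demo
seed: 1
stages: [simulate, summarize, vpd, bioclim, compare, tolerance]

# day-completeness and thresholds
min_hours: 20
temp_thresholds: [30.0, 39.0]
vpd_threshold_hpa: 12.0

# assay QC and inference
overheat_limit_c: 41.9
min_group_n: 5
n_boot: 200

# synthetic-data scale
sim_n_days: 60
sim_sites_per_area: 2
sim_humidity_sites: 1
sim_n_groups: 10
sim_n_per_group_band: 14
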