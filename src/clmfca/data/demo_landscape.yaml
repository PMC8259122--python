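# Demo synthetic landscape: a compact regional system small enough to run
# in seconds while keeping the urban/rural contrast of the defaults.
n_demand: 200
n_hospitals: 20
region_km: 120.0
n_clusters: 3
cluster_sd_km: 8.0
urban_fraction: 0.7
speed_kmh: 60.0
seed: 0
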