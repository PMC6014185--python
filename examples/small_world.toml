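# A small synthetic world that runs the full pipeline in ~30 s.
outdir = "podomap_run"
grid_shape = [40, 40]
n_covariates = 3
covariate_ranges = [20.0, 12.0, 8.0]
beta = [-9.0, 3.5, -2.0, 1.2]
oversample_region = [0.0, 20.0, 20.0, 40.0]
n_communities = 300
n_reps = 6
brt_max_trees = 1200
rf_trees = 300
geostat_mc = 300
n_samples = 300
seed = 3
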