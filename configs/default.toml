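eps_floor = 0.0001
linearize_srgb = true
export_mesh = false
seed = 0

[decomposition]
lambda_rx = 1.0
lambda_tx = 1.0
lambda_sc = 1000.0
retinex_threshold_t = 0.1
retinex_smooth_weight = 100.0
edge_weight_zero = 0.0
brightness_quantile = 0.95
texture_patch_px = 5
texture_knn = 4
texture_corr_min = 0.9
texture_stride = 2
texture_max_candidates = 2000
texture_var_min = 0.001
solver_tol = 1e-08
solver_max_iter = 10000
rng_seed = 0


[normals]
smooth_weight = 1.0
edge_weight = 1.0
data_weight = 1.0
flat_prior_weight = 0.001
solver_tol = 1e-08
solver_max_iter = 10000
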