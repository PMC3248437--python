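# Canonical benchmark configuration (desk-scale).
# Flat key: value pairs; list values are YAML lists.
n_genes: 30
edge_densities: [0.02, 0.05]
sample_sizes: [50, 200]
n_datasets: 10
noise_sd: 0.05
interaction_strength: 1.0
estimators: [empirical, miller_madow, shrink, schurmann_grassberger]
discretizations: [equal_frequency, equal_width, global_equal_width]
alpha: 0.05
correction: benjamini_hochberg
d_max: 4
n_permutations: 500
out_dir: results/benchmark
seed: 1
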