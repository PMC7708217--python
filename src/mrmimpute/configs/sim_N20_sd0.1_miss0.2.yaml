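# Benchmark setting: 20 subjects, noise sd 0.1, missing rate 0.2
n_regions: 100
n_cpg: 50
n_subjects: 20
cluster_props: [0.1, 0.2, 0.3, 0.4]
noise_sd: 0.1
missing_rate: 0.2
rbf_centers: 50
rbf_scale: 10.0
seed: 0
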