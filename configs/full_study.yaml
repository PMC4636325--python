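# Full-scale study: all scenarios, published replicate count, and the
# scenario-A error-SD sensitivity runs.
scenarios: [A, B, C]
sample_sizes: [50, 110, 500]
replicates: 5000
methods: [OLS, sAIC, sBIC, Ridge, LASSO, Enet1, Enet2, Enet3]
K: 10
master_seed: 2015
eval_size: 1000
sigma_overrides: [0.2, 0.6, 0.8]
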