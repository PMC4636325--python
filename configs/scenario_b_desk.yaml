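# Desk-scale run of the coefficient-accuracy scenario (glucose curve, k = 9)
scenarios: [B]
sample_sizes: [50, 110]
replicates: 500
methods: [OLS, sAIC, sBIC, Ridge, LASSO, Enet1, Enet2, Enet3]
K: 10
master_seed: 2015
eval_size: 1000
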