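# Desk-scale study: every data-generating mechanism, all five methods,
# 100 replicates of 200 individuals each.  Expect long runtimes.
scenarios:
  gamma_psi0: gamma_psi0
  jm_g000_l010: jm_g000_l010
  jm_g000_l030: jm_g000_l030
  jm_g000_l100: jm_g000_l100
  gamma_psi2: gamma_psi2
  gamma_lagged: gamma_lagged
  jm_g150_l010: jm_g150_l010
  jm_g150_l030: jm_g150_l030
  jm_g150_l100: jm_g150_l100
  jm_g300_l005_regular: jm_g300_l005_regular
methods: [A, B, C, D, E]
K: 100
master_seed: 1
n_quad: 9
outdir: study-desk
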