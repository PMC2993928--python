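# Full-pipeline demonstration: a 22-pair cohort with a bimodal FA elevation
# carried by 10 of 22 patients in one primary region ("vta") and an FA
# reduction carried by the complementary 12 in a second region ("mfb").
seed: 7
simulate:
  shape: [32, 32, 32]
  n_pairs: 22
  effects:
    - name: vta
      box: [[12, 17], [12, 17], [12, 17]]
      direction: increase
      effect_size: 0.0
      subgroup_fraction: 0.4545
      separation: 4.0
    - name: mfb
      box: [[22, 27], [8, 13], [20, 25]]
      direction: decrease
      effect_size: 0.0
      separation: 2.0
      complement_of: vta
gap:
  n_sims: 10000
  df_t: 4
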