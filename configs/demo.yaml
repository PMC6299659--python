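# Desk-scale demonstration run: a small partial-diallel trial with two
# traits (low-h2 growth with strong GxE, moderate-h2 wood with weak GxE),
# ABLUP/GBLUP ten-fold CV, and one ratio scenario.
outdir: scratch/demo_run
seed: 1
sim:
  n_markers: 1000
  n_qtl: 200
  n_parents: 20
  n_families: 40
  progeny_range: [3, 5]
  trait_specs:
    - [height, 0.15, 0.45]
    - [pilodyn, 0.40, 0.90]
scenarios:
  - {model: ablup, scope: joint, split: [kfold, 10], n_replicates: 3}
  - {model: gblup, scope: joint, split: [kfold, 10], n_replicates: 3}
  - {model: gblup, scope: joint, split: [ratio, "3:1"], n_replicates: 3}
mcmc_preset: desk
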