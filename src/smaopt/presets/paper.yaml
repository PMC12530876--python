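# Full-scale preset: the four standard sample-set designs (two grids of
# 6^4 = 1296 and 7^4 = 2401 points, two 2^11 = 2048-point Sobol sequences),
# 19 split ratios with 50 seeds each, and the complete hyperparameter grids.
# Provided for completeness; expect hours of compute.
seed: 0
sampling:
  designs:
    - name: Grid1296
      kind: grid
      axes:
        sigma_C: [0.0750, 0.0500, 0.3250]
        sigma_H: [0.0683, 0.0455, 0.2958]
        eps_C: [0.2465, 0.1643, 1.0680]
        eps_H: [0.0300, 0.0200, 0.1300]
    - name: Grid2401
      kind: grid
      axes:
        sigma_C: [0.0500, 0.0500, 0.3500]
        sigma_H: [0.0455, 0.0455, 0.3185]
        eps_C: [0.1643, 0.1643, 1.1501]
        eps_H: [0.0200, 0.0200, 0.1400]
    - name: Sobol1
      kind: sobol
      m: 11
      bounds:
        sigma_C: [0.0500, 0.3500]
        sigma_H: [0.0450, 0.3200]
        eps_C: [0.1500, 1.1500]
        eps_H: [0.0200, 0.1400]
    - name: Sobol2
      kind: sobol
      m: 11
      scramble_seed: derive
      bounds:
        sigma_C: [0.0500, 0.3500]
        sigma_H: [0.0450, 0.3500]
        eps_C: [0.1500, 1.1500]
        eps_H: [0.0100, 0.1500]
oracle:
  target_density: 700.0
  noise_sd: 5.0
  failure_prob: 0.05
preprocess:
  plaus_low: 0.0
  plaus_high: 1500.0
harness:
  ratios: {start: 0.05, stop: 0.95, step: 0.05}
  seeds_per_ratio: 50
  families:
    linear: [{}]
    polynomial: [{degree: 1}, {degree: 2}, {degree: 3}, {degree: 4}, {degree: 5},
                 {degree: 6}, {degree: 7}, {degree: 8}, {degree: 9}, {degree: 10}]
    random_forest: [{n_trees: 10}, {n_trees: 100}, {n_trees: 250},
                    {n_trees: 500}, {n_trees: 750}, {n_trees: 1000}]
    gaussian_process: [{kernel: rbf}, {kernel: matern}, {kernel: rq}]
    fnn: [{}]
selection:
  k: 12
optimizer:
  weights: [1.0, 1.0]
  tol: 1.0e-3
  max_iter: 20
  h_rel: 0.01
  alpha0: 0.1
  n_starts: 5
conformers:
  n: 97
verify:
  n_rep: 3
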