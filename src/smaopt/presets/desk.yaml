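# Reduced-scale preset for interactive desk runs (minutes on one CPU).
# Four ~256-point designs, 5 split ratios, 4 seeds per ratio.
seed: 0
sampling:
  designs:
    - name: GridA
      kind: grid
      axes:
        sigma_C: [0.0750, 0.0833333333, 0.3250]
        sigma_H: [0.0683, 0.0758333333, 0.2958]
        eps_C: [0.2465, 0.2738333333, 1.0680]
        eps_H: [0.0300, 0.0333333333, 0.1300]
    - name: GridB
      kind: grid
      axes:
        sigma_C: [0.0500, 0.1000, 0.3500]
        sigma_H: [0.0455, 0.0910, 0.3185]
        eps_C: [0.1643, 0.3286, 1.1501]
        eps_H: [0.0200, 0.0400, 0.1400]
    - name: SobolA
      kind: sobol
      m: 8
      bounds:
        sigma_C: [0.0500, 0.3500]
        sigma_H: [0.0450, 0.3200]
        eps_C: [0.1500, 1.1500]
        eps_H: [0.0200, 0.1400]
    - name: SobolB
      kind: sobol
      m: 8
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
  ratios: {start: 0.55, stop: 0.75, step: 0.05}
  seeds_per_ratio: 4
  families:
    polynomial: [{degree: 3}, {degree: 4}]
    random_forest: [{n_trees: 100}]
selection:
  k: 3
optimizer:
  weights: [1.0, 0.0]
  tol: 1.0e-3
  max_iter: 20
  h_rel: 0.01
  alpha0: 0.1
  n_starts: 3
verify:
  n_rep: 3
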