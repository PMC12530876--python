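# Methods

This note records the modelling choices, numerical conventions and built-in
benchmark constants that the implementation treats as ground truth.

## Parameter space

The optimization variables are the Lennard-Jones parameters of carbon and
hydrogen in an alkane: `sigma_C`, `sigma_H` (nm) and `eps_C`, `eps_H`
(kJ/mol). The default acquisition box is

| parameter | min | max |
|---|---|---|
| sigma_C | 0.05 | 0.35 |
| sigma_H | 0.045 | 0.35 |
| eps_C | 0.15 | 1.15 |
| eps_H | 0.01 | 0.15 |

Two sampling strategies are provided. Full-factorial grids are specified per
axis as (min, step, max) with inclusive endpoints (relative tolerance 1e-9)
and enumerated in lexicographic axis order. Sobol sets are unscrambled
base-2 sequences of 2^m points (scipy.stats.qmc), optionally Owen-scrambled
with a seed; 2^m points stratify every 1-D projection exactly. The four
reference designs (`reference_sample_specs`) are two grids of 6^4 = 1296 and
7^4 = 2401 points over slightly different boxes and two 2^11 = 2048-point
Sobol sequences.

## Synthetic density oracle

The oracle stands in for a bulk-phase MD simulation of n-octane density at
293.15 K / 1 bar. Its reference formula, constants and clamp are defined in
one place (`smaopt.oracle`) and all tests treat the formula itself as ground
truth:

```
v      = 8*sigma_C^3 + 18*sigma_H^3                     (volume proxy)
smooth = 200 + 1000 * expit(-(v - 0.15) * 10)           (kg/m^3)
rugged = 8 * eps_C * sin(2*pi*sigma_H / 0.06)
               * sin(2*pi*eps_C / 0.25)                 (default amplitude 60)
rho    = clip(smooth + rugged + noise, 0, 2000)
```

- The smooth term falls monotonically with the volume proxy and crosses the
  700 kg/m^3 target along a level set inside the box.
- The rugged term couples `sigma_H` and `eps_C` on a wavelength (0.06 nm)
  close to typical grid spacings, which is what makes grid-sampled training
  data alias it while Sobol samples resolve it.
- Observation noise is Gaussian (sd 5 kg/m^3); with probability 0.05 a draw
  "fails", returning either 0 or an implausibly high density, flagged
  invalid. Each point's randomness derives from
  `SeedSequence((master_seed, index))`, so datasets are reproducible and
  independent of evaluation order.
- `OracleConfig.mild()` sets the rugged amplitude to 8 kg/m^3 (about twice
  the noise sd) and disables failures. This "mild ruggedness" condition is
  defined a priori as ruggedness at the sampling-noise scale; it emulates
  the benign near-target region in which trained surrogates reach ~1 % MAPE.

Preprocessing keeps records that are valid and have
`0 < density <= 1500 kg/m^3` (the plausibility window for liquid alkanes).

## Surrogate families and metrics

Five families share one train/predict contract (`ModelSpec`,
`SurrogateModel`): ordinary least squares; polynomial regression (full
multivariate basis, degrees 1-10, standardized inputs, refuses degrees with
more basis functions than samples); random forest (10-1000 trees); Gaussian
process regression (constant * {RBF, Matern nu=2.5, rational quadratic}
kernels, standardized inputs, normalized targets, alpha = 1e-6, five restart
optimizations) and a feed-forward network (two 64-unit ReLU layers, Adam,
standardized inputs and targets). All stochastic fitting draws from the
spec's `train_seed`, so training is deterministic.

In addition to the three comparison kernels, a composite
`kernel="multiscale"` (constant * rational quadratic + constant * ARD RBF)
is exposed: the isotropic rational quadratic underfits the steep density
transition at small sample sizes (~3 % bias near level-set corners), while
the composite captures the landscape's two length scales and is the
recommended optimization surrogate.

Metrics: MAPE as a fraction, `(1/n) sum |y - yhat| / |y|` (undefined for
zero targets), and `R^2 = 1 - SS_res/SS_tot` (undefined for constant
targets).

## Comparison protocol

For each dataset, split ratio and seed, a model trains on a pseudo-random
`round(ratio * n)`-record subset and is scored twice: on the held-out
remainder of the same dataset (in-sample test, IST) and on the concatenation
of all other datasets (out-of-sample test, OST). Ratios sweep 0.05 to 0.95
in 0.05 steps (19 values); the full-scale plan uses 50 seeds per ratio and
4 datasets, giving 3800 / 38000 / 22800 / 11400 / 3800 trainings for the
linear / polynomial / forest / Gaussian-process / network grids.

Per-group scores aggregate to mean +/- sample standard deviation (ddof 1)
and group means are compared with Welch's two-sided t-test. Selection takes
the union of the k lowest-MAPE and k highest-R^2 models; entries with
identical (MAPE, R^2) pairs are treated as the same underlying model, which
is how the bundled 24-row candidate table reduces to a 17-model union.

## Conformers and relative conformational energies

The nanoscale objective uses a synthetic octane (C8H18) conformer fixture:
ideal geometry (C-C 0.153 nm, C-H 0.109 nm, CCC 112 deg), backbone dihedrals
drawn from {trans, gauche+, gauche-}^5 excluding adjacent opposite-sign
gauche pairs (syn-pentane clashes), plus a fixed bonded-energy offset per
conformer (2.9 kJ/mol per gauche dihedral plus small seeded variation).
Conformer energies are the offset plus the intramolecular Lennard-Jones sum
(1-2/1-3 pairs excluded, 1-4 included at full weight by default,
Lorentz-Berthelot combination), referenced to the all-trans conformer whose
relative energy is exactly zero. The default fixture holds 97 conformers
(96 nonzero relative energies).

Target energies are computed at a designated "true" parameter set
(0.2234, 0.150, 0.650, 0.110), chosen on the oracle's 700 kg/m^3 level set —
`sigma_H = 0.15` zeroes the rugged sine term exactly and `sigma_C` solves
the smooth sigmoid for the target — so the density and RCE objectives share
an optimum and parameter recovery is well-posed by construction.

## Optimization and verification

Error measures: `err_dens = 100 * (rho - target) / target` (signed percent)
and `err_rce` = mean unsigned percent deviation over conformers with nonzero
targets. The loss is `w_dens * (err_dens/100)^2 + w_rce * (err_rce/100)^2`.
Density comes from the surrogate's `predict`; RCE is computed directly.

Descent runs in box-normalized coordinates: central-difference gradients
(step 0.01 of each range, one-sided at bounds), a normalized step of initial
length 0.1 along the negative gradient, halved up to 10 times until the loss
decreases, proposals clamped to the box. Termination: relative improvement
below 1e-3, 20 iterations, zero gradient, or no decreasing step. Accepted
iterates have non-increasing loss and every objective evaluation is counted.

`verify` re-evaluates the final parameters against the ground-truth oracle
with n independent replicates (failure draws disabled — a failed replicate
would simply be re-run in practice) and reports the replicate mean +/-
sample sd, the resulting signed density error and the recomputed RCE error.

## Reproducibility

Every stochastic stage of the pipeline derives its seed from the global seed
via `sha256(f"{seed}/{tag}") mod 2^31`; artifacts are delimited text written
at 12 significant digits and the manifest records content hashes, so a rerun
with the same configuration and seed is byte-identical.
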