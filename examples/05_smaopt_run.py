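"""Full surrogate-model-assisted optimization (SMAOpt) run.

Workflow: sample the parameter space, evaluate densities through the oracle,
preprocess, train a Gaussian-process surrogate, then run gradient descent on
a combined objective -- the surrogate supplies the (expensive) density while
the relative conformational energies (RCE) of an octane conformer set are
computed directly.  The optimized parameters are finally verified against
the ground-truth oracle.
"""

import numpy as np

import smaopt as sm
from smaopt.optimizer import OptimizationTargets, OptimizerConfig, optimize, verify

space = sm.lj_acquisition_space()
oracle = sm.OracleConfig(master_seed=11).mild()  # mildly rugged, noisy

# 1. acquire and clean training data
raw = sm.evaluate_samples(sm.make_sobol(space, 8), oracle, name="train")
clean, removed = sm.preprocess(raw)
print(f"training data: {len(clean)} records ({removed} removed)")

# 2. train the recommended optimization surrogate
model = sm.train(
    sm.ModelSpec.make("gaussian_process", kernel="multiscale"),
    clean, input_space=space,
)
rep = sm.evaluate(model, clean, "IST")
print(f"surrogate in-sample: MAPE {rep.mape:.4f}, R^2 {rep.r2:.4f}\n")

# 3. conformer targets: 97 octane conformers, 96 nonzero reference energies
conformers = sm.make_conformer_fixture(n_conformers=97, seed=0)
targets = OptimizationTargets(target_density=700.0, conformers=conformers)

# 4. five optimization runs from random interior starts
cfg = OptimizerConfig(weights=(1.0, 1.0))
rng = np.random.default_rng(2)
print(f"{'run':>3s} {'iters':>5s} {'err_dens %':>10s} {'err_rce %':>9s}  termination")
for run in range(5):
    p0 = sm.LJParamSet.from_array(space.denormalize(rng.uniform(0.15, 0.85, 4)))
    traj = optimize(p0, targets, model.predict, space, cfg)
    vr = verify(traj.final.params, targets, oracle, n_rep=5,
                rho_pred=model.predict(traj.final.params))
    p = traj.final.params
    print(f"{run:3d} {traj.final.iteration:5d} {vr.err_dens:10.2f} {vr.err_rce:9.1f}"
          f"  {traj.termination}")
    print(f"      params: sigma_C={p.sigma_C:.3f} sigma_H={p.sigma_H:.3f} "
          f"eps_C={p.eps_C:.3f} eps_H={p.eps_H:.3f}  "
          f"rho={vr.rho_sim_mean:.1f}+/-{vr.rho_sim_sd:.1f} kg/m^3")
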