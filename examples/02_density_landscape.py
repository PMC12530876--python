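"""Explore the synthetic bulk-density landscape.

The built-in oracle emulates the qualitative structure of an MD density
landscape for n-octane: a smooth sigmoidal transition through the 700 kg/m^3
target as the effective molecular volume grows, a rugged sigma_H-eps_C
coupling on a much shorter length scale, observation noise, and occasional
failed runs that produce implausible densities.
"""

import numpy as np

import smaopt as sm
from smaopt.oracle import true_density, volume_proxy

space = sm.lj_acquisition_space()

# 1. the smooth backbone: density falls monotonically with the volume proxy
cfg = sm.OracleConfig(master_seed=0).smooth_only()
sigma_h = np.linspace(0.045, 0.35, 8)
pts = np.column_stack([np.full(8, 0.12), sigma_h, np.full(8, 0.5), np.full(8, 0.05)])
print("sigma_H scan (smooth landscape, sigma_C = 0.12 nm):")
for sh, v, rho in zip(sigma_h, volume_proxy(pts), true_density(pts, cfg)):
    marker = " <- near target" if abs(rho - 700) < 60 else ""
    print(f"  sigma_H={sh:.3f}  v={v:.4f}  rho={rho:7.1f}{marker}")

# 2. ruggedness: along eps_C the full landscape oscillates around the target
cfg_full = sm.OracleConfig(master_seed=0).noiseless()
eps_c = np.linspace(0.15, 1.15, 9)
pts = np.column_stack([np.full(9, 0.075), np.full(9, 0.20085), eps_c, np.full(9, 0.07)])
print("\neps_C scan on the target level set (rugged, noiseless):")
for ec, rho in zip(eps_c, true_density(pts, cfg_full)):
    print(f"  eps_C={ec:.3f}  rho={rho:7.1f}  ({rho - 700:+6.1f} from target)")

# 3. sampling with noise and failures, then preprocessing
noisy = sm.OracleConfig(master_seed=42)
ds = sm.evaluate_samples(sm.make_sobol(space, 9), noisy, name="demo")
clean, removed = sm.preprocess(ds)
print(f"\nsampled {len(ds)} points: {removed} removed "
      f"(failures/implausible), {len(clean)} kept for training")
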