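"""Build the standard sampling designs for the Lennard-Jones parameter space.

The study compares full-factorial grids against base-2 Sobol sequences for
acquiring density training data.  This script materializes the four reference
designs and demonstrates the property that makes Sobol sets attractive:
every 1-D projection of 2^m points is perfectly stratified.
"""

import numpy as np

import smaopt as sm

space = sm.lj_acquisition_space()
print("feasible parameter space:")
for name, lo, hi in zip(space.names, space.lower, space.upper):
    print(f"  {name:8s} [{lo}, {hi}]")

specs = sm.reference_sample_specs()
for key in ("Grid1296", "Grid2401"):
    pts = sm.make_grid(specs[key])
    print(f"\n{key}: {len(pts)} points, {specs[key].counts()} per axis")

sobol_space, m = specs["Sobol1"]
pts = sm.make_sobol(sobol_space, m)
print(f"\nSobol1: 2^{m} = {len(pts)} points")

# 1-D stratification: with 2^4 points, each sixteenth of every axis range
# holds exactly one point -- grids cannot do this with 16 points in 4-D.
small = sm.make_sobol(space, 4)
unit = space.normalize(small)
for dim, name in enumerate(space.names):
    bins = sorted(np.floor(unit[:, dim] * 16 + 1e-9).astype(int))
    print(f"{name}: occupied bins {bins}")
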