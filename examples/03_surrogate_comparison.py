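"""Compare the five surrogate families on one density dataset.

Each model trains on 75% of a Sobol-sampled dataset and is scored two ways:
on the held-out quarter of the same dataset (in-sample test, IST) and on an
independently sampled dataset (out-of-sample test, OST).  The OST probes
generalization beyond the sampling design that produced the training data.
"""

import smaopt as sm

space = sm.lj_acquisition_space()
cfg = sm.OracleConfig(master_seed=7)

train_set, _ = sm.preprocess(sm.evaluate_samples(sm.make_sobol(space, 8), cfg, "train"))
other, _ = sm.preprocess(
    sm.evaluate_samples(sm.make_sobol(space, 8, scramble_seed=99), cfg, "other")
)
print(f"training pool: {len(train_set)} records, OST pool: {len(other)} records\n")

candidates = [
    sm.ModelSpec.make("linear"),
    sm.ModelSpec.make("polynomial", degree=3),
    sm.ModelSpec.make("random_forest", n_trees=100),
    sm.ModelSpec.make("gaussian_process", kernel="rq"),
    sm.ModelSpec.make("gaussian_process", kernel="multiscale"),
    sm.ModelSpec.make("fnn"),
]

split = sm.SplitSpec(ratio=0.75, seed=1)
print(f"{'model':42s} {'IST MAPE':>9s} {'IST R2':>7s} {'OST MAPE':>9s} {'OST R2':>7s}")
rows = []
for spec in candidates:
    ist, ost = sm.run_ist_ost(spec, train_set, split, [other])
    rows.append((spec.label(), ist.mape, ist.r2))
    print(f"{spec.label():42s} {ist.mape:9.4f} {ist.r2:7.3f} {ost.mape:9.4f} {ost.r2:7.3f}")

sel = sm.select_top([(label, m, r) for label, m, r in rows], k=2)
print(f"\nbest by MAPE: {sel.by_mape[0]}")
print(f"best by R^2:  {sel.by_r2[0]}")
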