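"""The imbalance countermeasures on a small worked dataset.

Shows the three weight schemes (simple, linear, quadratic) on a 12-line
dataset with 3 sensitive lines, then the two upsampling schemes. Simple
weights equalize per-class mass; distance weights additionally emphasize
lines far from the IC50 threshold; upsampling balances by row duplication.
"""

import numpy as np

from sauronrf import (
    Dataset,
    binarize,
    distance_sample_weights,
    proportional_upsample,
    simple_sample_weights,
    upsample,
)

rng = np.random.default_rng(0)
y = np.array([-4.0, -2.0, -0.5] + [float(v) for v in range(1, 10)])
t = 0.0
ds = Dataset(
    sample_ids=[f"CL{i}" for i in range(12)],
    gene_ids=["g1", "g2"],
    X=rng.standard_normal((12, 2)),
    y=y,
    Y=binarize(y, t),
    t=t,
)
print(f"{ds.class_counts().n_sens} sensitive vs {ds.class_counts().n_res} resistant (t = {t})")

w = simple_sample_weights(ds.Y)
print(f"\nsimple weights: sensitive {w.w_star[0]:.1f}, resistant {w.w_star[-1]:.1f} "
      f"(per-class sums {w.w_star[ds.Y == 1].sum():.1f} / {w.w_star[ds.Y == 0].sum():.1f})")

for d, name in [(1, "linear"), (2, "quadratic")]:
    w = distance_sample_weights(ds.y, ds.Y, ds.t, d=d)
    sens = ", ".join(f"{v:.3f}" for v in w.w_star[ds.Y == 1])
    print(f"{name} weights (sensitive lines at distances 4, 2, 0.5): {sens} "
          f"(class sum {w.w_star[ds.Y == 1].sum():.1f})")

up = upsample(ds, seed=1)
print(f"\nupsample: {ds.n_samples} -> {up.n_samples} rows, "
      f"{up.class_counts().n_sens} sensitive = {up.class_counts().n_res} resistant")

prop = proportional_upsample(ds, seed=1)
copies = {s: sum(1 for sid in prop.sample_ids if sid.split('#')[0] == s) for s in ("CL0", "CL1", "CL2")}
print(f"proportional upsample copy counts by threshold distance: {copies} "
      "(farther from t = more copies)")
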