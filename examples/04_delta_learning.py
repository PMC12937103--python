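"""Delta-learning toward a higher reference level.

The 'high level' is the same analytic oracle with 10% stiffer springs.
A delta model trained on one third of the base set corrects the base
model's forces toward it; composition is strict addition.
"""

import numpy as np

from gpmlmm import (
    HierarchicalModel,
    build_dataset,
    default_toy_params,
    predict_vacuum,
    score,
    train_delta,
    train_vacuum,
)

base_level = default_toy_params()
high_level = base_level.scaled(1.1)

base_data = build_dataset(base_level, None, 90, rng=4)
high_data = build_dataset(high_level, None, 30, rng=5)   # 1/3 of base size
high_test = build_dataset(high_level, None, 40, rng=6)

vac = train_vacuum(base_data, lengthscale=1.0, sigma_f=1e-4)
delta = train_delta(HierarchicalModel(vacuum=vac), high_data, kind="vacuum")

ref = np.stack([s.vacuum_forces for s in high_test])
base_pred = np.stack([predict_vacuum(vac, s.geom)[1] for s in high_test])
comp_pred = np.stack(
    [predict_vacuum(vac, s.geom)[1] + predict_vacuum(delta, s.geom)[1]
     for s in high_test]
)
r_base = score(base_pred, ref, "forces").rmse
r_comp = score(comp_pred, ref, "forces").rmse
print(f"force RMSE vs the high-level reference:")
print(f"  base model          : {r_base:.4f} kcal/mol/A")
print(f"  base + delta model  : {r_comp:.4f} kcal/mol/A "
      f"({100 * (1 - r_comp / r_base):.1f}% lower)")
# the delta model learns only the (smooth, small) correction, so a third
# of the data suffices to nearly eliminate the level mismatch.
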