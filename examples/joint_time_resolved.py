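"""Joint change-of-state merging with a shared scale function.

Time-resolved experiments compare two states (e.g. dark vs. light) whose
difference signal is tiny — here 2% amplitude changes on 10% of
reflections. Fitting one scale function for both datasets while keeping
separate amplitude sets puts both states on a common scale, so the
per-reflection systematic errors cancel in the difference.
"""

import numpy as np
from scipy import stats

from varmerge import (ScaleConfig, SyntheticSpec, TrainingConfig, fit,
                      simulate)

spec = SyntheticSpec(noise_level=0.01, n_datasets=2, changed_fraction=0.10,
                     change_scale=0.02, seed=7)
table, truth = simulate(spec)
print(f"{len(table)} observations across 2 datasets; 10% of reflections "
      "change amplitude by 2% between states\n")

res = fit(table, "P1",
          training=TrainingConfig(iterations=8000, seed=7),
          scale_config=ScaleConfig(width=12))

j = res.unique_map.unique.merge(
    truth["unique"], on=["asu_h", "asu_k", "asu_l", "dataset_id"],
    how="left")
p = j.assign(F_est=res.posterior.mean).pivot_table(
    index=["asu_h", "asu_k", "asu_l"], columns="dataset_id",
    values=["F_est", "F", "changed"])
dF_est = (p[("F_est", 1)] - p[("F_est", 0)]).to_numpy()
dF_true = (p[("F", 1)] - p[("F", 0)]).to_numpy()
changed = p[("changed", 0)].astype(bool).to_numpy()

r = stats.pearsonr(dF_true, dF_est)[0]
print(f"Pearson r(true dF, inferred dF) over all reflections = {r:.3f}")
print(f"inferred dF on unchanged reflections: mean "
      f"{dF_est[~changed].mean():+.5f}, sd {dF_est[~changed].std():.5f}")
print(f"inferred |dF| on changed reflections: mean "
      f"{np.abs(dF_est[changed]).mean():.5f}")
print("\nA difference map built from dF benefits from the shared scale:")
print("unchanged reflections scatter around zero instead of inheriting")
print("two independent sets of scaling errors.")
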