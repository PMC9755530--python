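"""Minimal end-to-end walkthrough on the three-amplitude toy problem.

Thirty noisy intensity observations — three reflections seen once per
image across ten images, with a sharply varying scale — are enough to
recover both the scale curve and the amplitudes with calibrated
uncertainties.
"""

import numpy as np

from varmerge import ScaleConfig, TrainingConfig, fit, make_toy

table, truth = make_toy(seed=1)
print(f"{len(table)} observations of 3 unique reflections; "
      f"true amplitudes {truth.F_true}")

result = fit(table, "P1",
             training=TrainingConfig(iterations=5000, seed=1),
             scale_config=ScaleConfig(width=8))

lo, hi = result.posterior.interval(0.95)
print("\n  h   true F    posterior mean ± sd     95% interval   covered")
for i, (h, F) in enumerate(zip((1, 2, 3), truth.F_true)):
    mark = "yes" if lo[i] <= F <= hi[i] else "no"
    print(f"  {h}   {F:6.3f}    {result.posterior.mean[i]:6.3f} ± "
          f"{result.posterior.std[i]:5.3f}    [{lo[i]:5.3f}, {hi[i]:5.3f}]"
          f"   {mark}")

r = np.corrcoef(truth.F_true, result.posterior.mean)[0, 1]
print(f"\nPearson r(true F, posterior mean) = {r:.4f}")
print("The intervals should bracket the truth ~95% of the time; the")
print("correlation shows the relative amplitudes are recovered almost")
print("exactly even though every observation is distorted by a scale")
print("factor spanning a twenty-fold range.")
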