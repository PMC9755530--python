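"""Scale and merge a monochromatic rotation series, then write MTZ/CSV.

Simulates 200 unique reflections observed ~8 times each under a smooth
nonlinear scale field (resolution decay x rotation-angle sinusoid),
merges them by variational inference, and compares the posterior
amplitudes with the generating truth.
"""

from varmerge import (ScaleConfig, SyntheticSpec, TrainingConfig,
                      extract_merged, fit, simulate, write_merged)
from varmerge.synthetic import recovery_report

spec = SyntheticSpec(n_unique=200, multiplicity=8.0, noise_level=0.05,
                     seed=11)
table, truth = simulate(spec)
print(f"{len(table)} observations, {spec.n_unique} unique reflections, "
      f"{table.n_images} images, metadata {table.metadata_columns}")

result = fit(table, "P1",
             training=TrainingConfig(iterations=8000, seed=11),
             scale_config=ScaleConfig(depth=8, width=16))

rep = recovery_report(result, truth)
print(f"Pearson r(true F, inferred F)       = {rep['pearson_F']:.3f}")
print(f"Pearson r(true Sigma, mean Sigma)   = {rep['pearson_Sigma']:.3f}")
print(f"95% credible-interval coverage      = {rep['coverage_95']:.2f}")
print("(mean-field intervals narrow faster than residual scale-field")
print(" misfit shrinks, so coverage drops well below nominal at scale;")
print(" point estimates stay accurate — see docs/methods.md)")

merged = extract_merged(result)
write_merged(merged, "merged_example.mtz", spacegroup="P 1",
             cell=(30, 30, 30, 90, 90, 90))
write_merged(merged, "merged_example.csv")
print(f"\nwrote {len(merged)} merged amplitudes to merged_example.mtz/.csv")
print("F/SigF are posterior means and standard deviations on the Wilson")
print("scale (E[F^2] = multiplicity); no separate French-Wilson step is")
print("needed because the prior already constrains amplitudes positive.")
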