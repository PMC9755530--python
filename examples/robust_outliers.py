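"""Robust merging with a Student-t likelihood.

Injects 10% gross outliers and compares the normal error model with a
t-distributed one (16 degrees of freedom, the value that cross-validation
favors on real rotation data). The t model should match or beat the
normal model on both held-out prediction and amplitude recovery —
without any outlier-rejection step.
"""

from varmerge import (LikelihoodConfig, ScaleConfig, SyntheticSpec,
                      TrainingConfig, fit, simulate)
from varmerge.crossval import holdout_predict_score
from varmerge.synthetic import recovery_report

spec = SyntheticSpec(n_unique=100, multiplicity=6.0, outlier_fraction=0.10,
                     outlier_scale=10.0, seed=3)
table, truth = simulate(spec)
print(f"{len(table)} observations, ~10% replaced by ~10-sigma outliers\n")

sc = ScaleConfig(depth=8, width=8)
print("likelihood     held-out Spearman    Pearson r(true F, inferred F)")
for label, lik in [("normal ", LikelihoodConfig()),
                   ("t (16) ", LikelihoodConfig("student_t", 16.0))]:
    score, report, _ = holdout_predict_score(
        table, "P1", fraction=0.15, seed=3, likelihood=lik,
        scale_config=sc, training=TrainingConfig(iterations=6000, seed=3))
    res = fit(table, "P1", likelihood=lik, scale_config=sc,
              training=TrainingConfig(iterations=6000, seed=3))
    rep = recovery_report(res, truth)
    print(f"{label}        {score:.4f}               {rep['pearson_F']:.4f}")

print("\nThe t likelihood discounts observations many sigma from the")
print("model prediction, so spurious intensities stop dragging the scale")
print("function and the amplitudes; the normal model has no such guard.")
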